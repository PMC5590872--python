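chrom_x	start_x	end_x	gene_x	chrom_y	start_y	end_y	gene_y	length	mismatches
chrZ	1524420	1524638	SMAD2	chrW	397369	397587		219	39
chrZ	1555791	1555999		chrW	347291	347499		209	50
chrZ	1556251	1556531		chrW	346752	347032		281	54
chrZ	1557294	1557452		chrW	345857	346015		159	14
chrZ	18953921	18954146		chrW	809288	809513		226	52
chrZ	19036774	19036925		chrW	1096613	1096764	FET1	152	5
chrZ	19055988	19056151		chrW	1194410	1194573		164	15
chrZ	435849	436019	ST8SIA3	chrW	513668	513838		171	11
chrZ	437109	437271	ST8SIA3	chrW	519588	519750		163	27
chrZ	439711	439871	ST8SIA3	chrW	523214	523374		161	30
chrZ	53600234	53600410		chrW	619786	619962		177	45
chrZ	7219805	7219996	LOC407092	chrW	132663	132854	UBAP2	192	15
chrZ	7297965	7298239	LOC407092	chrW	98620	98894	UBAP2	275	49
chrZ	7300018	7300231	LOC407092	chrW	97675	97888	UBAP2	214	28
chrZ	7300957	7301146	LOC407092	chrW	96741	96930	UBAP2	190	42
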