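chrom_x	start_x	end_x	gene_x	chrom_y	start_y	end_y	gene_y	length	mismatches
chrX	11298648	11298818	AMELX	chrY	6868192	6868362	AMELY	171	14
chrX	11298809	11298973	AMELX	chrY	6868037	6868201	AMELY	165	11
chrX	12975506	12975677	TMSB4X	chrY	13703601	13703772	TMSB4Y	172	23
chrX	41136804	41137021	USP9X	chrY	12726575	12726792	USP9Y	218	18
chrX	41140966	41141217	USP9X	chrY	12735998	12736249	USP9Y	252	29
chrX	41143291	41143443	USP9X	chrY	12738157	12738309	USP9Y	153	15
chrX	41166023	41166214	USP9X	chrY	12773734	12773925	USP9Y	192	19
chrX	41168007	41168218	USP9X	chrY	12776649	12776860	USP9Y	212	28
chrX	41169995	41170234	USP9X	chrY	12778019	12778258	USP9Y	240	25
chrX	41184397	41184675	USP9X	chrY	12786522	12786800	USP9Y	279	36
chrX	41189313	41189475	USP9X	chrY	12793039	12793201	USP9Y	163	22
chrX	41223217	41223402	USP9X	chrY	12846333	12846518	USP9Y	186	15
chrX	45059247	45059466	KDM6A	chrY	13359767	13359986	UTY	220	20
chrX	45060609	45060764	KDM6A	chrY	13358464	13358619	UTY	156	15
chrX	45063422	45063817	KDM6A	chrY	13355003	13355398	UTY	396	73
chrX	45069579	45069955	KDM6A	chrY	13335959	13336335	UTY	377	65
chrX	45069962	45070357	KDM6A	chrY	13335563	13335958	UTY	396	56
chrX	45110079	45110249	KDM6A	chrY	13251017	13251187	UTY	171	19
chrX	45111953	45112110	KDM6A	chrY	13249180	13249337	UTY	158	17
chrX	53193437	53193636	KDM5C	chrY	19706441	19706640	KDM5D	200	15
chrX	53194139	53194577	KDM5C	chrY	19707147	19707585	KDM5D	439	62
chrX	53194546	53194708	KDM5C	chrY	19707554	19707716	KDM5D	163	15
chrX	53195231	53195410	KDM5C	chrY	19708244	19708423	KDM5D	180	15
chrX	53196686	53197044	KDM5C	chrY	19709451	19709809	KDM5D	359	63
chrX	53198490	53198642	KDM5C	chrY	19715352	19715504	KDM5D	153	27
chrX	53198977	53199158	KDM5C	chrY	19715823	19716004	KDM5D	182	15
chrX	53201550	53201743	KDM5C	chrY	19716279	19716472	KDM5D	194	27
chrX	53214689	53214847	KDM5C	chrY	19732584	19732742	KDM5D	159	32
chrX	53217796	53217966	KDM5C	chrY	19741318	19741488	KDM5D	171	20
chrX	53224740	53224908	KDM5C	chrY	19744385	19744553	KDM5D	169	27
chrX	5890658	5890815	NLGN4X	chrY	14843196	14843353	NLGN4Y	158	17
chrX	5890913	5891080	NLGN4X	chrY	14842933	14843100	NLGN4Y	168	19
chrX	5891146	5891303	NLGN4X	chrY	14842706	14842863	NLGN4Y	158	16
chrX	5892286	5892519	NLGN4X	chrY	14841542	14841775	NLGN4Y	234	34
chrX	5892564	5892721	NLGN4X	chrY	14841340	14841497	NLGN4Y	158	23
chrX	6151347	6151560	NLGN4X	chrY	14622026	14622239	NLGN4Y	214	19
chrX	6228566	6228845	NLGN4X	chrY	14522638	14522917	NLGN4Y	280	25
chrX	9465226	9465425	TBL1X	chrY	6910762	6910961	TBL1Y	200	87
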