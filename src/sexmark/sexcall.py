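"""Sex classification from marker hit counts.

A heterogametic genome (XY male, ZW female) contributes reads to both
members of each marker pair at roughly 1:1, a homogametic genome (XX, ZZ)
only to the shared-chromosome member (1:0).  The classifier therefore
looks at one number: the fraction of hits landing on the dominant
(sex-limited, Y/W) members.  At or above ``het_fraction_threshold``
(default 0.2, chosen to absorb stray mis-mapped hits) the sample is
heterogametic; below it, homogametic; with fewer than ``min_total_hits``
total marker hits no call is made at all.

:func:`train_threshold` re-derives the fraction threshold from labeled
samples by an exhaustive 0-1-loss sweep, and :func:`estimate_min_reads`
implements the pre-pass ("test mode") that recommends how many reads a
dataset needs before the hit floor is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

from .mapping import HitTable, MarkerIndex, count_hits
from .markers import PipelineParams
from .seqio import ReadRecord

logger = logging.getLogger("sexmark.sexcall")

__all__ = [
    "SexSystem",
    "CallClass",
    "SexCall",
    "classify",
    "train_threshold",
    "MinReadsEstimate",
    "estimate_min_reads",
    "DEFAULT_SCHEDULE",
]


class SexSystem(str, Enum):
    XY = "XY"  # male heterogametic (mammals)
    ZW = "ZW"  # female heterogametic (birds)


class CallClass(Enum):
    HETEROGAMETIC = "heterogametic"
    HOMOGAMETIC = "homogametic"
    INDETERMINATE = "indeterminate"


_SEX_LABEL = {
    (SexSystem.XY, CallClass.HETEROGAMETIC): "male",
    (SexSystem.XY, CallClass.HOMOGAMETIC): "female",
    (SexSystem.ZW, CallClass.HETEROGAMETIC): "female",
    (SexSystem.ZW, CallClass.HOMOGAMETIC): "male",
}


@dataclass(frozen=True)
class SexCall:
    """One sample's call: hit counts, dominant fraction, class, phenotype."""

    sample_id: str
    system: SexSystem
    hits_recessive: int
    hits_dominant: int
    fraction_dominant: float
    call: CallClass
    sex_label: str
    status: str
    reads_used: int = 0


def classify(
    hits: HitTable,
    system: SexSystem,
    params: PipelineParams | None = None,
    *,
    sample_id: str = "sample",
) -> SexCall:
    """Turn a HitTable into a SexCall under the declared sex system.

    fraction >= threshold -> heterogametic (the boundary value itself is
    heterogametic: only "less than threshold" is homogametic); total hits
    below ``min_total_hits`` -> indeterminate/unknown.
    """
    if params is None:
        params = PipelineParams()
    system = SexSystem(system)
    total = hits.hits_recessive + hits.hits_dominant
    fraction = hits.hits_dominant / total if total > 0 else 0.0
    if total < params.min_total_hits:
        call = CallClass.INDETERMINATE
        label = "unknown"
        status = f"insufficient hits ({total} < {params.min_total_hits})"
    else:
        call = (
            CallClass.HETEROGAMETIC
            if fraction >= params.het_fraction_threshold
            else CallClass.HOMOGAMETIC
        )
        label = _SEX_LABEL[(system, call)]
        status = "ok"
    return SexCall(
        sample_id=sample_id,
        system=system,
        hits_recessive=hits.hits_recessive,
        hits_dominant=hits.hits_dominant,
        fraction_dominant=fraction,
        call=call,
        sex_label=label,
        status=status,
        reads_used=hits.reads_processed,
    )


def train_threshold(labeled: Sequence[tuple[float, CallClass]]) -> float:
    """Learn the dominant-hit fraction threshold from labeled samples.

    Exhaustive sweep over the midpoints of adjacent distinct sorted
    fractions, minimizing 0-1 loss of the rule "heterogametic iff
    fraction >= threshold"; among minimizers the maximum-margin midpoint
    (largest distance to the nearest training fraction) wins, with the
    smaller threshold breaking exact margin ties.  Both classes must be
    present.
    """
    fracs = [f for f, _ in labeled]
    classes = {c for _, c in labeled}
    if CallClass.HETEROGAMETIC not in classes or CallClass.HOMOGAMETIC not in classes:
        raise ValueError("training data must contain both classes")
    if not all(0.0 <= f <= 1.0 for f in fracs):
        raise ValueError("fractions must lie in [0, 1]")
    distinct = sorted(set(fracs))
    if len(distinct) == 1:
        logger.warning("all training fractions identical; degenerate threshold")
        return distinct[0]
    candidates = [(a + b) / 2 for a, b in zip(distinct, distinct[1:])]
    best = None
    for t in candidates:
        errors = sum(
            1
            for f, c in labeled
            if (f >= t) != (c is CallClass.HETEROGAMETIC)
        )
        margin = min(abs(f - t) for f in distinct)
        key = (errors, -margin, t)
        if best is None or key < best[0]:
            best = (key, t)
    return best[1]


DEFAULT_SCHEDULE = (
    100_000, 500_000, 1_000_000, 5_000_000, 10_000_000, 50_000_000, 100_000_000,
)


@dataclass
class MinReadsEstimate:
    """Result of the test-mode pre-pass.

    ``steps`` records (reads consumed, cumulative marker hits, mean hits
    per marker pair) at each schedule point actually reached; the
    recommendation is the smallest schedule value at or past the read
    where cumulative hits first exceeded ``min_total_hits``.
    """

    recommended: int | None
    sufficient: bool
    crossing_read: int | None
    steps: list[tuple[int, int, float]]
    total_reads: int
    total_hits: int


def estimate_min_reads(
    reads: Iterable[ReadRecord],
    index: MarkerIndex,
    params: PipelineParams | None = None,
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
) -> MinReadsEstimate:
    """Single pass over the stream, cumulative hit counts at schedule points."""
    if params is None:
        params = PipelineParams()
    schedule = list(schedule)
    if any(b <= a for a, b in zip(schedule, schedule[1:])) or not schedule:
        raise ValueError("schedule must be non-empty and strictly increasing")
    n_pairs = len(index.markers)
    stream = iter(reads)
    consumed = 0
    cumulative = 0
    crossing: int | None = None
    steps: list[tuple[int, int, float]] = []
    exhausted = False
    for point in schedule:
        want = point - consumed
        table = count_hits(stream, index, max_reads=want, params=params)
        consumed += table.reads_processed
        # crossing is resolved at schedule granularity: the first schedule
        # point whose cumulative hit count clears the floor
        if crossing is None and cumulative + table.total_hits > params.min_total_hits:
            crossing = consumed
        cumulative += table.total_hits
        steps.append((consumed, cumulative, cumulative / n_pairs))
        if table.reads_processed < want:
            exhausted = True
            break
    if crossing is None:
        return MinReadsEstimate(None, False, None, steps, consumed, cumulative)
    recommended = next((p for p in schedule if p >= crossing), crossing)
    return MinReadsEstimate(recommended, True, crossing, steps, consumed, cumulative)
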