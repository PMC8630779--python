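"""Per sample x chromosome chromothripsis calling.

A chromosome is called chromothriptic when either of two high-confidence
criteria holds:

1. at least six interleaved intrachromosomal SVs, seven contiguous copy
   number segments oscillating between two states, a passing fragment
   joins test, and a passing chromosomal enrichment *or* exponential
   breakpoint distribution test; or
2. at least three interleaved intrachromosomal SVs plus four or more
   interchromosomal SVs touching the chromosome, seven oscillating
   segments, and a passing fragment joins test.

"Interleaved" is operationalized as the largest connected component of
the crossing graph over intrachromosomal SV intervals, where two
intervals cross iff they overlap without nesting (a1 < b1 < a2 < b2).
The three statistical tests are principled stand-ins with configurable
thresholds:

* fragment joins — chi-square goodness of fit of the four join-type
  counts (deletion-like, duplication-like, head-to-head, tail-to-tail)
  against equal proportions; random joins give high p, so the test
  passes when p > 0.05;
* chromosomal enrichment — binomial upper tail of the chromosome's
  genome-wide breakpoint share given a rate proportional to chromosome
  length; passes (enriched) when p < 0.05;
* exponential breakpoints — Kolmogorov-Smirnov of inter-breakpoint gaps
  against an exponential with rate 1/mean gap; consistency with random
  shattering passes when p > 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_model import SvCall

__all__ = [
    "CnSegment",
    "ChromothripsisCall",
    "ChromothripsisThresholds",
    "JOIN_TYPES",
    "join_type",
    "count_interleaved",
    "max_oscillation_run",
    "fragment_joins_test",
    "chrom_enrichment_test",
    "exponential_breakpoint_test",
    "call_chromothripsis",
    "scan_cohort",
]

JOIN_TYPES = ("deletion_like", "duplication_like", "head_to_head", "tail_to_tail")

_JOIN_BY_STRANDS = {
    ("+", "-"): "deletion_like",
    ("-", "+"): "duplication_like",
    ("+", "+"): "head_to_head",
    ("-", "-"): "tail_to_tail",
}


@dataclass(frozen=True)
class CnSegment:
    """One copy-number segment (0-based half-open, integer copy state)."""

    chrom: str
    start: int
    end: int
    cn_state: int
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("empty CN segment")
        if self.cn_state < 0:
            raise ValueError("negative copy state")


@dataclass(frozen=True)
class ChromothripsisThresholds:
    min_interleaved_1: int = 6
    min_interleaved_2: int = 3
    min_inter_2: int = 4
    min_oscillation: int = 7
    joins_alpha: float = 0.05  # passes when p > alpha
    enrichment_alpha: float = 0.05  # passes when p < alpha
    exponential_alpha: float = 0.05  # passes when p > alpha


@dataclass(frozen=True)
class ChromothripsisCall:
    sample_id: str
    chrom: str
    n_intra: int
    n_intra_interleaved: int
    n_inter: int
    max_oscillation_run: int
    p_fragment_joins: float
    p_chrom_enrichment: float
    p_exponential: float
    criterion_met: int  # 1, 2 or 0 (none)
    missing_cn: bool = False


def join_type(sv: SvCall) -> str:
    """Join-type of an intrachromosomal SV from its canonical strand pair."""
    if not sv.is_intrachromosomal:
        raise ValueError("join type is defined for intrachromosomal SVs")
    return _JOIN_BY_STRANDS[(sv.strand1, sv.strand2)]


def count_interleaved(intervals: Sequence[tuple[int, int]]) -> int:
    """Size of the largest crossing-connected cluster of SV intervals.

    Two intervals cross iff a1 < b1 < a2 < b2 — they overlap but neither
    nests inside the other.  Union-find over all crossing pairs.
    """
    n = len(intervals)
    if n == 0:
        return 0
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    ivs = [(min(a, b), max(a, b)) for a, b in intervals]
    for i in range(n):
        a1, a2 = ivs[i]
        for j in range(i + 1, n):
            b1, b2 = ivs[j]
            if a1 < b1 < a2 < b2 or b1 < a1 < b2 < a2:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    sizes: dict[int, int] = {}
    for i in range(n):
        r = find(i)
        sizes[r] = sizes.get(r, 0) + 1
    return max(sizes.values())


def max_oscillation_run(segments: Sequence[CnSegment] | Sequence[int]) -> int:
    """Longest run of contiguous segments alternating between exactly two
    distinct copy states (a, b, a, b, ...)."""
    states = [s.cn_state if isinstance(s, CnSegment) else int(s) for s in segments]
    n = len(states)
    if n < 2:
        return n
    best = 1
    start = 0
    while start < n - 1:
        a, b = states[start], states[start + 1]
        if a == b:
            start += 1
            continue
        length = 2
        i = start + 2
        while i < n and states[i] == (a if (i - start) % 2 == 0 else b):
            length += 1
            i += 1
        best = max(best, length)
        start = i - 1
    return best


def fragment_joins_test(svs: Sequence[SvCall]) -> float:
    """Chi-square goodness-of-fit p of the four join-type counts against
    equal proportions; p near 1 means joins look random."""
    counts = np.zeros(4)
    idx = {t: i for i, t in enumerate(JOIN_TYPES)}
    for sv in svs:
        if sv.is_intrachromosomal:
            counts[idx[join_type(sv)]] += 1
    if counts.sum() == 0:
        return 1.0
    stat, p = stats.chisquare(counts)
    return float(p)


def chrom_enrichment_test(
    breakpoints_per_chrom: Mapping[str, int], chrom: str, genome: Mapping[str, int]
) -> float:
    """Binomial upper-tail p of the chromosome's breakpoint count given a
    genome-wide rate proportional to chromosome length; small p = enriched."""
    total = sum(breakpoints_per_chrom.values())
    glen = sum(genome.values())
    if total == 0 or len(genome) < 2 or glen == 0:
        return 1.0
    k = breakpoints_per_chrom.get(chrom, 0)
    frac = genome[chrom] / glen
    return float(stats.binom.sf(k - 1, total, frac))


def exponential_breakpoint_test(positions: Sequence[int]) -> float:
    """KS p of inter-breakpoint gaps vs an exponential fitted by its mean;
    high p = consistent with random (Poisson) shattering."""
    pos = np.sort(np.asarray(positions, dtype=float))
    gaps = np.diff(pos)
    gaps = gaps[gaps >= 0]
    if len(gaps) < 2 or gaps.mean() == 0:
        return 1.0
    res = stats.kstest(gaps, "expon", args=(0, gaps.mean()))
    return float(res.pvalue)


def call_chromothripsis(
    sample_id: str,
    chrom: str,
    svs: Sequence[SvCall],
    segments: Sequence[CnSegment],
    genome: Mapping[str, int],
    thresholds: ChromothripsisThresholds = ChromothripsisThresholds(),
) -> ChromothripsisCall:
    """Evaluate both high-confidence criteria for one sample x chromosome.

    ``svs`` is the sample's full SV list (breakpoint counts on other
    chromosomes feed the enrichment test); ``segments`` are the sample's CN
    segments on ``chrom``.  Missing CN data yields criterion_met = 0 with
    the ``missing_cn`` flag set.
    """
    svs = [sv for sv in svs if sv.sample_id == sample_id or not sample_id]
    on_chrom_intra = [
        sv for sv in svs if sv.is_intrachromosomal and sv.chrom1 == chrom
    ]
    inter = [
        sv for sv in svs
        if not sv.is_intrachromosomal and chrom in (sv.chrom1, sv.chrom2)
    ]
    intervals = [(sv.pos1, sv.pos2) for sv in on_chrom_intra]
    n_interleaved = count_interleaved(intervals)

    seg_sorted = sorted(
        (s for s in segments if s.chrom == chrom), key=lambda s: s.start
    )
    missing_cn = len(seg_sorted) == 0
    osc = max_oscillation_run(seg_sorted)

    p_joins = fragment_joins_test(on_chrom_intra)

    per_chrom: dict[str, int] = {c: 0 for c in genome}
    positions = []
    for sv in svs:
        for c, pos, _ in sv.breakpoints():
            if c in per_chrom:
                per_chrom[c] += 1
            if c == chrom:
                positions.append(pos)
    p_enrich = chrom_enrichment_test(per_chrom, chrom, genome)
    p_exp = exponential_breakpoint_test(positions) if len(positions) >= 3 else 1.0

    th = thresholds
    joins_pass = p_joins > th.joins_alpha
    dist_pass = (p_enrich < th.enrichment_alpha) or (p_exp > th.exponential_alpha)
    crit1 = (
        not missing_cn
        and n_interleaved >= th.min_interleaved_1
        and osc >= th.min_oscillation
        and joins_pass
        and dist_pass
    )
    crit2 = (
        not missing_cn
        and n_interleaved >= th.min_interleaved_2
        and len(inter) >= th.min_inter_2
        and osc >= th.min_oscillation
        and joins_pass
    )
    return ChromothripsisCall(
        sample_id=sample_id,
        chrom=chrom,
        n_intra=len(on_chrom_intra),
        n_intra_interleaved=n_interleaved,
        n_inter=len(inter),
        max_oscillation_run=osc,
        p_fragment_joins=p_joins,
        p_chrom_enrichment=p_enrich,
        p_exponential=p_exp,
        criterion_met=1 if crit1 else 2 if crit2 else 0,
        missing_cn=missing_cn,
    )


def scan_cohort(
    svs_by_sample: Mapping[str, Sequence[SvCall]],
    segments_by_sample: Mapping[str, Sequence[CnSegment]],
    genome: Mapping[str, int],
    thresholds: ChromothripsisThresholds = ChromothripsisThresholds(),
) -> pd.DataFrame:
    """Call chromothripsis for every (sample, chromosome) with >= 1 SV."""
    rows = []
    for sample in sorted(svs_by_sample):
        svs = list(svs_by_sample[sample])
        segs = list(segments_by_sample.get(sample, []))
        touched = sorted({c for sv in svs for c in (sv.chrom1, sv.chrom2) if c in genome})
        for chrom in touched:
            call = call_chromothripsis(sample, chrom, svs, segs, genome, thresholds)
            rows.append(call.__dict__)
    return pd.DataFrame(rows)


def read_cn_segments(path) -> list[CnSegment]:
    """Read CN segments from a TSV with columns sample, chrom, start, end, cn."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "chrom": str})
    return [
        CnSegment(r.chrom, int(r.start), int(r.end), int(r.cn), r.sample)
        for r in df.itertuples(index=False)
    ]


def write_cn_segments(segments: Iterable[CnSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tcn\n")
        for s in segments:
            fh.write(f"{s.sample_id}\t{s.chrom}\t{s.start}\t{s.end}\t{s.cn_state}\n")
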