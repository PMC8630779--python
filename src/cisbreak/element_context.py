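"""Mechanism annotation of SV-expression associations.

Three mechanisms are annotated for breakpoint-gene associations:

* TAD disruption — an SV whose two breakpoints do not fall within one
  and the same TAD interval;
* enhancer hijacking — the rearrangement juxtaposes an enhancer within
  an effective 1 Mb of the gene, closer than any native enhancer;
* translocated LINE/SINE retrotransposons — same construction with a
  20 kb window, matching the shorter reach of promoter-like effects.

The hijack geometry follows the derivative chromosome implied by the
breakpoint orientations ("retained side" convention, see
:mod:`cisbreak.io_model`): the breakpoint local to the gene must retain
the gene-containing side, and translocated sequence is searched along
the retained direction of the distal (mate) breakpoint, up to the class
window minus the local breakpoint's distance to the gene start, so the
effective gene-to-element distance respects the class window.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .breakpoint_matrix import DEFAULT_W
from .io_model import Cohort, GeneModel, IntervalTrack, SvCall
from .sv_expression import ScanConfig, normalized_expression

__all__ = [
    "ENHANCER_WINDOW",
    "RETRO_WINDOW",
    "TranslocationCall",
    "classify_tad_disruption",
    "enumerate_upstream_associations",
    "detect_translocated_element",
    "hijack_calls",
    "context_enrichment",
]

ENHANCER_WINDOW = DEFAULT_W  # 1 Mb
RETRO_WINDOW = 20_000  # 20 kb for LINE/SINE promoter-range effects


def classify_tad_disruption(sv: SvCall, tad_track: IntervalTrack) -> bool:
    """True unless both breakpoints fall inside the same TAD interval.

    Interchromosomal SVs are always TAD-disrupting.  A breakpoint in a gap
    between TADs shares no TAD with anything, so any SV touching a gap is
    TAD-disrupting as well.
    """
    if not sv.is_intrachromosomal:
        return True
    tads1 = set(tad_track.overlapping(sv.chrom1, sv.pos1))
    tads2 = set(tad_track.overlapping(sv.chrom2, sv.pos2))
    return not (tads1 & tads2)


def _is_upstream(gene: GeneModel, pos: int) -> bool:
    return pos < gene.start if gene.strand == "+" else pos >= gene.end


def _upstream_distance(gene: GeneModel, pos: int) -> int:
    return gene.tss - pos if gene.strand == "+" else pos - gene.tss


def enumerate_upstream_associations(
    cohort: Cohort,
    class_window: int,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """One association per (gene, sample): the breakpoint closest to the
    gene start among breakpoints strictly upstream within ``class_window``.

    Ties are broken by smaller genomic position then sv_id.  Each row keeps
    the local breakpoint's orientation and its mate locus (needed for
    derivative-chromosome walks) plus an ``altered`` label from normalized
    expression against the +/- ``sd_threshold`` SD rule.
    """
    z = normalized_expression(cohort.expression, config.pseudocount)
    rows = []
    bp_by_chrom: dict[str, list[tuple]] = {}
    for sv in cohort.svs:
        ends = sv.breakpoints()
        for i, (chrom, pos, strand) in enumerate(ends):
            mate = ends[1 - i]
            bp_by_chrom.setdefault(chrom, []).append(
                (pos, strand, mate, sv.sample_id, sv.sv_id, i + 1)
            )
    for recs in bp_by_chrom.values():
        recs.sort(key=lambda r: (r[0], r[4], r[5]))

    for gene in cohort.genes:
        recs = bp_by_chrom.get(gene.chrom)
        if not recs:
            continue
        best: dict[str, tuple] = {}
        for pos, strand, mate, sample, sv_id, end_idx in recs:
            if not _is_upstream(gene, pos):
                continue
            d = _upstream_distance(gene, pos)
            if not (0 <= d <= class_window):
                continue
            cur = best.get(sample)
            cand = (d, pos, sv_id, strand, mate, end_idx)
            if cur is None or cand[:3] < cur[:3]:
                best[sample] = cand
        for sample in sorted(best):
            d, pos, sv_id, strand, mate, end_idx = best[sample]
            zval = z.at[gene.gene_id, sample] if gene.gene_id in z.index else 0.0
            altered = (
                "overexpressed" if zval > config.sd_threshold
                else "underexpressed" if zval < -config.sd_threshold
                else "none"
            )
            rows.append((
                gene.gene_id, sample, sv_id, end_idx, gene.chrom, pos, strand,
                mate[0], mate[1], mate[2], d, altered,
            ))
    return pd.DataFrame(rows, columns=[
        "gene_id", "sample_id", "sv_id", "local_end", "chrom", "pos", "strand",
        "mate_chrom", "mate_pos", "mate_strand", "d_gene", "altered",
    ])


@dataclass(frozen=True)
class TranslocationCall:
    """Outcome of testing one upstream association for a translocated element."""

    gene_id: str
    sample_id: str
    sv_id: str
    element_class: str
    d_gene: int
    d_translocated: float  # d_gene + mate-walk distance; inf if no element
    d_native: float  # gene start to nearest same-class reference element; inf if none
    is_hijack: bool
    element: tuple[str, int, int] | None = None
    reason: str = ""


def _distance_to_elements(
    starts: np.ndarray, ends: np.ndarray, pos: int, direction: str, limit: float
) -> tuple[float, int]:
    """Nearest-edge distance from ``pos`` to an element along one direction.

    ``direction`` "left" searches elements on coordinates <= pos (retained
    side of a ``+`` breakpoint), "right" the mirror case.  An element
    containing ``pos`` has distance 0.  Returns (distance, element index);
    (inf, -1) when nothing lies within ``limit``.
    """
    if len(starts) == 0:
        return math.inf, -1
    contains = (starts <= pos) & (ends > pos)
    if direction == "left":
        cand = ends <= pos
        dist = np.where(contains, 0, np.where(cand, pos - ends, np.inf))
    else:
        cand = starts > pos
        dist = np.where(contains, 0, np.where(cand, starts - pos, np.inf))
    i = int(np.argmin(dist))
    return (float(dist[i]), i) if dist[i] <= limit else (math.inf, -1)


def detect_translocated_element(
    assoc: pd.Series,
    gene: GeneModel,
    track: IntervalTrack,
    element_class: str,
    class_window: int,
) -> TranslocationCall:
    """Test whether the rearrangement behind one upstream association
    translocates an element of ``element_class`` near the gene.

    Requires (i) the local breakpoint to retain the gene side, (ii) an
    element on the mate's retained side within ``class_window - d_gene``,
    and (iii) the effective distance ``d_gene + walk`` to beat both the
    class window and the nearest native same-class element upstream of the
    gene (strict inequality).
    """
    d_gene = int(assoc["d_gene"])
    base = dict(
        gene_id=assoc["gene_id"], sample_id=assoc["sample_id"], sv_id=assoc["sv_id"],
        element_class=element_class, d_gene=d_gene,
    )
    d_native = _native_distance(gene, track, element_class, class_window)

    # local breakpoint must retain the gene-containing side
    gene_side_right = gene.strand == "+"  # upstream bp sits left of a + gene
    required = "-" if gene_side_right else "+"
    if assoc["strand"] != required:
        return TranslocationCall(
            **base, d_translocated=math.inf, d_native=d_native, is_hijack=False,
            reason="local breakpoint does not retain the gene side",
        )

    budget = class_window - d_gene
    starts, ends = track.arrays(assoc["mate_chrom"], element_class)
    direction = "left" if assoc["mate_strand"] == "+" else "right"
    walk, idx = _distance_to_elements(starts, ends, int(assoc["mate_pos"]), direction, budget)
    if idx < 0:
        return TranslocationCall(
            **base, d_translocated=math.inf, d_native=d_native, is_hijack=False,
            reason="no element on the mate's retained side within the window",
        )
    d_tr = d_gene + walk
    element = (str(assoc["mate_chrom"]), int(starts[idx]), int(ends[idx]))
    if not d_tr < d_native:
        return TranslocationCall(
            **base, d_translocated=d_tr, d_native=d_native, is_hijack=False,
            element=element, reason="a native element is at least as close",
        )
    return TranslocationCall(
        **base, d_translocated=d_tr, d_native=d_native, is_hijack=True, element=element,
    )


def _native_distance(
    gene: GeneModel, track: IntervalTrack, element_class: str, class_window: int
) -> float:
    """Distance from the gene start to the nearest same-class element within
    ``class_window`` upstream in the reference; inf if none."""
    starts, ends = track.arrays(gene.chrom, element_class)
    direction = "left" if gene.strand == "+" else "right"
    d, idx = _distance_to_elements(starts, ends, gene.tss, direction, class_window)
    return d if idx >= 0 else math.inf


def hijack_calls(
    cohort: Cohort,
    associations: pd.DataFrame,
    track: IntervalTrack,
    element_class: str,
    class_window: int,
) -> pd.DataFrame:
    """Run :func:`detect_translocated_element` over an association table."""
    rows = []
    for _, assoc in associations.iterrows():
        call = detect_translocated_element(
            assoc, cohort.gene(assoc["gene_id"]), track, element_class, class_window
        )
        rows.append({
            "gene_id": call.gene_id, "sample_id": call.sample_id, "sv_id": call.sv_id,
            "element_class": call.element_class, "d_gene": call.d_gene,
            "d_translocated": call.d_translocated, "d_native": call.d_native,
            "is_hijack": call.is_hijack, "altered": assoc["altered"],
            "reason": call.reason,
        })
    return pd.DataFrame(rows, columns=[
        "gene_id", "sample_id", "sv_id", "element_class", "d_gene",
        "d_translocated", "d_native", "is_hijack", "altered", "reason",
    ])


def context_enrichment(
    context_flags: np.ndarray, altered_flags: np.ndarray
) -> tuple[float, float, np.ndarray, np.ndarray]:
    """Pearson chi-square of (altered-expression association vs not) x
    (context event vs not).

    Returns (statistic, p, observed 2x2, expected 2x2); expected counts
    preserve the table total.  Tables with a zero margin return p = 1.
    """
    context_flags = np.asarray(context_flags, dtype=bool)
    altered_flags = np.asarray(altered_flags, dtype=bool)
    if context_flags.shape != altered_flags.shape:
        raise ValueError("flag arrays must be aligned")
    obs = np.array([
        [(altered_flags & context_flags).sum(), (altered_flags & ~context_flags).sum()],
        [(~altered_flags & context_flags).sum(), (~altered_flags & ~context_flags).sum()],
    ], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        import warnings

        warnings.warn("zero-margin contingency table; enrichment undefined")
        return 0.0, 1.0, obs, obs
    stat, p, _, expected = stats.chi2_contingency(obs, correction=False)
    return float(stat), float(p), obs, expected
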