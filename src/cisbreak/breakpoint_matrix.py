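"""Gene x sample SV-breakpoint matrices.

Two constructions are provided, mirroring the region windows used for
SV-expression association scans:

* binary occupancy for fixed windows — within the gene body, 100 kb
  upstream or 100 kb downstream (strand-aware flanks): entry 1 iff any
  breakpoint of any SV falls in the window for that gene and sample;
* a distance-weighted 1 Mb matrix: for each gene and sample, the
  breakpoint nearest the gene start (TSS proxy) is scored
  ``s = log2(W + 1) - log2(d + 1)`` where ``d`` is its distance to the
  gene start (0 for breakpoints inside the gene body) and ``W`` the
  window half-width, so closer breakpoints get more weight and
  breakpoints beyond ``W`` score 0.

Both breakpoint ends of every SV (including interchromosomal mates)
count as independent breakpoints.  Ties for the nearest breakpoint are
broken by smaller genomic position, then lexicographic sv_id, so the
matrices are invariant to SV input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .io_model import Cohort, GeneModel

__all__ = ["WindowSpec", "BreakpointMatrix", "build_binary_matrix", "build_weighted_matrix", "carriers"]

GENE_BODY = "gene_body"
UPSTREAM = "upstream_flank"
DOWNSTREAM = "downstream_flank"
WEIGHTED = "weighted_1mb"

DEFAULT_FLANK = 100_000
DEFAULT_W = 1_000_000

FIXED_WINDOWS = (GENE_BODY, UPSTREAM, DOWNSTREAM)


@dataclass(frozen=True)
class WindowSpec:
    kind: str
    width: int = DEFAULT_FLANK

    def __post_init__(self) -> None:
        if self.kind not in FIXED_WINDOWS + (WEIGHTED,):
            raise ValueError(f"unknown window kind {self.kind!r}")
        if self.width <= 0:
            raise ValueError("window width must be positive")

    @staticmethod
    def gene_body() -> "WindowSpec":
        return WindowSpec(GENE_BODY, 1)

    @staticmethod
    def upstream(width: int = DEFAULT_FLANK) -> "WindowSpec":
        return WindowSpec(UPSTREAM, width)

    @staticmethod
    def downstream(width: int = DEFAULT_FLANK) -> "WindowSpec":
        return WindowSpec(DOWNSTREAM, width)

    @staticmethod
    def weighted(width: int = DEFAULT_W) -> "WindowSpec":
        return WindowSpec(WEIGHTED, width)

    def bounds(self, gene: GeneModel) -> tuple[int, int]:
        """Half-open genomic interval of a fixed window for ``gene``."""
        if self.kind == GENE_BODY:
            return gene.start, gene.end
        if self.kind == UPSTREAM:
            if gene.strand == "+":
                return max(0, gene.start - self.width), gene.start
            return gene.end, gene.end + self.width
        if self.kind == DOWNSTREAM:
            if gene.strand == "+":
                return gene.end, gene.end + self.width
            return max(0, gene.start - self.width), gene.start
        raise ValueError("weighted window has no fixed bounds")


@dataclass
class BreakpointMatrix:
    """Gene x sample breakpoint matrix plus the nearest-breakpoint table.

    ``entries`` is {0,1}-valued for fixed windows and in
    [0, log2(W+1)] for the weighted window.  ``nearest`` is a long table
    (gene_id, sample_id, sv_id, pos, d) with one row per nonzero entry.
    """

    window: WindowSpec
    entries: pd.DataFrame
    nearest: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["gene_id", "sample_id", "sv_id", "pos", "d"]))

    def export(self, path: str | Path) -> None:
        self.entries.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")

    def export_nearest(self, path: str | Path) -> None:
        self.nearest.to_csv(path, sep="\t", index=False)


def _breakpoint_arrays(cohort: Cohort) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (pos, sample_idx, bp_order) sorted by position.

    ``bp_order`` ranks breakpoints by (pos, sv_id, end) for deterministic
    tie-breaking; the rank indexes ``_bp_ids``.
    """
    sample_idx = {s: i for i, s in enumerate(cohort.samples)}
    recs = []
    for sv in cohort.svs:
        for chrom, pos, _strand in sv.breakpoints():
            recs.append((chrom, pos, sv.sv_id, sample_idx[sv.sample_id]))
    recs.sort()
    out: dict[str, list[list]] = {}
    ids = []
    for rank, (chrom, pos, sv_id, si) in enumerate(recs):
        out.setdefault(chrom, [[], [], []])
        out[chrom][0].append(pos)
        out[chrom][1].append(si)
        out[chrom][2].append(rank)
        ids.append(sv_id)
    arrays = {
        c: (np.array(v[0], dtype=np.int64), np.array(v[1], dtype=np.intp), np.array(v[2], dtype=np.intp))
        for c, v in out.items()
    }
    arrays["__ids__"] = ids  # type: ignore[assignment]
    return arrays


def build_binary_matrix(
    cohort: Cohort, window: WindowSpec, collect_nearest: bool = True
) -> BreakpointMatrix:
    """Binary occupancy matrix for a fixed window (gene body or flank).

    ``collect_nearest=False`` skips the per-entry nearest-breakpoint table
    (not needed for association scans on large simulated cohorts).
    """
    if window.kind == WEIGHTED:
        raise ValueError("use build_weighted_matrix for the weighted window")
    genes = cohort.genes
    samples = cohort.samples
    arrays = _breakpoint_arrays(cohort)
    ids = arrays.pop("__ids__")
    entries = np.zeros((len(genes), len(samples)), dtype=np.int8)
    nearest_rows = []
    for gi, gene in enumerate(genes):
        if gene.chrom not in arrays:
            continue
        pos, sidx, order = arrays[gene.chrom]
        lo, hi = window.bounds(gene)
        a, b = np.searchsorted(pos, [lo, hi])
        if a == b:
            continue
        entries[gi, sidx[a:b]] = 1
        if not collect_nearest:
            continue
        # nearest-to-gene-start breakpoint among window hits, per sample
        p, si, od = pos[a:b], sidx[a:b], order[a:b]
        d = np.abs(p - gene.tss)
        key = np.lexsort((od, p, d, si))
        _, first = np.unique(si[key], return_index=True)
        for k in key[first]:
            nearest_rows.append(
                (gene.gene_id, samples[int(si[k])], ids[od[k]], int(p[k]), int(d[k]))
            )
    frame = pd.DataFrame(entries, index=[g.gene_id for g in genes], columns=samples)
    nearest = pd.DataFrame(nearest_rows, columns=["gene_id", "sample_id", "sv_id", "pos", "d"])
    return BreakpointMatrix(window=window, entries=frame, nearest=nearest)


def weight_from_distance(d: np.ndarray | float, W: int = DEFAULT_W) -> np.ndarray | float:
    """Relative-distance weight ``s = log2(W+1) - log2(d+1)``, 0 beyond W."""
    d = np.asarray(d, dtype=float)
    s = np.where(d <= W, np.log2(W + 1.0) - np.log2(d + 1.0), 0.0)
    return s if s.shape else float(s)


def build_weighted_matrix(
    cohort: Cohort, W: int = DEFAULT_W, collect_nearest: bool = True
) -> BreakpointMatrix:
    """Distance-weighted matrix over a +/- ``W`` window around the gene start.

    For each gene and sample, ``d`` is the minimum over breakpoints on the
    gene's chromosome of the distance to the strand-aware gene start, with
    breakpoints inside the gene body assigned d = 0; the entry is
    ``log2(W+1) - log2(d+1)`` when d <= W and 0 otherwise.
    """
    if W <= 0:
        raise ValueError("W must be positive")
    genes = cohort.genes
    samples = cohort.samples
    arrays = _breakpoint_arrays(cohort)
    ids = arrays.pop("__ids__")
    entries = np.zeros((len(genes), len(samples)), dtype=float)
    nearest_rows = []
    smax = np.log2(W + 1.0)
    for gi, gene in enumerate(genes):
        if gene.chrom not in arrays:
            continue
        pos, sidx, order = arrays[gene.chrom]
        lo = min(gene.start, gene.tss - W)
        hi = max(gene.end, gene.tss + W + 1)
        a, b = np.searchsorted(pos, [max(0, lo), hi])
        if a == b:
            continue
        p = pos[a:b]
        d = np.abs(p - gene.tss)
        d[(p >= gene.start) & (p < gene.end)] = 0
        ok = d <= W
        if not ok.any():
            continue
        p, d, si, od = p[ok], d[ok], sidx[a:b][ok], order[a:b][ok]
        key = np.lexsort((od, p, d, si))
        _, first = np.unique(si[key], return_index=True)
        sel = key[first]
        entries[gi, si[sel]] = smax - np.log2(d[sel] + 1.0)
        if collect_nearest:
            for k in sel:
                nearest_rows.append(
                    (gene.gene_id, samples[int(si[k])], ids[od[k]], int(p[k]), int(d[k]))
                )
    frame = pd.DataFrame(entries, index=[g.gene_id for g in genes], columns=samples)
    nearest = pd.DataFrame(nearest_rows, columns=["gene_id", "sample_id", "sv_id", "pos", "d"])
    return BreakpointMatrix(window=WindowSpec.weighted(W), entries=frame, nearest=nearest)


def carriers(matrix: BreakpointMatrix, gene_id: str) -> set[str]:
    """Samples with a nonzero entry for ``gene_id`` (the >=3-tumor filter's
    support set)."""
    if gene_id not in matrix.entries.index:
        raise KeyError(f"gene {gene_id!r} not in matrix")
    row = matrix.entries.loc[gene_id]
    return set(row.index[row.values > 0])
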