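"""Domain types and readers/writers for SV-expression integration cohorts.

All genomic coordinates are internally 0-based, half-open (BED convention).
BEDPE start columns are taken as the breakpoint positions; RepeatMasker
``.out`` tables (1-based, inclusive) are converted on read.

Breakpoint strand semantics — "retained side"
---------------------------------------------
For a breakpoint at position ``pos`` with strand ``+``, the sequence at
coordinates <= ``pos`` is retained in the derivative chromosome; strand
``-`` retains the sequence at coordinates >= ``pos``.  This single
convention is what lets mate orientation define derivative-chromosome
walks in :mod:`cisbreak.element_context`.  SV callers differ in how they
encode orientation; convert on ingest if your caller uses another
convention.
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "GeneModel",
    "SvCall",
    "IntervalTrack",
    "Cohort",
    "read_gene_table",
    "read_bedpe",
    "write_bedpe",
    "read_bed_track",
    "read_repeatmasker",
    "read_matrix",
    "write_matrix",
    "read_annotations",
    "write_annotations",
    "assemble_cohort",
    "write_cohort",
    "read_cohort",
    "dedupe_svs",
    "filter_recurrent_breakpoints",
]

SV_CLASSES = ("DEL", "DUP", "INV", "INS", "TRA", "other")


@dataclass(frozen=True)
class GeneModel:
    """A gene locus; ``start < end`` 0-based half-open, ``strand`` in {+,-}."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError(f"{self.gene_id}: empty chromosome")
        if not (0 <= self.start < self.end):
            raise ValueError(f"{self.gene_id}: invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be + or -, got {self.strand!r}")

    @property
    def tss(self) -> int:
        """Strand-aware gene start (transcription start proxy)."""
        return self.start if self.strand == "+" else self.end


@dataclass(frozen=True)
class SvCall:
    """One somatic rearrangement: two breakpoint loci with orientations.

    Canonicalized on construction: intrachromosomal calls have
    ``pos1 <= pos2``; interchromosomal calls order ends by (chrom, pos)
    so A/B labelling carries no information.
    """

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    sv_class: str = "other"
    sv_id: str = ""

    def __post_init__(self) -> None:
        if self.pos1 < 0 or self.pos2 < 0:
            raise ValueError(f"{self.sv_id}: negative breakpoint position")
        for s in (self.strand1, self.strand2):
            if s not in ("+", "-"):
                raise ValueError(f"{self.sv_id}: strand must be + or -, got {s!r}")
        if (self.chrom1, self.pos1) > (self.chrom2, self.pos2):
            c1, p1, s1 = self.chrom1, self.pos1, self.strand1
            c2, p2, s2 = self.chrom2, self.pos2, self.strand2
            object.__setattr__(self, "chrom1", c2)
            object.__setattr__(self, "pos1", p2)
            object.__setattr__(self, "strand1", s2)
            object.__setattr__(self, "chrom2", c1)
            object.__setattr__(self, "pos2", p1)
            object.__setattr__(self, "strand2", s1)

    @property
    def is_intrachromosomal(self) -> bool:
        return self.chrom1 == self.chrom2

    def breakpoints(self) -> tuple[tuple[str, int, str], tuple[str, int, str]]:
        return (
            (self.chrom1, self.pos1, self.strand1),
            (self.chrom2, self.pos2, self.strand2),
        )

    def locus_key(self) -> tuple:
        """Breakpoint geometry without the sample — used for recurrence filtering."""
        return (
            self.chrom1, self.pos1, self.strand1,
            self.chrom2, self.pos2, self.strand2,
        )


class IntervalTrack:
    """A named set of genomic intervals with optional element classes.

    Intervals are (chrom, start, end, element_class) with 0-based half-open
    coordinates; queries are served from per-chromosome interval trees plus
    sorted coordinate arrays for vectorized distance math.
    """

    def __init__(self, name: str, intervals: Iterable[tuple]) -> None:
        self.name = name
        rows = []
        for iv in intervals:
            if len(iv) == 3:
                chrom, start, end = iv
                cls = "other"
            else:
                chrom, start, end, cls = iv[:4]
            if start >= end:
                raise ValueError(f"{name}: empty interval {chrom}:{start}-{end}")
            rows.append((str(chrom), int(start), int(end), str(cls)))
        rows.sort()
        self.intervals: list[tuple[str, int, int, str]] = rows
        self._trees: dict[str, IntervalTree] = {}
        self._arrays: dict[tuple[str, str | None], tuple[np.ndarray, np.ndarray]] = {}
        for chrom, start, end, cls in rows:
            self._trees.setdefault(chrom, IntervalTree()).addi(start, end, cls)

    def __len__(self) -> int:
        return len(self.intervals)

    def overlapping(self, chrom: str, pos: int) -> list[tuple[int, int, str]]:
        """Intervals containing the single base at ``pos``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.at(pos))

    def arrays(self, chrom: str, element_class: str | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Sorted (starts, ends) arrays on a chromosome, optionally one class."""
        key = (chrom, element_class)
        if key not in self._arrays:
            sel = [
                (s, e)
                for c, s, e, cls in self.intervals
                if c == chrom and (element_class is None or cls == element_class)
            ]
            starts = np.array([s for s, _ in sel], dtype=np.int64)
            ends = np.array([e for _, e in sel], dtype=np.int64)
            self._arrays[key] = (starts, ends)
        return self._arrays[key]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.intervals, columns=["chrom", "start", "end", "element_class"])


@dataclass
class Cohort:
    """Aligned multi-omic cohort: gene models, expression (TPM), integer CNA,
    somatic SV calls, sample annotations and annotation tracks."""

    genes: list[GeneModel]
    expression: pd.DataFrame  # genes x samples, TPM
    cna: pd.DataFrame  # genes x samples, integer copy state
    svs: list[SvCall]
    annotations: pd.DataFrame  # index sample_id
    tracks: dict[str, IntervalTrack] = field(default_factory=dict)
    cn_segments: list = field(default_factory=list)  # per-sample CnSegment rows

    def __post_init__(self) -> None:
        self._gene_index = {g.gene_id: g for g in self.genes}
        self._svs_by_sample: dict[str, list[SvCall]] | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.expression.columns)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.expression.index)

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_index[gene_id]

    def svs_by_sample(self) -> Mapping[str, list[SvCall]]:
        if self._svs_by_sample is None:
            by: dict[str, list[SvCall]] = {s: [] for s in self.samples}
            for sv in self.svs:
                by.setdefault(sv.sample_id, []).append(sv)
            self._svs_by_sample = by
        return self._svs_by_sample

    def breakpoint_table(self) -> pd.DataFrame:
        """Long table with one row per breakpoint end (two per SV)."""
        rows = []
        for sv in self.svs:
            for end_idx, (chrom, pos, strand) in enumerate(sv.breakpoints(), start=1):
                rows.append((sv.sample_id, sv.sv_id, end_idx, chrom, pos, strand))
        return pd.DataFrame(
            rows, columns=["sample_id", "sv_id", "end", "chrom", "pos", "strand"]
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _warn(msg: str) -> None:
    print(f"[cisbreak] {msg}", file=sys.stderr)


def read_gene_table(path: str | Path) -> list[GeneModel]:
    """Read genes from a 5-column TSV (gene_id, chrom, start, end, strand)
    or BED6 (chrom, start, end, name, score, strand)."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] >= 6 and df.iloc[0, 1].isdigit() and df.iloc[0, 2].isdigit():
        genes = [
            GeneModel(r[3], r[0], int(r[1]), int(r[2]), r[5])
            for r in df.itertuples(index=False)
        ]
    elif df.shape[1] >= 5:
        genes = [
            GeneModel(r[0], r[1], int(r[2]), int(r[3]), r[4])
            for r in df.itertuples(index=False)
        ]
    else:
        raise ValueError(f"{path}: expected 5-column gene TSV or BED6")
    seen: set[str] = set()
    for g in genes:
        if g.gene_id in seen:
            raise ValueError(f"duplicate gene_id {g.gene_id}")
        seen.add(g.gene_id)
    return genes


def read_bedpe(
    path: str | Path,
    sample_id: str | None = None,
    sample_column: int | None = None,
    class_column: int | None = None,
) -> list[SvCall]:
    """Read somatic SV calls from a >=10-column BEDPE.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name score strand1 strand2
    [extra...].  The ``start`` columns are taken as breakpoint positions.
    ``sample_id`` is taken from ``sample_column`` (0-based) if given, else the
    fixed ``sample_id``, else the file stem.  ``class_column`` likewise
    selects an optional SV-class column.  Malformed rows are rejected and
    reported with their row numbers; missing strand columns are a hard error
    because orientation is required downstream.
    """
    path = Path(path)
    default_sample = sample_id if sample_id is not None else path.stem
    calls: list[SvCall] = []
    bad_rows: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("chrom1\t"):
                continue
            fields = line.split("\t")
            if len(fields) < 10:
                raise ValueError(
                    f"{path}:{lineno}: BEDPE requires >=10 columns incl. strands, got {len(fields)}"
                )
            try:
                sm = fields[sample_column] if sample_column is not None else default_sample
                cls = fields[class_column] if class_column is not None else "other"
                calls.append(
                    SvCall(
                        sample_id=sm,
                        chrom1=fields[0],
                        pos1=int(fields[1]),
                        strand1=fields[8],
                        chrom2=fields[3],
                        pos2=int(fields[4]),
                        strand2=fields[9],
                        sv_class=cls if cls in SV_CLASSES else "other",
                        sv_id=fields[6],
                    )
                )
            except (ValueError, IndexError):
                bad_rows.append(lineno)
    if bad_rows:
        _warn(f"{path}: rejected {len(bad_rows)} malformed BEDPE row(s): {bad_rows}")
    return calls


def write_bedpe(svs: Sequence[SvCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "#chrom1\tstart1\tend1\tchrom2\tstart2\tend2\tname\tscore\t"
            "strand1\tstrand2\tsample_id\tsv_class\n"
        )
        for sv in svs:
            fh.write(
                f"{sv.chrom1}\t{sv.pos1}\t{sv.pos1 + 1}\t{sv.chrom2}\t{sv.pos2}\t"
                f"{sv.pos2 + 1}\t{sv.sv_id}\t.\t{sv.strand1}\t{sv.strand2}\t"
                f"{sv.sample_id}\t{sv.sv_class}\n"
            )


def read_bedpe_with_samples(path: str | Path) -> list[SvCall]:
    """Read the 12-column BEDPE dialect written by :func:`write_bedpe`."""
    return read_bedpe(path, sample_column=10, class_column=11)


def read_bed_track(path: str | Path, name: str, element_class: str | None = None) -> IntervalTrack:
    """Read BED3/BED6 intervals; BED column 4 (name) is used as the element
    class when ``element_class`` is not forced."""
    ivs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            cls = element_class if element_class is not None else (f[3] if len(f) > 3 else "other")
            ivs.append((f[0], int(f[1]), int(f[2]), cls))
    return IntervalTrack(name, ivs)


_REPEAT_CLASS_MAP = {"LINE": "LINE", "SINE": "SINE"}


def read_repeatmasker(path: str | Path, name: str = "repeats") -> IntervalTrack:
    """Read a RepeatMasker ``.out`` table keeping only LINE/SINE rows.

    The ``.out`` format is whitespace-delimited with a 3-line header; genomic
    begin/end are 1-based inclusive (columns 6-7) and are converted to
    0-based half-open.  Repeat class (column 11, e.g. ``LINE/L1``) is mapped
    by its prefix; rows of other classes are dropped and rows with an
    unparseable class column are skipped with a warning count.
    """
    ivs = []
    skipped = 0
    with open(path) as fh:
        for line in fh:
            f = line.split()
            if len(f) < 11 or not f[0].replace(".", "").isdigit():
                continue  # header / blank lines
            try:
                chrom, begin, end = f[4], int(f[5]), int(f[6])
                prefix = f[10].split("/")[0]
            except (ValueError, IndexError):
                skipped += 1
                continue
            cls = _REPEAT_CLASS_MAP.get(prefix)
            if cls is not None:
                ivs.append((chrom, begin - 1, end, cls))
    if skipped:
        _warn(f"{path}: skipped {skipped} row(s) with unparseable repeat class")
    return IntervalTrack(name, ivs)


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample TSV: first column gene_id, header row = sample_ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, float_format: str | None = None) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id", float_format=float_format)


def read_annotations(path: str | Path) -> pd.DataFrame:
    """Sample annotation TSV with columns sample_id, cancer_type,
    therapy_flags (semicolon-separated), os_months, os_event."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cancer_type": str})
    df = df.set_index("sample_id")
    df["therapy_flags"] = [
        frozenset(str(x).split(";")) - {"", "nan"} for x in df.get("therapy_flags", "")
    ]
    if (df["os_months"] < 0).any():
        raise ValueError("negative survival times in annotations")
    if df["cancer_type"].isna().any() or (df["cancer_type"] == "").any():
        raise ValueError("empty cancer_type in annotations")
    return df


def write_annotations(ann: pd.DataFrame, path: str | Path) -> None:
    out = ann.copy()
    out["therapy_flags"] = [";".join(sorted(t)) for t in out["therapy_flags"]]
    out.to_csv(path, sep="\t", index_label="sample_id")


def dedupe_svs(svs: Sequence[SvCall]) -> list[SvCall]:
    """Collapse duplicate rows (identical sample, loci, strands) to one call."""
    seen: set[tuple] = set()
    out = []
    for sv in sorted(svs, key=lambda s: (s.sample_id, s.locus_key(), s.sv_id)):
        key = (sv.sample_id, sv.locus_key())
        if key not in seen:
            seen.add(key)
            out.append(sv)
    return out


def filter_recurrent_breakpoints(svs: Sequence[SvCall]) -> list[SvCall]:
    """Drop SVs whose exact breakpoint geometry recurs in more than one
    sample — such identical-breakpoint events across tumors are far more
    likely germline variants or technical artifacts than independent somatic
    rearrangements.  Exact-match semantics (0 bp tolerance)."""
    counts: dict[tuple, set[str]] = {}
    for sv in svs:
        counts.setdefault(sv.locus_key(), set()).add(sv.sample_id)
    kept = [sv for sv in svs if len(counts[sv.locus_key()]) == 1]
    dropped = len(svs) - len(kept)
    if dropped:
        _warn(f"dropped {dropped} SV(s) with breakpoints recurring across samples")
    return kept


def assemble_cohort(
    genes: Sequence[GeneModel],
    expression: pd.DataFrame,
    cna: pd.DataFrame,
    svs: Sequence[SvCall],
    annotations: pd.DataFrame,
    tracks: Mapping[str, IntervalTrack] | None = None,
    drop_recurrent_breakpoints: bool = False,
    cn_segments: Sequence | None = None,
) -> Cohort:
    """Align all components into a :class:`Cohort`.

    Samples: intersection of expression, CNA and annotation sample sets
    (samples without SV calls are valid and keep zero calls).  Genes:
    intersection of the gene table with expression and CNA.  Ordering is
    lexicographic throughout, so assembly is invariant to input row order.
    Dropped IDs are reported to stderr; an empty sample intersection is a
    hard error.
    """
    if (expression.values < 0).any():
        raise ValueError("negative expression values (TPM expected)")
    if (cna.values < 0).any() or not np.issubdtype(cna.values.dtype, np.integer):
        if not np.allclose(cna.values, np.round(cna.values)) or (cna.values < 0).any():
            raise ValueError("CNA matrix must hold non-negative integer copy states")
        cna = cna.round().astype(int)

    samples = sorted(set(expression.columns) & set(cna.columns) & set(annotations.index))
    if not samples:
        raise ValueError("no samples shared between expression, CNA and annotations")
    dropped_samples = (
        (set(expression.columns) | set(cna.columns) | set(annotations.index)) - set(samples)
    )
    if dropped_samples:
        _warn(f"dropped {len(dropped_samples)} sample(s) absent from some component")

    by_id = {g.gene_id: g for g in genes}
    gene_ids = sorted(set(by_id) & set(expression.index) & set(cna.index))
    dropped_genes = (set(by_id) | set(expression.index) | set(cna.index)) - set(gene_ids)
    if dropped_genes:
        _warn(f"dropped {len(dropped_genes)} gene(s) absent from some component")

    svs = dedupe_svs(svs)
    if drop_recurrent_breakpoints:
        svs = filter_recurrent_breakpoints(svs)
    sv_samples = {sv.sample_id for sv in svs}
    if sv_samples - set(samples):
        _warn(f"dropped SV calls from {len(sv_samples - set(samples))} unannotated sample(s)")
    svs = [sv for sv in svs if sv.sample_id in set(samples)]
    no_sv = set(samples) - sv_samples
    if no_sv:
        _warn(f"{len(no_sv)} sample(s) carry no SV calls")

    return Cohort(
        genes=[by_id[g] for g in gene_ids],
        expression=expression.loc[gene_ids, samples],
        cna=cna.loc[gene_ids, samples],
        svs=svs,
        annotations=annotations.loc[samples],
        tracks=dict(tracks or {}),
        cn_segments=sorted(
            (s for s in (cn_segments or []) if s.sample_id in set(samples)),
            key=lambda s: (s.sample_id, s.chrom, s.start),
        ),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Serialize a cohort to a directory of plain-text files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genes.tsv", "w") as fh:
        for g in cohort.genes:
            fh.write(f"{g.gene_id}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")
    write_matrix(cohort.expression, outdir / "expression.tsv", float_format="%.10g")
    write_matrix(cohort.cna, outdir / "cna.tsv")
    write_bedpe(cohort.svs, outdir / "svs.bedpe")
    write_annotations(cohort.annotations, outdir / "annotations.tsv")
    for name, track in cohort.tracks.items():
        with open(outdir / f"track_{name}.bed", "w") as fh:
            for chrom, s, e, cls in track.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{cls}\n")
    if cohort.cn_segments:
        from .chromothripsis import write_cn_segments

        write_cn_segments(cohort.cn_segments, outdir / "cn_segments.tsv")


def read_cohort(indir: str | Path) -> Cohort:
    indir = Path(indir)
    genes = read_gene_table(indir / "genes.tsv")
    expression = read_matrix(indir / "expression.tsv")
    cna = read_matrix(indir / "cna.tsv")
    svs = read_bedpe_with_samples(indir / "svs.bedpe")
    annotations = read_annotations(indir / "annotations.tsv")
    tracks = {}
    for p in sorted(indir.glob("track_*.bed")):
        name = p.stem[len("track_"):]
        tracks[name] = read_bed_track(p, name)
    segs = []
    if (indir / "cn_segments.tsv").exists():
        from .chromothripsis import read_cn_segments

        segs = read_cn_segments(indir / "cn_segments.tsv")
    return assemble_cohort(genes, expression, cna, svs, annotations, tracks,
                           cn_segments=segs)
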