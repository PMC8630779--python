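"""Synthetic multi-cancer tumor cohort generator with planted ground truth.

The generator emulates the statistical structure the analysis modules
assume in an advanced, heavily pretreated pan-cancer cohort profiled by
WGS + RNA-seq:

* sparse somatic SVs per tumor drawn from a heavy-tailed negative
  binomial, clipped to the 3-813 per-sample range reported for such
  cohorts, with optional breakpoint clustering;
* copy gain co-occurring with breakpoints at a configured probability
  (the major confounder of naive SV-expression association);
* expression on the log2 scale: per-gene lognormal baseline +
  cancer-type shifts + a CNA dose effect + planted cis-effects in
  breakpoint carriers + Gaussian noise, back-transformed to TPM;
* overall survival from an exponential hazard with planted log-HRs and
  uniform censoring; therapy labels logistic in log2 SV burden;
* optional shattered chromosomes: clustered breakpoints, copy number
  oscillating between two states, crossing SV chains with random join
  orientations.

Randomness flows through named SeedSequence substreams in a fixed
order (genes, tracks, sv_counts, therapy, svs, cna, expression,
survival), so e.g. adding planted effects does not perturb SV
placement.  Identical seed + config reproduce the cohort bit for bit,
including file serialization.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chromothripsis import CnSegment
from .io_model import Cohort, GeneModel, IntervalTrack, SvCall, assemble_cohort

__all__ = ["PlantedCis", "SimConfig", "GroundTruth", "generate", "generate_null"]

_SUBSTREAMS = (
    "genes", "tracks", "sv_counts", "therapy", "svs", "cna", "expression", "survival",
)

_CLASS_STRANDS = {
    "DEL": [("+", "-")],
    "DUP": [("-", "+")],
    "INV": [("+", "+"), ("-", "-")],
}


@dataclass(frozen=True)
class PlantedCis:
    """A planted cis-regulatory effect: ``n_carriers`` samples receive a
    breakpoint within ``max_distance`` bp upstream of the gene (oriented so
    the derivative juxtaposes mate sequence with the gene) and an
    expression shift of ``effect_sd`` standard deviations."""

    gene_id: str
    effect_sd: float
    n_carriers: int
    max_distance: int = 50_000
    in_gene_body: bool = False
    subgroup: str | None = None  # restrict carriers to a therapy label


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a 300-tumor, 2,000-gene toy cohort on a 5 x 50 Mb
    genome with per-sample SV counts matching the 3-813 range of advanced
    pan-cancer cohorts; expression noise is 1.0 on the log2 scale so
    planted effect sizes in SD units are exact by construction.
    """

    seed: int
    n_samples: int = 300
    n_genes: int = 2000
    n_cancer_types: int = 4
    genome: tuple[tuple[str, int], ...] = tuple(
        (f"chr{i}", 50_000_000) for i in range(1, 6)
    )
    # SV model; the default mean matches the per-Mb breakpoint density of a
    # ~120-SV tumor on a 3 Gb genome, scaled to the 250 Mb toy genome, so
    # breakpoints are as sparse relative to gene windows as in real cohorts
    sv_rate_mean: float = 10.0
    sv_rate_dispersion: float = 1.2  # negative binomial size parameter
    sv_count_range: tuple[int, int] = (3, 813)
    cluster_weight: float = 0.3
    clusters_per_sample: int = 2
    cluster_sd: float = 2_000_000.0
    # CNA model
    p_copy_gain_given_breakpoint: float = 0.30
    gain_window: int = 1_000_000
    p_background_cna: float = 0.03
    p_deep_deletion: float = 0.001
    cna_dose_effect: float = 0.35  # log2 expression per copy above 2
    # expression model; baseline mean of 5 on the log2(TPM+1) scale keeps
    # genes away from the TPM = 0 floor so planted effect sizes in SD units
    # hold exactly rather than being attenuated by censoring
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.5
    cancer_type_shift_sd: float = 0.5
    noise_sd: float = 1.0
    # planted signals
    cis_effects: tuple[PlantedCis, ...] = ()
    burden_effects: tuple[tuple[str, float], ...] = ()  # (gene_id, slope per log2 SV)
    hazard_effects: tuple[tuple[str, float, str], ...] = ()  # (gene_id, log_hr, variable)
    chromothripsis_plan: tuple[tuple[int, str, int], ...] = ()  # (sample_idx, chrom, n_fragments)
    # survival + therapy
    median_survival_months: float = 24.0
    censor_horizon_months: float = 120.0
    therapy_labels: tuple[str, ...] = ("alkylating", "taxane", "topoisomerase_i", "immunotherapy")
    therapy_base_rate: float = 0.35
    therapy_burden_log_odds: float = 1.0
    # tracks
    tad_size: int = 1_000_000
    enhancers_per_mb: float = 3.0
    lines_per_mb: float = 8.0
    sines_per_mb: float = 8.0

    def validate(self) -> None:
        for pc in self.cis_effects:
            if not (0 < pc.n_carriers <= self.n_samples):
                raise ValueError(
                    f"planted effect for {pc.gene_id}: {pc.n_carriers} carriers "
                    f"infeasible with {self.n_samples} samples"
                )
        if self.sv_rate_mean < 0 or self.noise_sd < 0:
            raise ValueError("rates must be non-negative")


@dataclass
class GroundTruth:
    """Everything needed to recompute each planted signal."""

    cis_carriers: dict[str, list[str]] = field(default_factory=dict)
    cis_effects: dict[str, float] = field(default_factory=dict)
    burden_slopes: dict[str, float] = field(default_factory=dict)
    hazard_log_hr: dict[str, float] = field(default_factory=dict)
    chromothripsis: list[tuple[str, str]] = field(default_factory=list)
    sv_counts: dict[str, int] = field(default_factory=dict)
    therapy: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        gt = cls(**raw)
        gt.chromothripsis = [tuple(x) for x in gt.chromothripsis]
        return gt


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_SUBSTREAMS, children)}


def _make_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    chroms = [c for c, _ in cfg.genome]
    lengths = np.array([l for _, l in cfg.genome], dtype=float)
    probs = lengths / lengths.sum()
    assignment = rng.choice(len(chroms), size=cfg.n_genes, p=probs)
    sizes = np.clip(rng.lognormal(np.log(2e4), 0.8, cfg.n_genes), 2_000, 500_000).astype(int)
    starts = (rng.random(cfg.n_genes) * (lengths[assignment] - sizes - 2)).astype(int) + 1
    strands = np.where(rng.random(cfg.n_genes) < 0.5, "+", "-")
    width = len(str(cfg.n_genes))
    genes = [
        GeneModel(f"g{i:0{width}d}", chroms[assignment[i]], int(starts[i]),
                  int(starts[i] + sizes[i]), str(strands[i]))
        for i in range(cfg.n_genes)
    ]
    return genes


def _make_tracks(cfg: SimConfig, rng: np.random.Generator) -> dict[str, IntervalTrack]:
    tads = []
    for chrom, length in cfg.genome:
        for s in range(0, length, cfg.tad_size):
            tads.append((chrom, s, min(s + cfg.tad_size, length), "TAD"))
    elements = []
    for cls, density, size in (
        ("enhancer", cfg.enhancers_per_mb, 1_000),
        ("LINE", cfg.lines_per_mb, 3_000),
        ("SINE", cfg.sines_per_mb, 300),
    ):
        for chrom, length in cfg.genome:
            n = int(round(density * length / 1e6))
            starts = np.sort(rng.integers(0, length - size, size=n))
            elements.extend((chrom, int(s), int(s + size), cls) for s in starts)
    return {
        "tads": IntervalTrack("tads", tads),
        "enhancers": IntervalTrack(
            "enhancers", [e for e in elements if e[3] == "enhancer"]),
        "repeats": IntervalTrack(
            "repeats", [e for e in elements if e[3] in ("LINE", "SINE")]),
    }


def _sample_ids(cfg: SimConfig) -> list[str]:
    width = len(str(cfg.n_samples))
    return [f"s{i:0{width}d}" for i in range(cfg.n_samples)]


def _draw_background_svs(
    cfg: SimConfig, sample: str, n: int, rng: np.random.Generator
) -> list[SvCall]:
    chroms = [c for c, _ in cfg.genome]
    lengths = {c: l for c, l in cfg.genome}
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    centers = [
        (chroms[rng.integers(len(chroms))], float(rng.random()) * lengths[chroms[0]])
        for _ in range(cfg.clusters_per_sample)
    ]
    svs = []
    classes = rng.choice(["DEL", "DUP", "INV", "TRA"], size=n, p=[0.35, 0.25, 0.2, 0.2])
    for i in range(n):
        if rng.random() < cfg.cluster_weight and centers:
            chrom, mu = centers[rng.integers(len(centers))]
            pos1 = int(np.clip(rng.normal(mu, cfg.cluster_sd), 1, lengths[chrom] - 2))
        else:
            chrom = chroms[rng.choice(len(chroms), p=probs)]
            pos1 = int(rng.integers(1, lengths[chrom] - 1))
        cls = str(classes[i])
        sv_id = f"{sample}_sv{i:04d}"
        if cls == "TRA":
            others = [c for c in chroms if c != chrom]
            chrom2 = others[rng.integers(len(others))]
            pos2 = int(rng.integers(1, lengths[chrom2] - 1))
            s1, s2 = rng.choice(["+", "-"], size=2)
            svs.append(SvCall(sample, chrom, pos1, str(s1), chrom2, pos2, str(s2),
                              "TRA", sv_id))
        else:
            size = int(np.clip(rng.lognormal(np.log(1e5), 1.2), 50, lengths[chrom] / 2))
            pos2 = min(pos1 + size, lengths[chrom] - 1)
            strands = _CLASS_STRANDS[cls]
            s1, s2 = strands[rng.integers(len(strands))]
            svs.append(SvCall(sample, chrom, pos1, s1, chrom, pos2, s2, cls, sv_id))
    return svs


def _planted_sv(
    cfg: SimConfig, gene: GeneModel, sample: str, rng: np.random.Generator
) -> SvCall:
    """A translocation whose local breakpoint sits upstream of ``gene``
    (or inside it) with the gene side retained, so downstream mechanism
    analyses see a well-formed derivative chromosome."""
    lengths = {c: l for c, l in cfg.genome}
    pc = next(p for p in cfg.cis_effects if p.gene_id == gene.gene_id)
    if pc.in_gene_body:
        pos = int(rng.integers(gene.start, gene.end))
        local_strand = str(rng.choice(["+", "-"]))
    else:
        d = int(rng.integers(500, pc.max_distance))
        if gene.strand == "+":
            pos = max(1, gene.tss - d)
            local_strand = "-"  # retain coordinates >= pos, i.e. the gene side
        else:
            pos = min(lengths[gene.chrom] - 2, gene.tss + d)
            local_strand = "+"
    others = [c for c, _ in cfg.genome if c != gene.chrom]
    chrom2 = others[rng.integers(len(others))]
    pos2 = int(rng.integers(1, lengths[chrom2] - 1))
    mate_strand = str(rng.choice(["+", "-"]))
    return SvCall(sample, gene.chrom, pos, local_strand, chrom2, pos2, mate_strand,
                  "TRA", f"{sample}_planted_{gene.gene_id}")


def _shatter(
    cfg: SimConfig, sample: str, chrom: str, n_fragments: int, rng: np.random.Generator
) -> tuple[list[SvCall], list[CnSegment]]:
    """Shattered chromosome: clustered breakpoints, CN oscillating between
    two states, and a chain of mutually crossing intra SVs with uniform
    random join orientations."""
    length = dict(cfg.genome)[chrom]
    region_len = int(0.3 * length)
    region_start = int(rng.integers(0, length - region_len))
    bnds = np.sort(rng.choice(
        np.arange(region_start + 1, region_start + region_len), size=n_fragments + 1,
        replace=False))
    segments = []
    if region_start > 0:
        segments.append(CnSegment(chrom, 0, int(bnds[0]), 2, sample))
    for i in range(n_fragments):
        cn = 2 if i % 2 == 0 else 1
        segments.append(CnSegment(chrom, int(bnds[i]), int(bnds[i + 1]), cn, sample))
    if bnds[-1] < length:
        segments.append(CnSegment(chrom, int(bnds[-1]), length, 2, sample))
    svs = []
    # staircase of crossing intervals over the fragment boundaries:
    # (b[i], b[i+2]) crosses (b[i+1], b[i+3])
    for i in range(max(0, n_fragments - 1)):
        a = int(bnds[i]) + int(rng.integers(0, 50))
        b = int(bnds[i + 2 if i + 2 <= n_fragments else n_fragments])
        s1, s2 = rng.choice(["+", "-"], size=2)
        svs.append(SvCall(sample, chrom, a, str(s1), chrom, max(b, a + 1), str(s2),
                          "other", f"{sample}_ct_{chrom}_{i:03d}"))
    return svs, segments


def generate(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Generate a cohort plus the ground truth of every planted signal."""
    cfg = config
    cfg.validate()
    rngs = _rngs(cfg.seed)
    truth = GroundTruth()
    samples = _sample_ids(cfg)
    genes = _make_genes(cfg, rngs["genes"])
    gene_by_id = {g.gene_id: g for g in genes}
    planted_ids = (
        [pc.gene_id for pc in cfg.cis_effects]
        + [g for g, _ in cfg.burden_effects]
        + [g for g, _, _ in cfg.hazard_effects]
    )
    for gid in planted_ids:
        if gid not in gene_by_id:
            raise ValueError(f"unknown planted gene {gid}")
    tracks = _make_tracks(cfg, rngs["tracks"])

    # --- per-sample SV counts, then therapy labels logistic in burden ---
    rng = rngs["sv_counts"]
    lo, hi = cfg.sv_count_range
    p_nb = cfg.sv_rate_dispersion / (cfg.sv_rate_dispersion + cfg.sv_rate_mean)
    counts = np.clip(
        rng.negative_binomial(cfg.sv_rate_dispersion, p_nb, cfg.n_samples), lo, hi)
    truth.sv_counts = {s: int(c) for s, c in zip(samples, counts)}

    rng = rngs["therapy"]
    log_burden = np.log2(counts + 1.0)
    centered = log_burden - log_burden.mean()
    base_logit = np.log(cfg.therapy_base_rate / (1 - cfg.therapy_base_rate))
    therapy: dict[str, set[str]] = {s: set() for s in samples}
    for label in cfg.therapy_labels:
        logit = base_logit + cfg.therapy_burden_log_odds * centered
        draws = rng.random(cfg.n_samples) < 1.0 / (1.0 + np.exp(-logit))
        for s, hit in zip(samples, draws):
            if hit:
                therapy[s].add(label)
    truth.therapy = {s: sorted(v) for s, v in therapy.items()}

    # --- SV placement: background, planted cis breakpoints, shattering ---
    rng = rngs["svs"]
    svs: list[SvCall] = []
    for s, n in zip(samples, counts):
        svs.extend(_draw_background_svs(cfg, s, int(n), rng))
    for pc in cfg.cis_effects:
        pool = (
            [s for s in samples if pc.subgroup in therapy[s]]
            if pc.subgroup else list(samples)
        )
        if pc.n_carriers > len(pool):
            raise ValueError(
                f"{pc.gene_id}: {pc.n_carriers} carriers requested but only "
                f"{len(pool)} eligible samples"
            )
        carriers = sorted(rng.choice(pool, size=pc.n_carriers, replace=False))
        truth.cis_carriers[pc.gene_id] = [str(c) for c in carriers]
        truth.cis_effects[pc.gene_id] = pc.effect_sd
        for s in carriers:
            svs.append(_planted_sv(cfg, gene_by_id[pc.gene_id], str(s), rng))
    segments: list[CnSegment] = []
    shattered: dict[tuple[str, str], bool] = {}
    for sample_idx, chrom, n_frag in cfg.chromothripsis_plan:
        s = samples[sample_idx]
        ct_svs, ct_segs = _shatter(cfg, s, chrom, n_frag, rng)
        svs.extend(ct_svs)
        segments.extend(ct_segs)
        shattered[(s, chrom)] = True
        truth.chromothripsis.append((s, chrom))
    # flat CN-2 segments for every untouched sample x chromosome
    for s in samples:
        for chrom, length in cfg.genome:
            if not shattered.get((s, chrom)):
                segments.append(CnSegment(chrom, 0, length, 2, s))

    # --- CNA: baseline 2, gains near breakpoints, background events ---
    rng = rngs["cna"]
    cn = np.full((cfg.n_genes, cfg.n_samples), 2, dtype=int)
    gene_pos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, _ in cfg.genome:
        idx = np.array([i for i, g in enumerate(genes) if g.chrom == chrom])
        tss = np.array([genes[i].tss for i in idx])
        order = np.argsort(tss)
        gene_pos[chrom] = (tss[order], idx[order])
    sample_index = {s: j for j, s in enumerate(samples)}
    for sv in svs:
        for chrom, pos, _ in sv.breakpoints():
            if rng.random() >= cfg.p_copy_gain_given_breakpoint:
                continue
            tss, idx = gene_pos[chrom]
            a, b = np.searchsorted(tss, [pos - cfg.gain_window, pos + cfg.gain_window])
            if a < b:
                gain = 1 + rng.integers(0, 3)
                cn[idx[a:b], sample_index[sv.sample_id]] += int(gain)
    background = rng.random(cn.shape)
    cn[background < cfg.p_background_cna / 2] += 1
    cn[(background >= cfg.p_background_cna / 2) & (background < cfg.p_background_cna)] -= 1
    deep = rng.random(cn.shape) < cfg.p_deep_deletion
    cn[deep] = 0
    cn = np.maximum(cn, 0)
    # genes on shattered chromosomes inherit the oscillating segment states
    seg_by_sample_chrom: dict[tuple[str, str], list[CnSegment]] = {}
    for seg in segments:
        seg_by_sample_chrom.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (s, chrom), flag in shattered.items():
        segs = sorted(seg_by_sample_chrom[(s, chrom)], key=lambda x: x.start)
        starts = np.array([x.start for x in segs])
        states = np.array([x.cn_state for x in segs])
        tss, idx = gene_pos[chrom]
        which = np.clip(np.searchsorted(starts, tss, side="right") - 1, 0, len(segs) - 1)
        cn[idx, sample_index[s]] = states[which]

    # --- expression on the log2(TPM + 1) scale ---
    rng = rngs["expression"]
    baseline = rng.normal(cfg.baseline_log_mean, cfg.baseline_log_sd, cfg.n_genes)
    # planted signals model regulation of expressed genes; keep their
    # baselines off the TPM = 0 floor so effect sizes hold exactly
    gene_index_pre = {g.gene_id: i for i, g in enumerate(genes)}
    for gid in planted_ids:
        gi = gene_index_pre[gid]
        baseline[gi] = max(baseline[gi], cfg.baseline_log_mean)
    type_shift = rng.normal(0.0, cfg.cancer_type_shift_sd,
                            (cfg.n_genes, cfg.n_cancer_types))
    cancer_type = np.array([i % cfg.n_cancer_types for i in range(cfg.n_samples)])
    X = (
        baseline[:, None]
        + type_shift[:, cancer_type]
        + cfg.cna_dose_effect * (cn - 2)
        + rng.normal(0.0, cfg.noise_sd, (cfg.n_genes, cfg.n_samples))
    )
    gene_index = {g.gene_id: i for i, g in enumerate(genes)}
    for pc in cfg.cis_effects:
        gi = gene_index[pc.gene_id]
        for s in truth.cis_carriers[pc.gene_id]:
            X[gi, sample_index[s]] += pc.effect_sd * cfg.noise_sd
    for gene_id, slope in cfg.burden_effects:
        gi = gene_index[gene_id]
        X[gi, :] += slope * centered
        truth.burden_slopes[gene_id] = slope
    tpm = np.maximum(np.exp2(X) - 1.0, 0.0)

    # --- survival and annotations ---
    rng = rngs["survival"]
    lin = np.zeros(cfg.n_samples)
    for gene_id, log_hr, variable in cfg.hazard_effects:
        gi = gene_index[gene_id]
        x = X[gi, :]
        sd = x.std(ddof=1)
        z = (x - np.median(x)) / sd if sd > 0 else np.zeros_like(x)
        lin += log_hr * z
        truth.hazard_log_hr[gene_id] = log_hr
    base_rate = np.log(2.0) / cfg.median_survival_months
    t_event = rng.exponential(1.0 / (base_rate * np.exp(lin)))
    t_censor = rng.uniform(6.0, cfg.censor_horizon_months, cfg.n_samples)
    os_months = np.minimum(t_event, t_censor)
    os_event = (t_event <= t_censor).astype(int)

    annotations = pd.DataFrame({
        "cancer_type": [f"type{t}" for t in cancer_type],
        "therapy_flags": [frozenset(therapy[s]) for s in samples],
        "os_months": np.round(os_months, 3),
        "os_event": os_event,
    }, index=pd.Index(samples, name="sample_id"))

    expression = pd.DataFrame(np.round(tpm, 4), index=[g.gene_id for g in genes],
                              columns=samples)
    cna = pd.DataFrame(cn, index=[g.gene_id for g in genes], columns=samples)
    cohort = assemble_cohort(genes, expression, cna, svs, annotations, tracks,
                             cn_segments=segments)
    return cohort, truth


def generate_null(config: SimConfig) -> tuple[Cohort, GroundTruth]:
    """Same machinery with every planted-effect table emptied."""
    cfg = dataclasses.replace(
        config, cis_effects=(), burden_effects=(), hazard_effects=(),
        chromothripsis_plan=(),
    )
    return generate(cfg)
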