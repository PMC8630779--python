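"""Per-sample, per-pathway somatic alteration tabulation.

For each (sample, gene) the first matching class in a fixed precedence
order is recorded: SNV/indel, gene fusion, deep deletion (zero copies),
high-level amplification (>= 5 copies), then SV-mediated cis effect.
SVs are considered only for genes already significant (FDR < 10%) in an
SV-expression scan, and are role-specific: oncogenes need a breakpoint
within 1 Mb with expression > +0.4 SD from the sample median;
tumor suppressors need a within-gene breakpoint with expression
< -0.4 SD.  SNVs in oncogenes are restricted to a hotspot-residue
whitelist when one is provided; SNVs/indels in tumor suppressors are
restricted to inactivating classes.

The default catalog covers the cancer pathways commonly tabulated in
pan-cancer studies (RTK, HIPPO, chromatin modification, SWI/SNF,
PI3K/AKT/mTOR, MYC family, TERT, Wnt/beta-catenin, p53/Rb); gene roles
are package defaults and can be overridden in a user catalog (YAML).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .breakpoint_matrix import BreakpointMatrix
from .io_model import Cohort
from .sv_expression import ScanConfig, estimate_fdr, normalized_expression

__all__ = [
    "PathwayCatalog",
    "default_catalog",
    "ALTERATION_CLASSES",
    "INACTIVATING_CLASSES",
    "call_gene_alteration",
    "call_alterations",
    "tabulate_pathways",
]

ALTERATION_CLASSES = ("snv_indel", "fusion", "deep_deletion", "amplification", "sv_cis")
INACTIVATING_CLASSES = frozenset(
    {"nonsense", "nonstop", "frameshift", "frameshift_indel", "indel", "splice"}
)
DEEP_DELETION_COPIES = 0
AMPLIFICATION_COPIES = 5


@dataclass
class PathwayCatalog:
    """Pathway -> gene lists with per-gene roles and optional hotspot lists."""

    pathways: dict[str, list[str]]
    roles: dict[str, str] = field(default_factory=dict)  # oncogene / tumor_suppressor / other
    hotspots: dict[str, set[str]] = field(default_factory=dict)

    def role(self, gene: str) -> str:
        return self.roles.get(gene, "other")

    def genes(self) -> list[str]:
        return sorted({g for gs in self.pathways.values() for g in gs})

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PathwayCatalog":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(
            pathways={k: list(v) for k, v in raw["pathways"].items()},
            roles=dict(raw.get("roles", {})),
            hotspots={k: set(v) for k, v in raw.get("hotspots", {}).items()},
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump({
            "pathways": {k: list(v) for k, v in self.pathways.items()},
            "roles": dict(self.roles),
            "hotspots": {k: sorted(v) for k, v in self.hotspots.items()},
        }, sort_keys=True))


_ONC = "oncogene"
_TSG = "tumor_suppressor"

_DEFAULT_PATHWAYS: dict[str, list[str]] = {
    "RTK": ["BRAF", "EGFR", "ERBB2", "ERBB3", "ERBB4", "FGFR1", "FGFR2", "FGFR3",
            "FGFR4", "HRAS", "KIT", "KRAS", "MET", "NF1", "NRAS"],
    "HIPPO": ["NF2", "SAV1", "WWC1"],
    "chromatin_modification": [
        "CREBBP", "EHMT1", "EHMT2", "EP300", "EZH1", "EZH2", "KAT2A", "KAT2B",
        "KDM1A", "KDM1B", "KDM4A", "KDM4B", "KDM5A", "KDM5B", "KDM5C", "KDM6A",
        "KDM6B", "KMT2A", "KMT2B", "KMT2C", "KMT2D", "KMT2E", "NSD1", "SETD2",
        "SMYD4", "SRCAP"],
    "SWI_SNF": ["ACTB", "ACTL6A", "ACTL6B", "ARID1A", "ARID1B", "ARID2", "BCL11A",
                "BCL11B", "BCL6", "BCL6B", "BRD7", "BRD9", "DPF1", "DPF2", "DPF3",
                "PBRM1", "PHF10", "SMARCA2", "SMARCA4", "SMARCB1", "SMARCC1",
                "SMARCC2", "SMARCD1", "SMARCD2", "SMARCD3", "SMARCE1"],
    "mTOR": ["AKT1", "AKT2", "AKT3", "MTOR", "PIK3CA", "PIK3R1", "PTEN", "RHEB",
             "STK11", "TSC1", "TSC2", "IDH1", "IDH2", "VHL"],
    "MYC_family": ["MYC", "MYCN", "MYB"],
    "TERT": ["TERT"],
    "Wnt_beta_catenin": ["APC", "AXIN1", "CTNNB1", "FGF19", "NCOR1"],
    "p53_Rb": ["ATM", "CCND1", "CCNE1", "CDK4", "CDKN1A", "CDKN2A", "E2F2", "E2F3",
               "FBXW7", "MDM2", "RB1", "TP53"],
}

_DEFAULT_ROLES: dict[str, str] = {
    # oncogenes
    **{g: _ONC for g in [
        "BRAF", "EGFR", "ERBB2", "ERBB3", "ERBB4", "FGFR1", "FGFR2", "FGFR3",
        "FGFR4", "HRAS", "KIT", "KRAS", "MET", "NRAS", "EZH2", "AKT1", "AKT2",
        "AKT3", "MTOR", "PIK3CA", "RHEB", "IDH1", "IDH2", "MYC", "MYCN", "MYB",
        "TERT", "CTNNB1", "FGF19", "CCND1", "CCNE1", "CDK4", "E2F2", "E2F3",
        "MDM2"]},
    # tumor suppressors
    **{g: _TSG for g in [
        "NF1", "NF2", "SAV1", "WWC1", "CREBBP", "EP300", "KDM5C", "KDM6A",
        "KMT2A", "KMT2B", "KMT2C", "KMT2D", "KMT2E", "NSD1", "SETD2",
        "ARID1A", "ARID1B", "ARID2", "PBRM1", "SMARCA2", "SMARCA4", "SMARCB1",
        "PIK3R1", "PTEN", "STK11", "TSC1", "TSC2", "VHL", "APC", "AXIN1",
        "NCOR1", "ATM", "CDKN1A", "CDKN2A", "FBXW7", "RB1", "TP53"]},
}


def default_catalog() -> PathwayCatalog:
    return PathwayCatalog(
        pathways={k: list(v) for k, v in _DEFAULT_PATHWAYS.items()},
        roles=dict(_DEFAULT_ROLES),
    )


def call_gene_alteration(
    sample_id: str,
    gene: str,
    role: str,
    snv_rows: pd.DataFrame,
    has_fusion: bool,
    copies: int | None,
    sv_eligible: bool,
    bp_in_1mb: bool,
    bp_in_body: bool,
    expr_z: float,
    hotspots: set[str] | None = None,
    sd_threshold: float = 0.4,
) -> str | None:
    """First alteration class (precedence order) supported for one
    sample x gene, or None.  ``snv_rows`` are the sample/gene's SNV/indel
    rows with columns ``class`` and ``protein_change``."""
    if len(snv_rows):
        if role == _ONC:
            if hotspots:
                ok = snv_rows["protein_change"].isin(hotspots).any()
            else:
                ok = True
        elif role == _TSG:
            ok = snv_rows["class"].isin(INACTIVATING_CLASSES).any()
        else:
            ok = True
        if ok:
            return "snv_indel"
    if has_fusion:
        return "fusion"
    if copies is not None:
        if copies == DEEP_DELETION_COPIES:
            return "deep_deletion"
        if copies >= AMPLIFICATION_COPIES:
            return "amplification"
    if sv_eligible:
        if role == _ONC and bp_in_1mb and expr_z > sd_threshold:
            return "sv_cis"
        if role == _TSG and bp_in_body and expr_z < -sd_threshold:
            return "sv_cis"
    return None


def call_alterations(
    cohort: Cohort,
    catalog: PathwayCatalog,
    snv_table: pd.DataFrame | None,
    fusion_table: pd.DataFrame | None,
    sv_significant_genes: Iterable[str],
    body_matrix: BreakpointMatrix,
    weighted_matrix: BreakpointMatrix,
    config: ScanConfig = ScanConfig(),
) -> pd.DataFrame:
    """Tabulate alterations for every catalog gene across the cohort.

    ``snv_table``/``fusion_table`` are external input tables with columns
    (sample, gene, class, protein_change) and (sample, gene);
    ``sv_significant_genes`` is the FDR < 10% SV-expression gene set (any
    window) gating the SV rule.  Genes with role "other" are skipped with a
    warning when only the SV rule could apply.
    """
    import warnings

    snv_table = snv_table if snv_table is not None else pd.DataFrame(
        columns=["sample", "gene", "class", "protein_change"])
    fusion_table = fusion_table if fusion_table is not None else pd.DataFrame(
        columns=["sample", "gene"])
    sv_ok = set(sv_significant_genes)
    z = normalized_expression(cohort.expression, config.pseudocount)
    rows = []
    skipped_roleless = 0
    for pathway, genes in sorted(catalog.pathways.items()):
        for gene in genes:
            role = catalog.role(gene)
            in_cohort = gene in cohort.expression.index
            for sample in cohort.samples:
                srows = snv_table[(snv_table["sample"] == sample)
                                  & (snv_table["gene"] == gene)]
                fus = bool(((fusion_table["sample"] == sample)
                            & (fusion_table["gene"] == gene)).any())
                copies = (int(cohort.cna.at[gene, sample])
                          if gene in cohort.cna.index else None)
                bp1mb = bool(gene in weighted_matrix.entries.index
                             and weighted_matrix.entries.at[gene, sample] > 0)
                bpbody = bool(gene in body_matrix.entries.index
                              and body_matrix.entries.at[gene, sample] > 0)
                zval = float(z.at[gene, sample]) if in_cohort else 0.0
                if role == "other" and gene in sv_ok and (bp1mb or bpbody):
                    skipped_roleless += 1
                cls = call_gene_alteration(
                    sample, gene, role, srows, fus, copies, gene in sv_ok,
                    bp1mb, bpbody, zval, catalog.hotspots.get(gene),
                    config.sd_threshold,
                )
                if cls is not None:
                    rows.append((sample, pathway, gene, cls))
    if skipped_roleless:
        warnings.warn(
            f"{skipped_roleless} candidate SV event(s) skipped for genes without "
            "an oncogene/tumor-suppressor role"
        )
    return pd.DataFrame(rows, columns=["sample_id", "pathway", "gene", "alteration_class"])


def tabulate_pathways(
    cohort: Cohort, catalog: PathwayCatalog, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample x pathway alteration matrix plus per-cancer-type enrichment.

    A pathway is altered in a sample iff >= 1 member gene carries any
    alteration.  Enrichment per (pathway, cancer type): one-sided Fisher of
    the altered fraction within the type versus the rest of the cohort,
    FDR-corrected across all (pathway, type) pairs.
    """
    samples = cohort.samples
    pathways = sorted(catalog.pathways)
    mat = pd.DataFrame(0, index=samples, columns=pathways, dtype=int)
    for _, r in calls.iterrows():
        mat.at[r["sample_id"], r["pathway"]] = 1
    types = cohort.annotations["cancer_type"]
    rows = []
    for pw in pathways:
        altered = mat[pw].to_numpy(dtype=bool)
        for ct in sorted(types.unique()):
            in_ct = (types == ct).to_numpy()
            a = int((altered & in_ct).sum())
            b = int((~altered & in_ct).sum())
            c = int((altered & ~in_ct).sum())
            d = int((~altered & ~in_ct).sum())
            _, p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
            rows.append((pw, ct, a, a + b, p))
    enr = pd.DataFrame(rows, columns=["pathway", "cancer_type", "n_altered",
                                      "n_type", "p"])
    enr["q"] = estimate_fdr(enr["p"]) if len(enr) else []
    return mat, enr
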