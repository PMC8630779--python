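"""SV-burden expression correlates, survival scans and signature scoring.

Burden correlates regress log2(TPM + 1) on the per-tumor log2(SV count
+ 1), with gene-level CNA and cancer type as covariates, reusing the
vectorized OLS engine of :mod:`cisbreak.sv_expression`.

Survival scans fit, per gene, a Cox proportional-hazards model
stratified by cancer type (Efron tie handling) on either (i) the
weighted breakpoint score — the log2-transformed relative distance
construct, with 0 for tumors lacking a nearby breakpoint — with
gene-level CNA as covariate, or (ii) the gene's log2 expression.
Effect sizes come from a Newton fit of the stratified partial
likelihood; the per-gene p-value is a permutation-calibrated score
test (see :mod:`cisbreak._cox` for why the usual Wald p is
anticonservative for sparse, skewed gene-level covariates).
A survival signature is the set of genes with positive SV-expression
association whose breakpoint pattern *and* expression both predict
worse survival; per-sample signature scores are means over the
signature genes of expression normalized as SDs from the median.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from ._cox import cox_fit, cox_score_permutation_test

from .breakpoint_matrix import BreakpointMatrix
from .io_model import Cohort
from .sv_expression import ScanConfig, _scan_ols, estimate_fdr, expressed_gene_mask

__all__ = [
    "compute_burden",
    "burden_expression_scan",
    "apply_followup_cap",
    "cox_gene_scan",
    "cox_breakpoint_scan",
    "cox_expression_scan",
    "build_survival_signature",
    "score_signature",
    "tertile_groups",
    "tertile_logrank",
    "km_table",
]


def compute_burden(cohort: Cohort) -> pd.DataFrame:
    """Per-sample SV event counts (deduplicated) and log2(n_sv + 1)."""
    counts = pd.Series(0, index=pd.Index(cohort.samples, name="sample_id"), dtype=int)
    for sv in cohort.svs:
        counts[sv.sample_id] += 1
    return pd.DataFrame({"n_sv": counts, "log_burden": np.log2(counts + 1.0)})


def burden_expression_scan(
    cohort: Cohort, config: ScanConfig = ScanConfig()
) -> pd.DataFrame:
    """Per-gene OLS of log2 expression on log2 SV burden + CNA + cancer type."""
    burden = compute_burden(cohort)["log_burden"].to_numpy()
    expr = cohort.expression
    keep = expressed_gene_mask(expr, config)
    genes = [g for g in expr.index if keep[g]]
    Y = np.log2(expr.loc[genes].to_numpy(dtype=float) + config.pseudocount)
    B = np.tile(burden, (len(genes), 1))
    C = cohort.cna.loc[genes].to_numpy(dtype=float) if config.use_cna else None
    strata = (
        cohort.annotations["cancer_type"].tolist() if config.use_cancer_type else None
    )
    beta, t, p, dg = _scan_ols(Y, B, C, strata)
    res = pd.DataFrame({
        "gene_id": genes, "slope": beta, "t": t, "p": p,
        "q": estimate_fdr(p),
        "direction": np.where(beta >= 0, "pos", "neg"),
        "degenerate": dg,
    })
    return res.sort_values(["q", "gene_id"], kind="mergesort").reset_index(drop=True)


def apply_followup_cap(
    times: Sequence[float], events: Sequence[int], cap_months: float
) -> tuple[np.ndarray, np.ndarray]:
    """Censor observations beyond ``cap_months`` at the cap (idempotent)."""
    if cap_months <= 0:
        raise ValueError("cap must be positive")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if (t < 0).any():
        raise ValueError("negative survival times")
    over = t > cap_months
    return np.where(over, cap_months, t), np.where(over, 0, e)


def cox_gene_scan(
    cohort: Cohort,
    values: pd.DataFrame,
    variable: str,
    covariates: pd.DataFrame | None = None,
    min_events: int = 10,
    cap_months: float | None = None,
    seed: int = 0,
    n_perm: int = 1999,
) -> pd.DataFrame:
    """Stratified Cox scan: one fit per gene row of ``values``.

    The per-gene covariate of interest is the gene's row of ``values``;
    ``covariates`` (e.g. the CNA matrix) contributes one extra per-gene
    column.  Strata are cancer types; ties use the Efron approximation.
    The coefficient and its SE come from the full Newton fit; the p-value
    is the permutation score test (``n_perm`` within-stratum shuffles,
    deterministic given ``seed``).  Returns gene_id, variable, coef, se,
    hr_direction, p, n_events.  Scans with fewer than ``min_events``
    events return an empty table with a warning.
    """
    ann = cohort.annotations
    times = ann["os_months"].to_numpy(dtype=float)
    events = ann["os_event"].to_numpy(dtype=int)
    if cap_months is not None:
        times, events = apply_followup_cap(times, events, cap_months)
    if events.sum() < min_events:
        warnings.warn(
            f"only {events.sum()} events (< {min_events}); survival scan skipped"
        )
        return pd.DataFrame(columns=[
            "gene_id", "variable", "coef", "se", "hr_direction", "p", "n_events"])
    times = np.maximum(times, 1e-6)
    strata = ann["cancer_type"].to_numpy()
    n_events = int(events.sum())
    rows = []
    child_seeds = np.random.SeedSequence(seed).spawn(max(len(values.index), 1))
    for k, gene_id in enumerate(values.index):
        x = values.loc[gene_id, ann.index].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            rows.append((gene_id, variable, 0.0, np.inf, 0, 1.0, n_events))
            continue
        nuisance = (
            covariates.loc[gene_id, ann.index].to_numpy(dtype=float)
            if covariates is not None else None
        )
        rng = np.random.default_rng(child_seeds[k])
        _, p = cox_score_permutation_test(times, events, x, nuisance, strata,
                                          n_perm=n_perm, rng=rng)
        X = x[:, None] if nuisance is None else np.column_stack([x, nuisance])
        fit = cox_fit(times, events, X, strata)
        coef = float(fit.beta[0]) if fit.converged else 0.0
        se = float(np.sqrt(fit.cov[0, 0])) if fit.converged else np.inf
        rows.append((gene_id, variable, coef, se, int(np.sign(coef)), p, n_events))
    return pd.DataFrame(rows, columns=[
        "gene_id", "variable", "coef", "se", "hr_direction", "p", "n_events"])


def cox_breakpoint_scan(
    cohort: Cohort,
    weighted_matrix: BreakpointMatrix,
    config: ScanConfig = ScanConfig(),
    min_events: int = 10,
    cap_months: float | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Survival vs the weighted breakpoint score, correcting for CNA;
    samples without a nearby breakpoint carry score 0 rather than being
    dropped."""
    values = weighted_matrix.entries
    if genes is not None:
        values = values.loc[[g for g in genes if g in values.index]]
    # only genes with at least one scored breakpoint are informative
    values = values.loc[(values.to_numpy() > 0).any(axis=1)]
    cov = cohort.cna.reindex(index=values.index).fillna(0) if config.use_cna else None
    return cox_gene_scan(cohort, values, "breakpoint_distance", cov,
                         min_events, cap_months)


def cox_expression_scan(
    cohort: Cohort,
    config: ScanConfig = ScanConfig(),
    min_events: int = 10,
    cap_months: float | None = None,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Survival vs log2 gene expression, stratified by cancer type."""
    expr = cohort.expression
    if genes is None:
        keep = expressed_gene_mask(expr, config)
        genes = [g for g in expr.index if keep[g]]
    values = np.log2(expr.loc[list(genes)] + config.pseudocount)
    return cox_gene_scan(cohort, values, "expression", None, min_events, cap_months)


def build_survival_signature(
    assoc_results: pd.DataFrame,
    cox_bp: pd.DataFrame,
    cox_expr: pd.DataFrame,
    p_cut: float = 0.05,
) -> tuple[list[str], float]:
    """Signature gene set and the significance of its construction.

    Signature = genes with a positive SV-expression association (p < cut)
    that also predict worse survival by both breakpoint pattern and
    expression (positive Cox coefficient, p < cut in each scan).  The
    returned Fisher p (one-sided) tests whether the positive-association
    set overlaps the poor-prognosis set more than chance, over the common
    gene universe.
    """
    universe = (
        set(assoc_results["gene_id"]) & set(cox_bp["gene_id"]) & set(cox_expr["gene_id"])
    )
    if not universe:
        raise ValueError("empty common gene universe")
    pos_assoc = {
        g for g, b, p in zip(assoc_results["gene_id"], assoc_results["beta"],
                             assoc_results["p"])
        if g in universe and b > 0 and p < p_cut
    }
    worse_bp = {
        g for g, c, p in zip(cox_bp["gene_id"], cox_bp["coef"], cox_bp["p"])
        if g in universe and c > 0 and p < p_cut
    }
    worse_expr = {
        g for g, c, p in zip(cox_expr["gene_id"], cox_expr["coef"], cox_expr["p"])
        if g in universe and c > 0 and p < p_cut
    }
    poor_prognosis = worse_bp & worse_expr
    signature = sorted(pos_assoc & poor_prognosis)
    a = len(signature)
    b = len(pos_assoc) - a
    c = len(poor_prognosis) - a
    d = len(universe) - a - b - c
    _, fisher_p = stats.fisher_exact([[a, b], [c, d]], alternative="greater")
    return signature, float(fisher_p)


def score_signature(
    expression: pd.DataFrame, gene_set: Iterable[str], pseudocount: float = 1.0
) -> pd.Series:
    """Per-sample signature score: mean over signature genes of
    (x - median_g) / SD_g on log2 expression.  Genes absent from the
    matrix or with zero SD are excluded with a warning."""
    genes = [g for g in gene_set if g in expression.index]
    if not genes:
        raise ValueError("no signature genes present in the expression matrix")
    x = np.log2(expression.loc[genes] + pseudocount)
    med = x.median(axis=1)
    sd = x.std(axis=1, ddof=1)
    usable = sd > 0
    if (~usable).any():
        warnings.warn(f"excluded {(~usable).sum()} zero-SD signature gene(s)")
    x = x.loc[usable.index[usable]]
    z = x.sub(med[usable], axis=0).div(sd[usable], axis=0)
    return z.mean(axis=0).rename("signature_score")


def tertile_groups(scores: pd.Series) -> pd.Series:
    """Low/intermediate/high groups by empirical 1/3 quantiles; scores tied
    with a boundary fall in the lower group."""
    q1, q2 = scores.quantile([1 / 3, 2 / 3])
    return pd.Series(
        np.where(scores <= q1, "low", np.where(scores <= q2, "intermediate", "high")),
        index=scores.index, name="tertile",
    )


def tertile_logrank(
    scores: pd.Series, times: Sequence[float], events: Sequence[int]
) -> tuple[float, pd.Series]:
    """Log-rank test across score tertiles; returns (p, group labels)."""
    groups = tertile_groups(scores)
    res = multivariate_logrank_test(np.asarray(times, dtype=float), groups.to_numpy(),
                                    np.asarray(events, dtype=int))
    return float(res.p_value), groups


def km_table(
    times: Sequence[float], events: Sequence[int], groups: Sequence[str]
) -> pd.DataFrame:
    """Kaplan-Meier event table per group: time, at-risk and observed events."""
    from lifelines import KaplanMeierFitter

    df = pd.DataFrame({"T": times, "E": events, "group": list(groups)})
    out = []
    for name, sub in df.groupby("group"):
        km = KaplanMeierFitter()
        km.fit(sub["T"], sub["E"], label=str(name))
        tab = km.event_table.reset_index()[["event_at", "at_risk", "observed"]]
        tab.insert(0, "group", name)
        out.append(tab)
    return pd.concat(out, ignore_index=True)
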