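"""Association scan: FDR estimator, OLS engine vs statsmodels, filters,
Fisher utilities vs direct hypergeometric summation."""

import math

import numpy as np
import pandas as pd
import pytest

from cisbreak.breakpoint_matrix import WindowSpec, build_binary_matrix, build_weighted_matrix
from cisbreak.io_model import GeneModel, SvCall
from cisbreak.sv_expression import (
    ScanConfig, breakpoint_group_enrichment, estimate_fdr, fit_gene_association,
    gene_set_enrichment, normalized_expression, run_scan, run_subgroup_scan,
)
from conftest import make_cohort


class TestEstimateFdr:
    def test_direct_formula_value(self):
        # 100 of 1000 genes significant at p <= 0.05 -> q = 0.05 * 1000 / 100
        p = np.concatenate([np.linspace(1e-6, 0.05, 100), np.linspace(0.2, 1, 900)])
        q = estimate_fdr(p)
        assert q[99] == pytest.approx(0.5)

    def test_all_significant_limit(self):
        p = np.full(50, 0.01)
        assert estimate_fdr(p) == pytest.approx(0.01)

    def test_matches_brute_force_with_cummax(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.random(rng.integers(1, 200))
            # independent brute-force evaluation of the published formula
            raw = np.array([pi * len(p) / np.sum(p <= pi) for pi in p])
            order = np.argsort(p, kind="mergesort")
            expected = np.minimum(raw, 1.0)
            expected[order] = np.maximum.accumulate(expected[order])
            assert estimate_fdr(p) == pytest.approx(expected)

    def test_monotone_bounded_and_tie_consistent(self):
        rng = np.random.default_rng(1)
        p = np.round(rng.random(300), 2)  # force ties
        q = estimate_fdr(p)
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()
        for val in np.unique(p):
            assert len(np.unique(q[p == val])) == 1

    def test_empty_input(self):
        assert estimate_fdr([]).size == 0


class TestFitGeneAssociation:
    def test_constant_expression_is_degenerate(self):
        fit = fit_gene_association(np.full(30, 7.0), np.arange(30.0))
        assert (fit.beta, fit.t, fit.p) == (0.0, 0.0, 1.0)
        assert fit.degenerate

    def test_exact_linear_fit_recovered(self):
        bp = np.array([0.0] * 15 + [1.0] * 15)
        tpm = 2.0 ** (2 * bp + 1) - 1.0  # log2(TPM+1) = 2*bp + 1 exactly
        fit = fit_gene_association(tpm, bp)
        assert fit.beta == pytest.approx(2.0)
        assert fit.p < 1e-12 and not fit.degenerate

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        n = 120
        strata = [f"t{i % 3}" for i in range(n)]
        cna = rng.integers(0, 6, n).astype(float)
        bp = np.where(rng.random(n) < 0.2, rng.uniform(1, 20, n), 0.0)
        bp_corr = bp + 0.5 * cna  # breakpoint correlated with copy number
        y = 1.0 * bp_corr + 0.4 * cna + rng.normal(0, 1, n) \
            + np.array([0.0, 0.7, -0.5])[np.arange(n) % 3]
        tpm = 2.0**y - 1.0
        fit = fit_gene_association(tpm, bp_corr, cna, strata)
        D = pd.get_dummies(pd.Series(strata), drop_first=True).to_numpy(dtype=float)
        X = sm.add_constant(np.column_stack([bp_corr, cna, D]))
        ref = sm.OLS(np.log2(tpm + 1), X).fit()
        assert fit.beta == pytest.approx(ref.params[1], rel=1e-8)
        assert fit.t == pytest.approx(ref.tvalues[1], rel=1e-6)
        assert fit.p == pytest.approx(ref.pvalues[1], rel=1e-6, abs=1e-12)
        # planted direct effect of 1.0 recovered within 3 SE
        se = abs(fit.beta / fit.t)
        assert abs(fit.beta - 1.0) < 3 * se


def _scan_cohort(n_genes=12, n_samples=40, seed=0, carrier_counts=None):
    rng = np.random.default_rng(seed)
    genes = [GeneModel(f"g{i:02d}", "chr1", 1_000_000 * (i + 1),
                       1_000_000 * (i + 1) + 10_000, "+") for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n_samples)]
    svs = []
    for gi, gene in enumerate(genes):
        k = carrier_counts[gi] if carrier_counts else int(rng.integers(0, 8))
        for s in rng.choice(samples, size=k, replace=False):
            svs.append(SvCall(str(s), "chr1", int(gene.start + 5_000), "+",
                              "chr1", int(gene.start + 6_000), "-", "DEL",
                              f"{gene.gene_id}_{s}"))
    return make_cohort(genes, svs, samples, seed=seed)


class TestRunScan:
    def test_min_carrier_filter_excludes_two_carrier_genes(self):
        cohort = _scan_cohort(carrier_counts=[2, 3, 4, 5, 0, 1, 2, 3, 6, 2, 3, 7])
        mat = build_binary_matrix(cohort, WindowSpec.gene_body())
        res = run_scan(cohort, mat, ScanConfig(min_carriers=3))
        kept = set(res["gene_id"])
        assert "g01" in kept and "g08" in kept
        assert {"g00", "g04", "g05", "g06", "g09"} & kept == set()

    def test_planted_effect_ranks_first(self):
        cohort = _scan_cohort(n_genes=10, n_samples=60, seed=3,
                              carrier_counts=[5] * 10)
        mat = build_binary_matrix(cohort, WindowSpec.gene_body())
        expr = cohort.expression.copy()
        carriers = mat.entries.loc["g03"] > 0
        expr.loc["g03", carriers[carriers].index] *= 2.0 ** 4
        cohort = make_cohort(cohort.genes, cohort.svs, cohort.samples,
                             expression=expr)
        res = run_scan(cohort, mat, ScanConfig(min_carriers=3))
        assert res.iloc[0]["gene_id"] == "g03"
        assert res.iloc[0]["direction"] == "pos"

    def test_direction_labels_match_beta_sign(self, random_small_cohort):
        mat = build_weighted_matrix(random_small_cohort)
        res = run_scan(random_small_cohort, mat)
        assert (np.sign(res["beta"]) >= 0).equals(res["direction"] == "pos")


class TestSubgroupScan:
    def test_small_subgroup_refused_with_threshold_in_message(self):
        cohort = _scan_cohort(n_samples=40)
        mat = build_weighted_matrix(cohort)
        with pytest.raises(ValueError, match="20"):
            run_subgroup_scan(cohort, cohort.samples[:10], mat)
        with pytest.raises(ValueError, match="19"):
            run_subgroup_scan(cohort, cohort.samples[:10], mat, kind="cancer_type")

    def test_significant_gene_without_extreme_carrier_filtered_out(self):
        cohort = _scan_cohort(n_genes=8, n_samples=30, seed=9,
                              carrier_counts=[6] * 8)
        mat = build_weighted_matrix(cohort)
        res_all = run_scan(cohort, mat, ScanConfig(min_carriers=0))
        # force one gene significant, then flatten its carriers to the median
        expr = cohort.expression.copy()
        carr = mat.entries.loc["g02"] > 0
        med = expr.loc["g02"].median()
        expr.loc["g02"] = med  # constant -> degenerate, never significant
        # instead plant a clean subgroup effect on g05
        carr5 = mat.entries.loc["g05"] > 0
        expr.loc["g05", carr5[carr5].index] *= 2.0 ** 5
        cohort2 = make_cohort(cohort.genes, cohort.svs, cohort.samples,
                              expression=expr)
        res = run_subgroup_scan(cohort2, cohort2.samples, mat,
                                ScanConfig(min_carriers=0))
        assert "g05" in set(res["gene_id"])
        sig = res[res["q"] < 0.10]
        z = normalized_expression(cohort2.expression)
        for g in sig["gene_id"]:
            zrow = z.loc[g]
            carr = mat.entries.loc[g] > 0
            assert (zrow[carr].abs() > 0.4).any()


def hypergeom_tail(a, row1, col1, n):
    """P(X >= a) for the 2x2 Fisher table by direct summation."""
    total = 0.0
    for k in range(a, min(row1, col1) + 1):
        total += (math.comb(col1, k) * math.comb(n - col1, row1 - k)
                  / math.comb(n, row1))
    return total


class TestFisherUtilities:
    def test_enrichment_p_equals_hypergeometric_tail(self):
        cohort = _scan_cohort(n_genes=4, n_samples=12, seed=2,
                              carrier_counts=[3, 5, 2, 6])
        mat = build_binary_matrix(cohort, WindowSpec.gene_body())
        for gene in ("g00", "g01", "g03"):
            carr = sorted(s for s in cohort.samples if mat.entries.at[gene, s] > 0)
            group = set(carr)  # group exactly the carriers: strongest enrichment
            p = breakpoint_group_enrichment(mat, gene, group)
            expected = hypergeom_tail(len(carr), len(carr), len(carr), 12)
            assert p == pytest.approx(expected, rel=1e-9)

    def test_empty_and_disjoint_groups_give_p_one(self):
        cohort = _scan_cohort(n_genes=2, n_samples=12, carrier_counts=[3, 4])
        mat = build_binary_matrix(cohort, WindowSpec.gene_body())
        assert breakpoint_group_enrichment(mat, "g00", set()) == 1.0
        carr = {s for s in cohort.samples if mat.entries.at["g00", s] > 0}
        disjoint = set(cohort.samples) - carr
        assert breakpoint_group_enrichment(mat, "g00", disjoint) == pytest.approx(1.0)

    def test_gene_set_enrichment_oracle_and_edge_cases(self):
        universe = [f"g{i}" for i in range(40)]
        sets = {"hit_set": universe[:10], "disjoint": universe[20:30]}
        hits = set(universe[:8])
        res = gene_set_enrichment(hits, universe, sets)
        row = res.set_index("gene_set")
        assert row.loc["disjoint", "p"] == pytest.approx(1.0)
        expected = hypergeom_tail(8, 8, 10, 40)
        assert row.loc["hit_set", "p"] == pytest.approx(expected, rel=1e-9)
        empty = gene_set_enrichment([], universe, sets)
        assert (empty["p"] == 1.0).all()
        with pytest.raises(ValueError):
            gene_set_enrichment(hits, [], sets)


def test_normalized_expression_median_and_unit_sd():
    expr = pd.DataFrame({"a": [1.0], "b": [3.0], "c": [7.0]}, index=["g"])
    z = normalized_expression(expr)
    x = np.log2(expr + 1).to_numpy()[0]
    assert z.to_numpy()[0] == pytest.approx((x - np.median(x)) / x.std(ddof=1))


def test_subgroup_only_effect_found_in_subgroup_but_not_full_scan():
    """A cis-effect present only in therapy-labelled tumors reaches FDR
    significance in the subgroup scan but not in the full-cohort scan."""
    from cisbreak.breakpoint_matrix import build_weighted_matrix
    from cisbreak.synthetic import PlantedCis, SimConfig, generate

    cfg = SimConfig(
        seed=2718, n_samples=300, n_genes=300,
        cis_effects=(PlantedCis("g100", 2.0, 25, subgroup="taxane"),),
    )
    cohort, truth = generate(cfg)
    label_members = [s for s in cohort.samples
                     if "taxane" in cohort.annotations.at[s, "therapy_flags"]]
    assert set(truth.cis_carriers["g100"]) <= set(label_members)
    matrix = build_weighted_matrix(cohort, collect_nearest=False)
    full = run_scan(cohort, matrix)
    sub = run_subgroup_scan(cohort, label_members, matrix)
    q_full = float(full.set_index("gene_id").loc["g100", "q"])
    q_sub = float(sub.set_index("gene_id").loc["g100", "q"])
    assert q_sub < 0.10
    assert q_sub < q_full
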