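"""Burden correlates, survival scans, signature construction and scoring."""

import math

import numpy as np
import pandas as pd
import pytest

from cisbreak.burden_survival import (
    apply_followup_cap, build_survival_signature, burden_expression_scan,
    compute_burden, cox_breakpoint_scan, cox_expression_scan, cox_gene_scan,
    km_table, score_signature, tertile_groups, tertile_logrank,
)
from cisbreak.breakpoint_matrix import build_weighted_matrix
from cisbreak.io_model import GeneModel, SvCall
from cisbreak.synthetic import PlantedCis, SimConfig, generate
from conftest import make_cohort


class TestBurden:
    def test_counts_by_direct_tally(self):
        genes = [GeneModel("g1", "chr1", 100, 200)]
        svs = [SvCall("A", "chr1", i, "+", "chr1", i + 10, "-", "DEL", f"a{i}")
               for i in range(4)]
        svs += [SvCall("B", "chr1", 100 + i, "+", "chr1", 500 + i, "-", "DEL", f"b{i}")
                for i in range(3)]
        cohort = make_cohort(genes, svs, ["A", "B", "C"])
        burden = compute_burden(cohort)
        assert burden.loc["A", "n_sv"] == 4 and burden.loc["B", "n_sv"] == 3
        assert burden.loc["C", "n_sv"] == 0 and burden.loc["C", "log_burden"] == 0.0

    def test_counts_match_groupby_oracle(self, random_small_cohort):
        burden = compute_burden(random_small_cohort)
        oracle = pd.Series([sv.sample_id for sv in random_small_cohort.svs]).value_counts()
        for s in random_small_cohort.samples:
            assert burden.loc[s, "n_sv"] == oracle.get(s, 0)

    def test_planted_burden_slope_recovered_within_3se(self):
        cfg = SimConfig(seed=21, n_samples=200, n_genes=400,
                        burden_effects=(("g040", 0.8), ("g041", 0.8)))
        cohort, _ = generate(cfg)
        res = burden_expression_scan(cohort).set_index("gene_id")
        for g in ("g040", "g041"):
            slope, t = res.loc[g, "slope"], res.loc[g, "t"]
            se = abs(slope / t)
            assert abs(slope - 0.8) < 3 * se
            assert res.loc[g, "q"] < 0.10


class TestFollowupCap:
    def test_event_beyond_cap_censored(self):
        t, e = apply_followup_cap([250.0], [1], 200.0)
        assert t[0] == 200.0 and e[0] == 0

    def test_event_before_cap_unchanged(self):
        t, e = apply_followup_cap([150.0], [1], 200.0)
        assert t[0] == 150.0 and e[0] == 1

    def test_idempotent(self):
        times = np.array([10.0, 250.0, 199.9, 300.0])
        events = np.array([1, 1, 0, 0])
        once = apply_followup_cap(times, events, 200.0)
        twice = apply_followup_cap(*once, 200.0)
        assert np.array_equal(once[0], twice[0]) and np.array_equal(once[1], twice[1])
        assert not ((once[0] > 200.0).any() or ((once[0] == 200.0) & (once[1] == 1)).any())

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            apply_followup_cap([-1.0], [0], 200.0)


class TestCoxScans:
    def test_planted_expression_hazard_recovered_within_3se(self):
        cfg = SimConfig(seed=31, n_samples=250, n_genes=60,
                        hazard_effects=(("g10", math.log(2.0), "expression"),))
        cohort, _ = generate(cfg)
        res = cox_expression_scan(cohort, genes=["g10"])
        row = res.iloc[0]
        assert row["hr_direction"] > 0 and row["p"] < 0.05
        # coefficient per log2-expression unit; planted log-HR is per SD of
        # log2 expression, so compare on the per-SD scale
        x = np.log2(cohort.expression.loc["g10"] + 1)
        coef_per_sd = row["coef"] * x.std(ddof=1)
        from lifelines import CoxPHFitter

        df = pd.DataFrame({
            "T": np.maximum(cohort.annotations["os_months"].to_numpy(), 1e-6),
            "E": cohort.annotations["os_event"].to_numpy(),
            "x": (x - np.median(x)).to_numpy() / x.std(ddof=1),
            "strata": cohort.annotations["cancer_type"].to_numpy(),
        })
        cph = CoxPHFitter().fit(df, "T", "E", strata=["strata"])
        se = float(cph.summary.loc["x", "se(coef)"])
        assert abs(coef_per_sd - math.log(2.0)) < 3 * se

    def test_all_censored_returns_empty_with_warning(self):
        cfg = SimConfig(seed=32, n_samples=30, n_genes=20)
        cohort, _ = generate(cfg)
        cohort.annotations["os_event"] = 0
        with pytest.warns(UserWarning, match="events"):
            res = cox_expression_scan(cohort)
        assert res.empty

    def test_breakpoint_scan_runs_and_keeps_scored_genes(self):
        cfg = SimConfig(seed=33, n_samples=80, n_genes=50)
        cohort, _ = generate(cfg)
        m = build_weighted_matrix(cohort, collect_nearest=False)
        res = cox_breakpoint_scan(cohort, m)
        assert (res["variable"] == "breakpoint_distance").all()
        assert ((res["p"] > 0) & (res["p"] <= 1)).all()


class TestSignature:
    def test_overlap_fisher_matches_hypergeometric_oracle(self):
        genes = [f"g{i}" for i in range(50)]
        assoc = pd.DataFrame({
            "gene_id": genes,
            "beta": [1.0] * 20 + [-1.0] * 30,
            "p": [0.01] * 20 + [0.5] * 30,
        })
        cox_bp = pd.DataFrame({
            "gene_id": genes,
            "coef": [1.0] * 15 + [-1.0] * 35,
            "p": [0.01] * 15 + [0.9] * 35,
        })
        cox_ex = cox_bp.copy()
        sig, p = build_survival_signature(assoc, cox_bp, cox_ex)
        assert sig == sorted(f"g{i}" for i in range(15))
        # direct hypergeometric tail: 20 positives, 15 poor-prognosis, 50 genes
        tail = sum(
            math.comb(15, k) * math.comb(35, 20 - k) / math.comb(50, 20)
            for k in range(15, 16)
        )
        assert p == pytest.approx(tail, rel=1e-9)

    def test_disjoint_sets_empty_signature_p_one(self):
        genes = [f"g{i}" for i in range(30)]
        assoc = pd.DataFrame({"gene_id": genes, "beta": [1.0] * 15 + [-1.0] * 15,
                              "p": [0.01] * 15 + [0.9] * 15})
        cox = pd.DataFrame({"gene_id": genes, "coef": [-1.0] * 15 + [1.0] * 15,
                            "p": [0.01] * 30})
        sig, p = build_survival_signature(assoc, cox, cox)
        assert sig == [] and p == pytest.approx(1.0)

    def test_score_zero_at_median_and_unit_at_one_sd(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.lognormal(3, 1, (5, 31)),
                            index=[f"g{i}" for i in range(5)],
                            columns=[f"s{i}" for i in range(31)])
        scores = score_signature(expr, [f"g{i}" for i in range(5)])
        x = np.log2(expr + 1)
        manual = ((x.sub(x.median(axis=1), axis=0)).div(x.std(axis=1, ddof=1), axis=0)).mean()
        assert scores.to_numpy() == pytest.approx(manual.to_numpy())
        one = pd.DataFrame({"a": [3.0], "b": [7.0], "c": [15.0], "d": [1.0]},
                           index=["g"])  # log2(TPM+1) = 2,3,4,1
        s = score_signature(one, ["g"])
        x1 = np.log2(one + 1).to_numpy()[0]
        assert s["b"] == pytest.approx((x1[1] - np.median(x1)) / x1.std(ddof=1))

    def test_signature_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        expr = pd.DataFrame(rng.lognormal(3, 1, (6, 20)),
                            index=[f"g{i}" for i in range(6)],
                            columns=[f"s{i}" for i in range(20)])
        a = score_signature(expr, ["g0", "g3", "g5"])
        b = score_signature(expr, ["g5", "g0", "g3"])
        assert a.to_numpy() == pytest.approx(b.to_numpy())

    def test_high_tertile_with_planted_hazard_flagged_by_logrank(self):
        rng = np.random.default_rng(9)
        n = 600
        scores = pd.Series(rng.normal(0, 1, n), index=[f"s{i}" for i in range(n)])
        groups = tertile_groups(scores)
        hr = np.where(groups == "high", 2.0, 1.0)
        times = rng.exponential(50.0 / hr)
        events = (times < rng.uniform(5, 120, n)).astype(int)
        times = np.minimum(times, 120)
        p, _ = tertile_logrank(scores, times, events)
        assert p < 0.01

    def test_km_table_counts(self):
        times = [5, 10, 10, 20, 30]
        events = [1, 1, 0, 1, 0]
        groups = ["a"] * 5
        tab = km_table(times, events, groups)
        assert tab["observed"].sum() == 3
        assert tab["at_risk"].max() == 5
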