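"""Equivalence (TOST), reliability (ICC) and signed-rank statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from augvol.errors import IncompleteDesignError, SchemaError
from augvol.stats import (
    PairedMeasurements,
    icc_two_way_mixed_single,
    interpret_icc,
    summarize_table,
    tost_paired,
    wilcoxon_signed_rank,
)

from oracles import anova_two_way_oracle, icc_a1_oracle, wilcoxon_exact_oracle


def pairs_from_diffs(d):
    d = np.asarray(d, float)
    return PairedMeasurements.from_arrays(np.arange(len(d)), d, np.zeros(len(d)))


class TestTOST:
    def test_tiny_jitter_is_equivalent_not_different(self):
        rng = np.random.default_rng(0)
        d = rng.normal(0, 1e-4, 20)
        res = tost_paired(pairs_from_diffs(d), margin=0.15)
        assert res.equivalent and not res.different_from_zero

    def test_large_mean_not_equivalent(self):
        rng = np.random.default_rng(1)
        d = 0.5 + rng.normal(0, 0.01, 19)
        res = tost_paired(pairs_from_diffs(d), margin=0.15)
        assert not res.equivalent and res.different_from_zero

    def test_reported_regime_round_trip(self):
        """n=19 differences with mean −0.015 and a 90 % CI of half-width
        0.0475 cm^3: TOST at ±0.15 declares equivalence with p < 0.001.

        The sd is derived by inverting the CI half-width
        (sd = hw·sqrt(n)/t_{0.95,18}) and verified by round-trip.
        """
        n, mean, hw = 19, -0.015, (0.033 + 0.062) / 2
        sd = hw * np.sqrt(n) / sps.t.ppf(0.95, n - 1)
        rng = np.random.default_rng(2)
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std(ddof=1)
        d = mean + sd * x
        res = tost_paired(pairs_from_diffs(d), margin=0.15)
        assert res.ci90[0] == pytest.approx(mean - hw, abs=1e-9)
        assert res.ci90[1] == pytest.approx(mean + hw, abs=1e-9)
        assert res.tost_p < 0.001
        assert res.equivalent and not res.different_from_zero

    def test_decision_equals_ci_in_bounds(self):
        """(tost_p < alpha) <=> (90 % CI inside ±margin), random datasets."""
        rng = np.random.default_rng(3)
        margin = 0.15
        for _ in range(1000):
            n = rng.integers(4, 40)
            d = rng.normal(rng.uniform(-0.3, 0.3), rng.uniform(0.01, 0.3), n)
            res = tost_paired(pairs_from_diffs(d), margin=margin)
            ci_inside = -margin < res.ci90[0] and res.ci90[1] < margin
            assert res.equivalent == ci_inside

    def test_zero_variance_degenerate(self):
        res = tost_paired(pairs_from_diffs(np.full(10, 0.01)), margin=0.15)
        assert res.ci90[0] == pytest.approx(0.01, abs=1e-12)
        assert res.ci90[1] == pytest.approx(0.01, abs=1e-12)
        assert res.equivalent

    def test_missing_pairs_excluded_and_counted(self):
        a = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        b = np.array([1.0, 2.0, 3.0, 4.0, np.nan])
        pm = PairedMeasurements.from_arrays(np.arange(5), a, b)
        assert len(pm) == 3 and pm.n_excluded == 2

    def test_too_few_pairs(self):
        with pytest.raises(SchemaError):
            tost_paired(pairs_from_diffs([0.1, 0.2]))

    def test_power_in_study_regime(self):
        """True difference 0, sd 0.07, n 19, margin 0.15: power >= 95 %."""
        rng = np.random.default_rng(4)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            d = rng.normal(0.0, 0.07, 19)
            if tost_paired(pairs_from_diffs(d), margin=0.15).equivalent:
                hits += 1
        assert hits / n_sim >= 0.95

    def test_type_I_error_at_the_bound(self):
        """At a true difference equal to the margin, false equivalence <= alpha."""
        rng = np.random.default_rng(5)
        hits = 0
        n_sim = 2000
        for _ in range(n_sim):
            d = rng.normal(0.15, 0.07, 19)
            if tost_paired(pairs_from_diffs(d), margin=0.15).equivalent:
                hits += 1
        assert hits / n_sim <= 0.05 + 2.5 * np.sqrt(0.05 * 0.95 / n_sim)


class TestICC:
    def test_perfect_repeat_is_one_excellent(self):
        x = np.random.default_rng(6).normal(0.8, 0.1, 12)
        res = icc_two_way_mixed_single(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)
        assert res.interpretation == "excellent"

    def test_matches_anova_oracle(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(50, 2))  # no subject effect: ICC near 0
        res = icc_two_way_mixed_single(X)
        ms = anova_two_way_oracle(X)
        for key in ("MSR", "MSC", "MSE"):
            assert res.anova[key] == pytest.approx(ms[key], abs=1e-10)
        assert res.icc == pytest.approx(icc_a1_oracle(X), abs=1e-10)
        assert abs(res.icc) < 0.3

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        subj = rng.normal(0.8, 0.09, 20)
        X = np.column_stack(
            [subj + rng.normal(0, 0.02, 20), subj + 0.01 + rng.normal(0, 0.02, 20)]
        )
        mine = icc_two_way_mixed_single(X)
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(20), 2),
                "r": np.tile(["t0", "t1"], 20),
                "v": X.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(df, targets="s", raters="r", ratings="v")
        ref_a1 = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
        assert mine.icc == pytest.approx(float(ref_a1["ICC"]), abs=1e-9)
        lo, hi = ref_a1["CI95"]
        assert mine.ci95[0] == pytest.approx(lo, abs=5e-3)  # pingouin rounds
        assert mine.ci95[1] == pytest.approx(hi, abs=5e-3)

    def test_constant_shift_invariance(self):
        rng = np.random.default_rng(9)
        X = rng.normal(0.8, 0.1, (15, 2))
        a = icc_two_way_mixed_single(X)
        b = icc_two_way_mixed_single(X + 5.0)
        assert a.icc == pytest.approx(b.icc, abs=1e-12)

    def test_rater_offset_hits_agreement_not_consistency(self):
        rng = np.random.default_rng(10)
        subj = rng.normal(0.8, 0.1, 30)
        noise = rng.normal(0, 0.01, (30, 2))
        X = np.column_stack([subj, subj + 0.15]) + noise  # systematic t1 offset
        agree = icc_two_way_mixed_single(X, agreement=True)
        consist = icc_two_way_mixed_single(X, agreement=False)
        assert consist.icc > 0.95
        assert agree.icc < consist.icc - 0.2

    def test_ci_coverage_in_study_regime(self):
        """95 % CI covers the true ICC >= 93 % of the time (500 replicates)."""
        rng = np.random.default_rng(11)
        sb, sw = 0.09, 0.02
        true_icc = sb**2 / (sb**2 + sw**2)
        n, covered = 20, 0
        reps = 500
        for _ in range(reps):
            subj = rng.normal(0.8, sb, n)
            X = subj[:, None] + rng.normal(0, sw, (n, 2))
            res = icc_two_way_mixed_single(X)
            if res.ci95[0] <= true_icc <= res.ci95[1]:
                covered += 1
        assert covered / reps >= 0.93

    def test_incomplete_design_rejected(self):
        with pytest.raises(IncompleteDesignError):
            icc_two_way_mixed_single(np.array([[1.0, np.nan], [2.0, 2.0]] * 3))

    def test_interpretation_bands(self):
        assert interpret_icc(0.49) == "poor"
        assert interpret_icc(0.5) == "moderate"
        assert interpret_icc(0.75) == "good"
        assert interpret_icc(0.9) == "excellent"


class TestWilcoxon:
    def test_antisymmetric_differences_p_one(self):
        d = np.array([1.0, -1.0, 2.0, -2.0, 3.0, -3.0])
        res = wilcoxon_signed_rank(pairs_from_diffs(d))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(1.0)

    def test_six_positive_differences_exact_p(self):
        res = wilcoxon_signed_rank(pairs_from_diffs([1.0, 2, 3, 4, 5, 6]))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(2 / 64)

    @pytest.mark.parametrize("n", [5, 8, 10, 12])
    def test_exact_p_matches_full_enumeration(self, n):
        rng = np.random.default_rng(n)
        for _ in range(5):
            d = np.round(rng.normal(0, 1, n), 2)
            d = d[d != 0]
            if len(d) < 5 or len(np.unique(np.abs(d))) < len(d):
                continue  # scipy's exact path requires untied magnitudes
            res = wilcoxon_signed_rank(pairs_from_diffs(d))
            assert res.p_value == pytest.approx(
                wilcoxon_exact_oracle(d), abs=1e-12
            )

    def test_exact_and_approx_agree_at_boundary_n(self):
        rng = np.random.default_rng(12)
        d = rng.normal(0.1, 1.0, 20)
        pm = pairs_from_diffs(d)
        exact = wilcoxon_signed_rank(pm)
        approx = sps.wilcoxon(d, zero_method="wilcox", correction=True, method="approx")
        assert exact.method == "exact"
        assert exact.p_value == pytest.approx(float(approx.pvalue), abs=0.02)

    def test_zeros_dropped_and_counted(self):
        d = np.array([0.0, 0.0, 1.0, 2.0, 3.0, -1.5, 2.5])
        res = wilcoxon_signed_rank(pairs_from_diffs(d))
        assert res.n_zero == 2 and res.n_used == 5

    def test_all_zero_degenerate(self):
        res = wilcoxon_signed_rank(pairs_from_diffs(np.zeros(8)))
        assert res.p_value == 1.0 and res.method == "degenerate"


class TestSummarizeTable:
    def _table(self, rng, n=10, techniques=("B", "S1")):
        rows = []
        for tech in techniques:
            base = {"B": 0.35, "S1": 0.76}[tech]
            for i in range(n):
                truth = rng.normal(base, 0.08)
                for method, bias in (("semiautomatic", -0.01), ("manual", 0.0)):
                    rows.append(
                        {
                            "specimen": f"s{i}",
                            "technique": tech,
                            "method": method,
                            "timepoint": "t0",
                            "value": truth + bias + rng.normal(0, 0.02),
                        }
                    )
        return pd.DataFrame(rows)

    def test_full_report_populated(self):
        table = self._table(np.random.default_rng(13))
        rep = summarize_table(table, margin=0.15)
        assert len(rep) == 2
        assert (rep["n_pairs"] == 10).all()
        assert rep["equivalent"].all()
        assert {"mean_difference", "ci90_lower", "tost_p", "nhst_p"} <= set(rep.columns)

    def test_single_cell_single_row(self):
        table = self._table(np.random.default_rng(14), n=6, techniques=("B",))
        rep = summarize_table(table)
        assert len(rep) == 1

    def test_empty_input_raises(self):
        with pytest.raises(SchemaError):
            summarize_table(pd.DataFrame())

    def test_missing_columns_raise(self):
        with pytest.raises(SchemaError):
            summarize_table(pd.DataFrame({"specimen": [1], "value": [2.0]}))

    def test_missing_side_counted(self):
        table = self._table(np.random.default_rng(15), n=8, techniques=("B",))
        table = table.drop(table[(table.specimen == "s0") & (table.method == "manual")].index)
        rep = summarize_table(table)
        assert rep.loc[0, "n_pairs"] == 7
        assert rep.loc[0, "n_excluded"] == 1

    def test_wilcoxon_layout(self):
        rng = np.random.default_rng(16)
        table = self._table(rng, n=12)
        table["value"] = 280 + rng.normal(0, 50, len(table))
        rep = summarize_table(table, wilcoxon=True)
        assert "wilcoxon_p" in rep.columns
        assert ((0 <= rep["wilcoxon_p"]) & (rep["wilcoxon_p"] <= 1)).all()
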