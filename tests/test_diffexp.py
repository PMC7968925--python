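"""Differential-binding stage: normalization, filtering, NB-GLM LRT, calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import optimize, stats

from bioidnet import (
    DispersionEstimate,
    PsmMatrix,
    call_candidates,
    estimate_dispersion,
    filter_detected,
    impute_missing,
    lrt_differential,
    overlap_stats,
    simulate_psm,
    sum_normalize,
)
from bioidnet.diffexp import nb_loglik
from bioidnet.io import NumericError


def _psm(counts: dict, conditions: list[str], index=None) -> PsmMatrix:
    df = pd.DataFrame(counts, index=index, dtype=float)
    cond = pd.Series(conditions, index=df.columns)
    rep = pd.Series(range(1, len(conditions) + 1), index=df.columns)
    return PsmMatrix(counts=df, condition=cond, replicate=rep)


class TestImpute:
    def test_nan_cells_become_exactly_zero(self, toy_psm):
        toy_psm.counts.loc["P1", "b1"] = np.nan
        out = impute_missing(toy_psm)
        assert out.counts.loc["P1", "b1"] == 0.0

    def test_identity_without_missing_cells(self, toy_psm):
        out = impute_missing(toy_psm)
        pd.testing.assert_frame_equal(out.counts, toy_psm.counts)

    def test_random_masking_touches_only_masked_positions(self):
        psm, _ = simulate_psm(n_proteins=50, n_true=10, zero_rate=0.0, seed=9)
        rng = np.random.default_rng(9)
        mask = rng.random(psm.counts.shape) < 0.2
        masked = psm.counts.where(~mask)
        noisy = PsmMatrix(counts=masked, condition=psm.condition, replicate=psm.replicate)
        out = impute_missing(noisy)
        assert (out.counts.to_numpy()[mask] == 0).all()
        np.testing.assert_array_equal(
            out.counts.to_numpy()[~mask], psm.counts.to_numpy()[~mask]
        )


class TestSumNormalize:
    def test_scale_factors_forced_by_contract(self):
        psm = _psm({"s1": [60.0, 40.0], "s2": [150.0, 50.0]}, ["bait", "control"])
        norm = sum_normalize(psm)
        # totals 100 and 200 -> grand mean 150 -> factors 1.5 and 0.75
        np.testing.assert_allclose(norm["s1"], [90.0, 60.0])
        np.testing.assert_allclose(norm["s2"], [112.5, 37.5])

    def test_equal_totals_left_unchanged(self):
        psm = _psm({"s1": [10.0, 20.0], "s2": [25.0, 5.0]}, ["bait", "control"])
        pd.testing.assert_frame_equal(sum_normalize(psm), psm.counts)

    def test_column_totals_equalized_on_random_fixture(self):
        psm, _ = simulate_psm(n_proteins=200, n_true=30, seed=4)
        norm = sum_normalize(psm)
        totals = norm.sum(axis=0)
        np.testing.assert_allclose(totals, totals.mean(), atol=1e-9)

    def test_zero_total_sample_is_an_error_naming_it(self):
        psm = _psm({"s1": [1.0, 2.0], "s2": [0.0, 0.0]}, ["bait", "control"])
        with pytest.raises(NumericError, match="s2"):
            sum_normalize(psm)


class TestFilterDetected:
    @pytest.mark.parametrize(
        "bait_counts,expected",
        [((3, 3, 0), True), ((3, 2, 2), False), ((0, 0, 0), False), ((3, 3, 3), True)],
    )
    def test_rule_applied_literally_on_bait_replicates(self, bait_counts, expected):
        psm = _psm(
            {
                "b1": [bait_counts[0]], "b2": [bait_counts[1]], "b3": [bait_counts[2]],
                "c1": [99.0], "c2": [99.0],
            },
            ["bait", "bait", "bait", "control", "control"],
            index=["P"],
        )
        kept = filter_detected(psm, min_psm=2, min_reps=2)
        assert ("P" in kept) is expected

    def test_matches_exhaustive_per_protein_recheck(self):
        psm, _ = simulate_psm(n_proteins=300, n_true=60, seed=21)
        kept = set(filter_detected(psm, min_psm=2, min_reps=2))
        bait_cols = psm.samples("bait")
        for prot in psm.protein_ids:
            n_hit = sum(psm.counts.loc[prot, c] > 2 for c in bait_cols)
            assert (prot in kept) == bool(n_hit >= 2)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        min_psm=st.integers(min_value=0, max_value=6),
        min_reps=st.integers(min_value=0, max_value=3),
    )
    def test_tightening_thresholds_never_grows_the_set(self, min_psm, min_reps):
        psm, _ = simulate_psm(n_proteins=80, n_true=20, seed=12)
        base = set(filter_detected(psm, min_psm, min_reps))
        assert set(filter_detected(psm, min_psm + 1, min_reps)) <= base
        assert set(filter_detected(psm, min_psm, min(min_reps + 1, 3))) <= base


class TestDispersion:
    def test_poisson_limit_estimates_near_zero(self):
        psm, _ = simulate_psm(n_proteins=500, n_true=0, fold=1.0, phi=0.0,
                              zero_rate=0.0, seed=3)
        norm = sum_normalize(impute_missing(psm))
        assert estimate_dispersion(norm, psm.condition).phi <= 0.05

    def test_known_truth_recovered_within_band(self):
        psm, _ = simulate_psm(n_proteins=500, n_true=0, fold=1.0, phi=0.4,
                              zero_rate=0.0, seed=8)
        norm = sum_normalize(impute_missing(psm))
        assert 0.3 <= estimate_dispersion(norm, psm.condition).phi <= 0.5

    def test_zero_variance_counts_give_zero_dispersion(self):
        psm = _psm(
            {"s1": [5.0, 9.0], "s2": [5.0, 9.0], "s3": [5.0, 9.0], "s4": [5.0, 9.0]},
            ["bait", "bait", "control", "control"],
        )
        assert estimate_dispersion(psm.counts, psm.condition).phi < 1e-3


class TestLrt:
    def test_identical_counts_give_null_identity(self):
        psm = _psm(
            {"s1": [7.0], "s2": [7.0], "s3": [7.0], "s4": [7.0]},
            ["bait", "bait", "control", "control"], index=["P"],
        )
        res = lrt_differential(psm.counts, psm.condition, DispersionEstimate(0.1))
        assert res.loc["P", "lrt_stat"] == 0.0
        assert res.loc["P", "pvalue"] == 1.0

    def test_statistic_matches_direct_numeric_maximization(self):
        counts = pd.DataFrame(
            {"b1": [10.0], "b2": [10.0], "b3": [10.0],
             "c1": [0.0], "c2": [0.0], "c3": [0.0]},
            index=["P"],
        )
        cond = pd.Series(["bait"] * 3 + ["control"] * 3, index=counts.columns)
        phi = 0.1
        res = lrt_differential(counts, cond, DispersionEstimate(phi))

        y = counts.to_numpy()[0]

        def neg_ll_two_means(params):
            mu_b, mu_c = np.exp(params)
            return -(nb_loglik(y[:3], np.full(3, mu_b), phi).sum()
                     + nb_loglik(y[3:], np.full(3, mu_c), phi).sum())

        def neg_ll_one_mean(param):
            return -nb_loglik(y, np.full(6, np.exp(param[0])), phi).sum()

        # control group is all-zero: its likelihood tends to 0 as mu->0, so
        # maximize the bait part numerically and take the boundary for control
        full = optimize.minimize(
            lambda p: -nb_loglik(y[:3], np.full(3, np.exp(p[0])), phi).sum(),
            [np.log(10.0)], method="Nelder-Mead", options={"xatol": 1e-10, "fatol": 1e-12},
        )
        null = optimize.minimize(
            neg_ll_one_mean, [np.log(5.0)], method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12},
        )
        stat_oracle = 2.0 * (-full.fun - (-null.fun))
        assert res.loc["P", "lrt_stat"] == pytest.approx(stat_oracle, abs=1e-4)

    def test_null_simulation_type_one_error_in_binomial_band(self):
        psm, _ = simulate_psm(n_proteins=1000, n_true=0, fold=1.0, phi=0.3,
                              zero_rate=0.0, seed=11)
        psm = impute_missing(psm)
        norm = sum_normalize(psm)
        kept = filter_detected(psm)
        disp = estimate_dispersion(norm.loc[kept], psm.condition)
        p = lrt_differential(norm.loc[kept], psm.condition, disp)["pvalue"].to_numpy()
        frac = (p < 0.05).mean()
        half = 2.576 * np.sqrt(0.05 * 0.95 / len(p))
        assert 0.05 - half <= frac <= 0.05 + half


class TestCallCandidates:
    def test_strict_fold_change_threshold(self):
        res = pd.DataFrame(
            {
                "mean_bait": [29.0, 40.0], "mean_control": [9.7, 3.0],
                "log2fc": [np.log2(2.9), np.log2(10.0)],
                "lrt_stat": [20.0, 25.0], "pvalue": [0.0001, 0.00001],
            },
            index=pd.Index(["FC29", "FC10"], name="protein_id"),
        )
        out = call_candidates(res, alpha=0.05, fc_min=3.0)
        assert out.loc["FC29", "candidate"] == 0  # adjp fine but FC 2.9 <= 3
        assert out.loc["FC10", "candidate"] == 1

    def test_empty_input_gives_empty_output(self):
        res = pd.DataFrame(
            columns=["mean_bait", "mean_control", "log2fc", "lrt_stat", "pvalue"],
            index=pd.Index([], name="protein_id"), dtype=float,
        )
        assert len(call_candidates(res)) == 0

    def test_bh_matches_independent_rank_recomputation(self):
        rng = np.random.default_rng(2)
        pvals = rng.uniform(size=97)
        res = pd.DataFrame(
            {"mean_bait": 1.0, "mean_control": 1.0, "log2fc": 0.0,
             "lrt_stat": 0.0, "pvalue": pvals},
            index=pd.Index([f"P{i}" for i in range(97)], name="protein_id"),
        )
        out = call_candidates(res)
        # brute-force BH: adjp_(i) = min_{j>=i} p_(j) * n / j
        order = np.argsort(pvals)
        n = len(pvals)
        stepup = np.minimum.accumulate((pvals[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepup, 1.0)
        np.testing.assert_allclose(
            out["adjp"].reindex([f"P{i}" for i in range(97)]).to_numpy(), expected
        )

    def test_bh_monotone_and_at_least_p(self):
        rng = np.random.default_rng(5)
        pvals = rng.uniform(size=200)
        res = pd.DataFrame(
            {"mean_bait": 1.0, "mean_control": 1.0, "log2fc": 0.0,
             "lrt_stat": 0.0, "pvalue": pvals},
            index=pd.Index([f"P{i}" for i in range(200)], name="protein_id"),
        )
        out = call_candidates(res)
        assert (out["adjp"] >= out["pvalue"] - 1e-12).all()
        by_p = out.sort_values("pvalue")
        assert (np.diff(by_p["adjp"].to_numpy()) >= -1e-12).all()

    def test_calling_invariant_to_row_order(self):
        psm, _ = simulate_psm(n_proteins=120, n_true=25, seed=6)
        psm = impute_missing(psm)
        norm = sum_normalize(psm)
        kept = filter_detected(psm)
        disp = estimate_dispersion(norm.loc[kept], psm.condition)
        res = lrt_differential(norm.loc[kept], psm.condition, disp)
        out1 = call_candidates(res)
        shuffled = res.sample(frac=1.0, random_state=1)
        out2 = call_candidates(shuffled)
        pd.testing.assert_frame_equal(out1, out2)


class TestOverlapStats:
    def test_hand_computed_odds_ratio(self):
        # 2x2 table [[5,5],[5,85]] -> OR = 5*85 / (5*5) = 17
        a = {f"a{i}" for i in range(10)}
        b = {f"a{i}" for i in range(5)} | {f"b{i}" for i in range(5)}
        out = overlap_stats(a, b, universe_size=100)
        assert out["odds_ratio"] == pytest.approx(17.0)
        assert not out["haldane_corrected"]

    def test_disjoint_sets_flagged_and_corrected(self):
        a = {f"a{i}" for i in range(30)}
        b = {f"b{i}" for i in range(30)}
        out = overlap_stats(a, b, universe_size=1000)
        assert out["overlap"] == 0
        assert out["haldane_corrected"]
        assert out["odds_ratio"] < 1.0

    def test_chi_squared_matches_textbook_formula(self):
        rng = np.random.default_rng(10)
        uni = [f"g{i}" for i in range(200)]
        a = set(rng.choice(uni, 40, replace=False))
        b = set(rng.choice(uni, 70, replace=False))
        out = overlap_stats(a, b, universe_size=200)
        both = len(a & b)
        tbl = np.array([[both, len(a) - both], [len(b) - both, 200 - len(a | b)]])
        n = tbl.sum()
        row, col = tbl.sum(1), tbl.sum(0)
        expected = np.outer(row, col) / n
        chi2 = ((tbl - expected) ** 2 / expected).sum()
        assert out["chi2_stat"] == pytest.approx(chi2, abs=1e-9)
        assert out["pvalue"] == pytest.approx(stats.chi2.sf(chi2, 1), abs=1e-12)

    def test_universe_smaller_than_union_rejected(self):
        with pytest.raises(ValueError):
            overlap_stats({"a"}, {"b"}, universe_size=1)
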