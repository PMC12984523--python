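"""Evaluation: metrics, Wilcoxon signed-rank, comparison/stability/sensitivity."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.stats import rankdata

import densrisk as dr
from densrisk.exceptions import ConfigurationError, DegenerateComparisonError


def brute_force_signed_rank_p(diffs: np.ndarray) -> float:
    """Exhaustive two-sided p over all 2^n sign assignments (oracle)."""
    d = diffs[diffs != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    sums = np.array(
        [sum(r for r, s in zip(ranks, signs) if s) for signs in itertools.product([False, True], repeat=n)]
    )
    lower = np.mean(sums <= w_obs + 1e-12)
    upper = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


class TestComputeMetrics:
    def test_identity_predictions(self):
        m = dr.compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "x")
        assert (m.mse, m.mae, m.r_squared) == (0.0, 0.0, 1.0)

    def test_closed_form_example(self):
        m = dr.compute_metrics([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], "x")
        assert m.mse == pytest.approx(2 / 3)
        assert m.mae == pytest.approx(2 / 3)
        assert m.r_squared == pytest.approx(0.0)

    def test_matches_hand_arithmetic_on_random_pairs(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=200)
        p = y + rng.normal(size=200)
        m = dr.compute_metrics(y, p, "x")
        resid = y - p
        assert m.mse == pytest.approx(float(np.sum(resid**2)) / 200, abs=1e-12)
        assert m.mae == pytest.approx(float(np.sum(np.abs(resid))) / 200, abs=1e-12)
        assert m.r_squared == pytest.approx(
            1 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2), abs=1e-12
        )

    def test_length_mismatch_and_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            dr.compute_metrics([1.0, 2.0], [1.0], "x")
        with pytest.raises(ValueError, match="zero variance"):
            dr.compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0], "x")

    @settings(derandomize=True, max_examples=50)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50),
        st.integers(0, 2**31 - 1),
    )
    def test_jensen_inequality_holds(self, truth, seed):
        y = np.asarray(truth)
        if np.var(y) == 0:
            y[0] += 1.0
        preds = y + np.random.default_rng(seed).normal(size=y.size)
        m = dr.compute_metrics(y, preds, "x")
        assert m.mae**2 <= m.mse + 1e-9


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        e = np.array([0.1, 0.5, 0.2, 0.9, 0.4])
        with pytest.raises(DegenerateComparisonError):
            dr.wilcoxon_signed_rank(e, e)

    def test_exact_p_matches_enumeration_on_stated_differences(self):
        d = np.array([1, 2, 3, 4, 5, -6, -7, 8, 9, 10], dtype=float)
        res = dr.wilcoxon_signed_rank(d, np.zeros_like(d))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_exact_branch_matches_enumeration_on_50_random_samples(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            n = int(rng.integers(5, 13))
            # integer magnitudes force ties; random signs
            d = rng.integers(1, 6, size=n) * rng.choice([-1.0, 1.0], size=n)
            res = dr.wilcoxon_signed_rank(d, np.zeros(n))
            assert res.method == "exact"
            assert res.n_effective == n
            assert res.p_value == pytest.approx(brute_force_signed_rank_p(d), abs=1e-12)

    def test_zero_differences_are_dropped(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        b = a.copy()
        b[:5] += np.array([0.5, -0.5, 1.0, -1.0, 2.0])
        res = dr.wilcoxon_signed_rank(a, b)
        assert res.n_effective == 5

    def test_normal_approximation_matches_scipy(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            n = int(rng.integers(20, 120))
            a = np.abs(rng.normal(size=n))
            b = np.abs(rng.normal(size=n))
            res = dr.wilcoxon_signed_rank(a, b)
            assert res.method == "normal-approximation"
            ref = stats.wilcoxon(a, b, correction=True, method="approx")
            assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 5"):
            dr.wilcoxon_signed_rank(np.array([1.0, 2.0, 3.0]), np.zeros(3))


@pytest.fixture(scope="module")
def report(default_cohort):
    return dr.compare_models(default_cohort, dr.NetworkConfig(), split_seed=0)


class TestCompareModels:
    def test_table_shape(self, report):
        assert len(report.rows) == 4
        assert [(r["model"], r["output"]) for r in report.rows] == [
            ("linear_regression", "riskenum"),
            ("mlp", "riskenum"),
            ("bifurcated", "densitanum"),
            ("bifurcated", "riskenum"),
        ]
        for row in report.rows:
            assert row["mae"] ** 2 <= row["mse"] + 1e-9

    def test_interpretation_never_claims_equivalence(self, report):
        assert np.isfinite(report.wilcoxon.p_value)
        text = report.interpretation.lower()
        if report.wilcoxon.p_value >= 0.05:
            assert "not find enough evidence" in text
            assert "does not demonstrate" in text
        assert "equivalent" not in text

    def test_published_reference_is_flagged_non_reproducible(self, report):
        assert report.published_reference["reproducible"] is False

    def test_model_trained_on_other_split_rejected(self, default_cohort):
        other_train, _ = dr.split_cohort(default_cohort, 0.8, seed=99)
        foreign = dr.train_mlp(
            other_train, "riskenum", dr.NetworkConfig(max_epochs=2, patience=2)
        )
        with pytest.raises(ValueError, match="shared training split"):
            dr.compare_models(default_cohort, dr.NetworkConfig(), split_seed=0, mlp_model=foreign)


class TestSeedStability:
    def test_identical_seeds_give_zero_spread(self, default_cohort):
        cfg = dr.NetworkConfig(max_epochs=5, patience=5)
        report = dr.seed_stability(default_cohort, cfg, seeds=(7, 7, 7), split_seed=0)
        assert report.spread == {"densitanum": 0.0, "riskenum": 0.0}

    def test_two_seeds_is_a_valid_report(self, default_cohort):
        cfg = dr.NetworkConfig(max_epochs=5, patience=5)
        report = dr.seed_stability(default_cohort, cfg, seeds=(0, 1), split_seed=0)
        assert report.n_seeds == 2
        assert all(s >= 0 for s in report.spread.values())
        assert set(report.sd) == {"densitanum", "riskenum"}

    def test_fewer_than_two_seeds_rejected(self, default_cohort):
        with pytest.raises(ConfigurationError, match="2 seeds"):
            dr.seed_stability(default_cohort, seeds=(0,))


class TestNoiseSensitivity:
    def test_factor_one_reproduces_base_run(self):
        sim = dr.SimulationConfig(n_patients=200, master_seed=5)
        net = dr.NetworkConfig(max_epochs=10, patience=10)
        report = dr.noise_sensitivity(sim, 1.0, net, split_seed=0)
        assert report["base"] == report["scaled"]

    def test_inflated_noise_report_structure(self):
        sim = dr.SimulationConfig(n_patients=200, master_seed=5)
        net = dr.NetworkConfig(max_epochs=10, patience=10)
        report = dr.noise_sensitivity(sim, 1.2, net, split_seed=0)
        assert report["noise_sd_scale"] == pytest.approx(np.sqrt(1.2))
        for section in ("base", "scaled"):
            assert set(report[section]) == {"densitanum", "riskenum"}


class TestResponseSurface:
    def test_grid_row_count(self, bif_default):
        frame = dr.response_surface(bif_default, np.arange(25.0, 86.0, 1.0))
        assert len(frame) == 61
        assert not frame["extrapolated"].any()
        assert {"age", "densitanum", "riskenum"} <= set(frame.columns)

    def test_out_of_range_grid_warns_and_flags(self, bif_default):
        with pytest.warns(UserWarning, match="extrapolation"):
            frame = dr.response_surface(bif_default, np.array([20.0, 50.0, 90.0]))
        assert frame["extrapolated"].tolist() == [True, False, True]

    def test_density_declines_from_midlife_to_old_age(self, bif_default):
        frame = dr.response_surface(bif_default, np.array([45.0, 80.0]))
        dens = frame["densitanum"].to_numpy()
        assert dens[1] < dens[0]
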