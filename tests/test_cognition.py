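"""Spline trajectory model, contrasts, delay conversion, cluster bootstrap."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import interp1d

from stoptrial import cognition as cg
from stoptrial._mixed import fit_weighted_random_intercept


def simulate_lmm(
    n_clusters=500,
    beta=None,
    sigma_b=2.0,
    sigma_e=1.5,
    seed=0,
    p_disc=0.3,
    visit_times=(0, 4, 8, 12, 18, 24, 36, 48),
):
    """Data generated directly from the analysis model itself."""
    rng = np.random.default_rng(seed)
    basis = cg.SplineBasis()
    beta = beta or {
        "const": 19.0,
        "arm": -0.2,
        "t": -0.17,
        "t2": 0.001,
        "t_knot82": -0.001,
        "arm_x_t": -0.18,
        "arm_x_t2": 0.009,
        "arm_x_t_knot82": -0.009,
    }
    rows = []
    for i in range(n_clusters):
        arm = int(rng.random() < p_disc)
        b = rng.normal(0, sigma_b)
        for t in visit_times:
            B = basis.design(np.array([float(t)]))[0]
            mu = (
                beta["const"]
                + beta["arm"] * arm
                + B @ [beta["t"], beta["t2"], beta["t_knot82"]]
                + arm * (B @ [beta["arm_x_t"], beta["arm_x_t2"],
                              beta["arm_x_t_knot82"]])
            )
            rows.append(
                {
                    "record_id": i,
                    "patient_id": f"p{i}",
                    "trial_month": 0,
                    "arm": arm,
                    "t": float(t),
                    "mmse": mu + b + rng.normal(0, sigma_e),
                    "weight": 1.0,
                }
            )
    return pd.DataFrame(rows), beta


class TestSplineBasis:
    def test_zero_at_baseline(self):
        B = cg.SplineBasis().design(np.array([0.0]))
        assert np.allclose(B, 0.0)

    def test_c1_continuity_at_the_knot(self):
        basis = cg.SplineBasis(knot=8.0)
        eps = 1e-6
        left = basis.design(np.array([8.0 - eps]))[0]
        right = basis.design(np.array([8.0 + eps]))[0]
        assert np.allclose(left, right, atol=1e-5)
        dleft = (
            basis.design(np.array([8.0 - eps]))[0]
            - basis.design(np.array([8.0 - 2 * eps]))[0]
        ) / eps
        dright = (
            basis.design(np.array([8.0 + 2 * eps]))[0]
            - basis.design(np.array([8.0 + eps]))[0]
        ) / eps
        assert np.allclose(dleft, dright, atol=1e-4)


class TestFitTrajectory:
    def test_parameter_recovery_from_own_model(self):
        long, beta = simulate_lmm(n_clusters=2000, seed=11)
        model = cg.fit_trajectory(long)
        for name, true in beta.items():
            assert model.beta[name] == pytest.approx(true, abs=0.05), name
        assert model.sigma_b == pytest.approx(2.0, rel=0.08)
        assert model.sigma_e == pytest.approx(1.5, rel=0.05)

    def test_unit_weights_match_statsmodels_mixedlm(self):
        import statsmodels.api as sm

        long, _ = simulate_lmm(n_clusters=200, seed=3)
        model = cg.fit_trajectory(long)
        from stoptrial.cognition import _trajectory_design

        X = _trajectory_design(long, cg.SplineBasis())
        ref = sm.MixedLM(
            long["mmse"].to_numpy(), X.to_numpy(), groups=long["record_id"]
        ).fit(reml=False)
        assert np.allclose(model.beta.to_numpy(), ref.fe_params, atol=2e-3)
        assert model.sigma_b**2 == pytest.approx(
            float(np.asarray(ref.cov_re)[0, 0]), rel=0.02
        )
        assert model.sigma_e**2 == pytest.approx(float(ref.scale), rel=0.02)

    def test_integer_cluster_weights_equal_duplicated_clusters(self):
        long, _ = simulate_lmm(n_clusters=120, seed=7)
        rng = np.random.default_rng(1)
        mult = rng.integers(1, 4, size=120)
        long["weight"] = mult[long["record_id"].to_numpy()]
        weighted = cg.fit_trajectory(long)
        dup = []
        for k, m in enumerate(mult):
            block = long[long["record_id"] == k]
            for copy in range(m):
                dup.append(block.assign(record_id=1000 * k + copy, weight=1.0))
        duplicated = cg.fit_trajectory(pd.concat(dup, ignore_index=True))
        assert np.allclose(
            weighted.beta.to_numpy(), duplicated.beta.to_numpy(), atol=1e-5
        )
        assert weighted.sigma_b == pytest.approx(duplicated.sigma_b, abs=1e-3)

    def test_all_singleton_clusters_unidentifiable(self):
        long, _ = simulate_lmm(n_clusters=50, seed=2, visit_times=(0,))
        with pytest.raises(ValueError, match="unidentifiable"):
            cg.fit_trajectory(long)

    def test_null_arm_effect_gives_near_zero_interactions(self):
        beta = {
            "const": 19.0, "arm": 0.0, "t": -0.17, "t2": 0.0,
            "t_knot82": 0.0, "arm_x_t": 0.0, "arm_x_t2": 0.0,
            "arm_x_t_knot82": 0.0,
        }
        long, _ = simulate_lmm(n_clusters=2500, beta=beta, seed=21)
        model = cg.fit_trajectory(long)
        assert cg.group_difference(model, 12) == pytest.approx(0.0, abs=0.25)


class TestPredictChange:
    def _linear_model(self, slope=-0.2, extra=-0.1):
        beta = pd.Series(
            {
                "const": 19.0, "arm": -0.3,
                "t": slope, "t2": 0.0, "t_knot82": 0.0,
                "arm_x_t": extra, "arm_x_t2": 0.0, "arm_x_t_knot82": 0.0,
            }
        )
        return cg.TrajectoryModel(
            beta=beta, sigma_b=2.0, sigma_e=1.5, basis=cg.SplineBasis(),
            neg2ll=0.0, n_obs=0, n_clusters=0,
        )

    def test_change_is_zero_at_baseline(self):
        model = self._linear_model()
        for arm in (0, 1):
            assert cg.predict_change(model, arm, np.array([0.0]))[0] == 0.0

    def test_linear_slope_closed_form(self):
        model = self._linear_model(slope=-0.2, extra=0.0)
        assert cg.predict_change(model, 0, np.array([12.0]))[0] == pytest.approx(
            -2.4
        )

    def test_negative_time_is_an_error(self):
        with pytest.raises(ValueError, match="nonnegative"):
            cg.predict_change(self._linear_model(), 0, np.array([-1.0]))

    def test_matches_per_record_averaging_oracle(self):
        long, _ = simulate_lmm(n_clusters=150, seed=9)
        long["trial_month"] = np.tile(
            np.repeat(np.arange(5), 8), 30
        )[: len(long)]
        model = cg.fit_trajectory(long)
        records = long[long["t"] == 0][
            ["record_id", "patient_id", "trial_month", "arm"]
        ].copy()
        for arm in (0, 1):
            for t in (6.0, 12.0, 30.0):
                rows_t = records.assign(t=t, arm=arm)
                rows_0 = records.assign(t=0.0, arm=arm)
                pred = (
                    cg.design_for_model(model, rows_t) @ model.beta.to_numpy()
                    - cg.design_for_model(model, rows_0) @ model.beta.to_numpy()
                )
                assert np.mean(pred) == pytest.approx(
                    cg.predict_change(model, arm, np.array([t]))[0], abs=1e-9
                )


class TestDifferencesAndDelay:
    @pytest.mark.parametrize(
        "cont, disc, printed",
        [
            (-2.05, -3.02, 0.97),
            (-3.74, -4.62, 0.88),
            (-5.22, -6.38, 1.16),
            (-6.49, -8.30, 1.81),
            (-1.98, -3.33, 1.35),
            (-2.39, -3.25, 0.86),
            (-6.55, -9.02, 2.47),
        ],
    )
    def test_decline_difference_sign_convention(self, cont, disc, printed):
        assert cg.decline_difference(cont, disc) == pytest.approx(printed)

    def test_parallel_linear_delay_is_gap_over_slope(self):
        s, d = 0.2, 0.8
        delay = cg.delay_from_curves(
            lambda t: -s * t, target=-s * 12 - d, t=12.0, horizon=72.0
        )
        assert delay == pytest.approx(d / s, abs=1e-9)

    def test_piecewise_linear_interpolation_of_yearly_changes(self):
        cont = interp1d([0, 12, 24], [0.0, -2.05, -3.74])
        delay = cg.delay_from_curves(
            lambda t: float(cont(t)), target=-3.02, t=12.0, horizon=24.0
        )
        assert delay == pytest.approx(12 * (3.02 - 2.05) / (3.74 - 2.05), abs=1e-6)
        assert delay == pytest.approx(6.9, abs=0.05)

    def test_zero_arm_effect_gives_zero_delay(self):
        delay = cg.delay_from_curves(
            lambda t: -0.2 * t, target=-0.2 * 12, t=12.0
        )
        assert delay == 0.0

    def test_unreached_level_raises_with_horizon(self):
        with pytest.raises(cg.DelayNotReached):
            cg.delay_from_curves(
                lambda t: -0.01 * t, target=-5.0, t=12.0, horizon=24.0
            )

    def test_difference_and_delay_agree_in_sign(self):
        long, _ = simulate_lmm(n_clusters=800, seed=31)
        model = cg.fit_trajectory(long)
        diff = cg.group_difference(model, 12)
        delay = cg.delay_in_decline(model, 12)
        assert diff > 0 and delay > 0


def _mean_statistic_dataset(n=500, seed=4):
    rng = np.random.default_rng(seed)
    rec = pd.DataFrame(
        {
            "record_id": np.arange(n),
            "patient_id": [f"p{i}" for i in range(n)],
            "trial_month": 0,
            "arm": rng.integers(0, 2, n),
            "x": rng.normal(size=n),
            "weight": 1.0,
            "t_death": np.nan,
            "t_admin": 60.0,
            "t_last_visit": 12.0,
            "baseline_mmse": 20.0,
        }
    )
    from stoptrial.trials import WeightedTrialDataset

    long = rec[["record_id", "patient_id", "trial_month", "arm"]].assign(
        t=0, mmse=20.0
    )
    return WeightedTrialDataset(records=rec, long=long, admin_end=60)


class TestClusterBootstrap:
    def test_ci_width_close_to_closed_form_for_a_mean(self):
        ds = _mean_statistic_dataset(n=500)

        def stat(d, eff):
            keep = eff > 0
            return np.average(d.records["x"][keep], weights=eff[keep])

        reps = cg.cluster_bootstrap(ds, stat, B=500, seed=12)
        res = cg.summarize_bootstrap(float(ds.records["x"].mean()), reps)
        sd = ds.records["x"].std(ddof=1)
        closed = 2 * 1.96 * sd / np.sqrt(500)
        assert abs((res.ci_high - res.ci_low) - closed) < 0.15 * closed

    def test_constant_statistic_gives_zero_width_ci(self):
        ds = _mean_statistic_dataset(n=60)
        reps = cg.cluster_bootstrap(ds, lambda d, e: 3.14, B=60, seed=1)
        res = cg.summarize_bootstrap(3.14, reps)
        assert res.ci_low == res.ci_high == pytest.approx(3.14)

    def test_fixed_seed_is_bit_reproducible(self):
        ds = _mean_statistic_dataset(n=100)

        def stat(d, eff):
            keep = eff > 0
            return np.average(d.records["x"][keep], weights=eff[keep])

        r1 = cg.cluster_bootstrap(ds, stat, B=80, seed=42)
        r2 = cg.cluster_bootstrap(ds, stat, B=80, seed=42)
        assert np.array_equal(r1, r2)

    def test_low_replicate_count_warns(self):
        ds = _mean_statistic_dataset(n=30)
        with pytest.warns(UserWarning, match="low"):
            cg.cluster_bootstrap(ds, lambda d, e: 0.0, B=20, seed=0)

    def test_excess_statistic_failures_raise(self):
        ds = _mean_statistic_dataset(n=30)

        def bad(d, eff):
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError, match="replicates failed"):
            cg.cluster_bootstrap(ds, bad, B=60, seed=0)


class TestWeightedEngine:
    def test_row_weight_duplication_identity(self):
        rng = np.random.default_rng(8)
        n, p = 300, 3
        X = np.c_[np.ones(n), rng.normal(size=(n, p - 1))]
        cl = np.repeat(np.arange(60), 5)
        y = X @ [1.0, 0.5, -0.3] + rng.normal(0, 1.5, n)[cl % n] + rng.normal(
            0, 1, n
        )
        w = rng.integers(1, 3, size=n).astype(float)
        fit_w = fit_weighted_random_intercept(X, y, cl, row_weights=w)
        reps = np.repeat(np.arange(n), w.astype(int))
        fit_d = fit_weighted_random_intercept(X[reps], y[reps], cl[reps])
        assert np.allclose(fit_w.beta, fit_d.beta, atol=1e-5)
        assert fit_w.sigma_e == pytest.approx(fit_d.sigma_e, abs=1e-3)
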