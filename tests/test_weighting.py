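"""Propensity scores, stabilized weights, balance metrics, and IPCW."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stoptrial import weighting
from stoptrial.cohort import screen_eligibility
from stoptrial.simdata import scenario_library, simulate_cohort
from stoptrial.trials import WeightedTrialDataset, expand_sequential_trials


def _records(arm, **cols):
    df = pd.DataFrame({"arm": np.asarray(arm, int)})
    df["record_id"] = np.arange(len(df))
    df["trial_month"] = cols.pop("trial_month", 0)
    for k, v in cols.items():
        df[k] = v
    return df


class TestPropensity:
    def test_intercept_only_scores_equal_marginal_proportion(self):
        rec = _records([1] * 30 + [0] * 70)
        model = weighting.fit_propensity(
            rec, covariates=[], include_trial_month=False
        )
        assert np.allclose(model.scores, 0.30)

    def test_saturated_two_by_two_recovers_cell_proportions(self):
        # x=0: 40 continue / 10 discontinue; x=1: 30 / 20
        arm = [1] * 10 + [0] * 40 + [1] * 20 + [0] * 30
        x = [0] * 50 + [1] * 50
        rec = _records(arm, x=x)
        model = weighting.fit_propensity(
            rec, covariates=["x"], include_trial_month=False
        )
        scores = pd.Series(model.scores, index=rec.index)
        assert np.allclose(scores[rec["x"] == 0], 10 / 50, atol=1e-6)
        assert np.allclose(scores[rec["x"] == 1], 20 / 50, atol=1e-6)

    def test_parameter_recovery_on_confounded_generator(self):
        cfg = dataclasses.replace(
            scenario_library()["paper_like"], n_patients=5000
        )
        patients, visits = simulate_cohort(cfg, seed=17)
        records, _ = screen_eligibility(patients, visits)
        model = weighting.fit_propensity(records)
        # stoppers are older, lower-MMSE, more institutionalised by design
        assert model.params["age"] > 0
        assert model.params["baseline_mmse"] < 0
        assert model.params["nursing_home"] > 0
        assert model.params["mrrc"] < 0

    def test_single_arm_input_is_an_error(self):
        rec = _records([0] * 50)
        with pytest.raises(ValueError, match="one arm"):
            weighting.fit_propensity(rec, covariates=[])

    def test_complete_separation_names_the_covariate(self):
        rec = _records([1] * 20 + [0] * 20, z=np.r_[np.ones(20), np.zeros(20)])
        with pytest.raises(ValueError, match="separated"):
            weighting.fit_propensity(
                rec, covariates=["z"], include_trial_month=False
            )


class TestStabilizedWeights:
    def test_no_confounding_gives_unit_weights(self):
        rec = _records([1] * 30 + [0] * 70)
        model = weighting.fit_propensity(
            rec, covariates=[], include_trial_month=False
        )
        sw = weighting.stabilized_weights(model, rec)
        assert np.allclose(sw, 1.0)

    def test_two_by_two_matches_hand_computation(self):
        arm = [1] * 10 + [0] * 40 + [1] * 20 + [0] * 30
        x = [0] * 50 + [1] * 50
        rec = _records(arm, x=x)
        model = weighting.fit_propensity(
            rec, covariates=["x"], include_trial_month=False
        )
        sw = weighting.stabilized_weights(model, rec)
        pbar = 0.30
        expected = {
            (1, 0): pbar / 0.2,
            (0, 0): (1 - pbar) / 0.8,
            (1, 1): pbar / 0.4,
            (0, 1): (1 - pbar) / 0.6,
        }
        for (a, xv), val in expected.items():
            sel = (rec["arm"] == a) & (rec["x"] == xv)
            assert np.allclose(sw[sel.to_numpy()], val, atol=1e-6)

    def test_mean_stabilized_weight_is_one_for_saturated_model(self):
        arm = [1] * 10 + [0] * 40 + [1] * 20 + [0] * 30
        rec = _records(arm, x=[0] * 50 + [1] * 50)
        model = weighting.fit_propensity(
            rec, covariates=["x"], include_trial_month=False
        )
        sw = weighting.stabilized_weights(model, rec)
        assert np.isclose(sw.mean(), 1.0, atol=1e-9)

    def test_weighted_arm_proportions_match_marginal_exactly_when_saturated(self):
        arm = [1] * 10 + [0] * 40 + [1] * 20 + [0] * 30
        rec = _records(arm, x=[0] * 50 + [1] * 50)
        model = weighting.fit_propensity(
            rec, covariates=["x"], include_trial_month=False
        )
        sw = weighting.stabilized_weights(model, rec)
        a = rec["arm"].to_numpy()
        assert np.average(a, weights=sw) == pytest.approx(a.mean(), abs=1e-9)


class TestSMD:
    def test_identical_distributions_have_zero_smd(self):
        x = np.r_[np.arange(10), np.arange(10)].astype(float)
        arm = np.r_[np.ones(10), np.zeros(10)].astype(int)
        assert weighting.standardized_mean_difference(x, arm) == pytest.approx(0.0)

    def test_published_style_summary_moments(self):
        # two-point arrays realise mean 17.9 sd 4.61 vs mean 19.1 sd 4.45
        x = np.array([17.9 - 4.61, 17.9 + 4.61, 19.1 - 4.45, 19.1 + 4.45])
        arm = np.array([1, 1, 0, 0])
        smd = weighting.standardized_mean_difference(x, arm, binary=False)
        assert smd == pytest.approx(
            -1.2 / np.sqrt((4.61**2 + 4.45**2) / 2), abs=1e-12
        )
        assert smd == pytest.approx(-0.265, abs=0.001)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_naive_two_pass_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 60
        x = rng.normal(size=n)
        arm = rng.integers(0, 2, size=n)
        if arm.min() == arm.max():
            arm[0] = 1 - arm[0]
        w = rng.uniform(0.2, 3.0, size=n)

        def naive(g):
            xg, wg = x[arm == g], w[arm == g]
            mu = (xg * wg).sum() / wg.sum()
            var = (wg * (xg - mu) ** 2).sum() / wg.sum()
            return mu, var

        (m1, v1), (m0, v0) = naive(1), naive(0)
        expected = (m1 - m0) / np.sqrt((v1 + v0) / 2)
        got = weighting.standardized_mean_difference(x, arm, w, binary=False)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_degenerate_covariate_with_equal_means_is_zero(self):
        x = np.ones(10)
        arm = np.r_[np.ones(5), np.zeros(5)].astype(int)
        assert weighting.standardized_mean_difference(x, arm, binary=False) == 0.0

    def test_symmetry_up_to_sign(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        arm = rng.integers(0, 2, size=50)
        a = weighting.standardized_mean_difference(x, arm, binary=False)
        b = weighting.standardized_mean_difference(x, 1 - arm, binary=False)
        assert a == pytest.approx(-b)

    def test_positivity_summary_warns_on_extreme_scores(self):
        model = weighting.PropensityModel(
            params=pd.Series({"const": 0.0}),
            scores=np.array([0.005, 0.5, 0.995]),
            covariates=[],
        )
        with pytest.warns(UserWarning, match="near 0/1"):
            out = weighting.positivity_summary(model)
        assert out["n_below_0.01"] == 1 and out["n_above_0.99"] == 1


def _censor_fixture():
    """Blocks whose empirical censoring pattern sits exactly on an
    additive-logit surface: monthly in-follow-up odds 3, 2, 1 for x=0 and
    doubled (6, 4, 2) for x=1."""
    rows = []
    rid = 0

    def add(x, t_obs, count):
        nonlocal rid
        for _ in range(count):
            rows.append((rid, f"q{rid}", 0, 0, x, np.nan, 3.0, float(t_obs)))
            rid += 1

    add(0, 0, 12); add(0, 1, 12); add(0, 2, 12); add(0, 3, 12)
    add(1, 0, 10); add(1, 1, 12); add(1, 2, 16); add(1, 3, 32)
    rec = pd.DataFrame(
        rows,
        columns=[
            "record_id", "patient_id", "trial_month", "arm", "x",
            "t_death", "t_admin", "t_last_visit",
        ],
    )
    rec["weight"] = 1.0
    rec["baseline_mmse"] = 20.0
    long = rec[["record_id", "patient_id", "trial_month", "arm"]].assign(
        t=0, mmse=20.0
    )
    return WeightedTrialDataset(records=rec, long=long, admin_end=3)


class TestIPCW:
    def test_no_censoring_before_horizon_gives_unit_weights(self):
        rec = pd.DataFrame(
            {
                "record_id": range(6),
                "patient_id": [f"p{i}" for i in range(6)],
                "trial_month": 0,
                "arm": [0, 1] * 3,
                "t_death": np.nan,
                "t_admin": 12.0,
                "t_last_visit": 12.0,
                "weight": 1.0,
                "baseline_mmse": 20.0,
            }
        )
        long = rec[["record_id", "patient_id", "trial_month", "arm"]].assign(
            t=0, mmse=20.0
        )
        ds = WeightedTrialDataset(records=rec, long=long, admin_end=12)
        out = weighting.censoring_weights(ds, covariates=[], horizon=12)
        assert np.allclose(out["ipcw"], 1.0)

    def test_three_month_toy_matches_hand_computed_products(self):
        ds = _censor_fixture()
        out = weighting.censoring_weights(ds, covariates=["x"], horizon=3)
        out = out.merge(ds.records[["record_id", "x"]], on="record_id")
        p_den = {0: [3 / 4, 2 / 3, 1 / 2], 1: [6 / 7, 4 / 5, 2 / 3]}
        p_num = [96 / 118, 72 / 96, 44 / 72]
        for x in (0, 1):
            for m in (1, 2, 3):
                expect = np.prod(
                    [p_num[k] / p_den[x][k] for k in range(m)]
                )
                got = out[(out["x"] == x) & (out["m"] == m)]["ipcw"]
                assert np.allclose(got, expect, atol=1e-6), (x, m)

    def test_mnar_dropout_ipcw_moves_estimate_toward_truth(self):
        # dropout driven by current (latent) cognition biases the observed
        # trajectories; censoring weights should shrink that bias on average
        from stoptrial import cognition as cg
        from stoptrial.simdata import truth

        cfg = dataclasses.replace(
            scenario_library()["mnar_dropout"],
            n_patients=1500,
            dropout_mmse_coef=-0.25,
            dropout_intercept=-2.2,
        )
        true12 = truth(cfg)["difference_12"]
        err_plain, err_ipcw = [], []
        for seed in range(8):
            patients, visits = simulate_cohort(cfg, seed=seed)
            records, _ = screen_eligibility(patients, visits)
            ds = expand_sequential_trials(records, visits, admin_end=83)
            prop = weighting.fit_propensity(ds.records)
            ds = ds.with_weights(
                weighting.stabilized_weights(prop, ds.records)
            )
            long = ds.long_with_weights()
            long = long[long["t"] <= 48]
            m0 = cg.fit_trajectory(long)
            ipcw = weighting.censoring_weights(ds, horizon=48)
            long_w = long.merge(
                ipcw.rename(columns={"m": "t", "ipcw": "row_w"}),
                on=["record_id", "t"],
                how="left",
            )
            long_w["row_w"] = long_w["row_w"].fillna(1.0)
            m1 = cg.fit_trajectory(long_w, row_weight_col="row_w")
            err_plain.append(cg.group_difference(m0, 12) - true12)
            err_ipcw.append(cg.group_difference(m1, 12) - true12)
        assert abs(np.mean(err_ipcw)) <= abs(np.mean(err_plain)) + 0.02
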