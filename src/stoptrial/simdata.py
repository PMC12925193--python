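"""Synthetic memory-clinic registry cohorts with known causal estimands.

The generator emulates the statistical structure the emulation pipeline
assumes: irregular consultation schedules, confounded discontinuation of a
symptomatic treatment inside a 12-month policy window, MMSE trajectories
with a spline-shaped post-discontinuation deficit, covariate-driven decline
heterogeneity (the confounding that IPTW must remove), MAR/MNAR dropout,
and a discrete-time death process.  Every scenario's true estimands are
available in closed form (or by deterministic numerical standardization)
from :func:`truth`, so pipeline recovery can be tested sharply.

Design choices that make the stacked sequential-trial ITT estimand equal
the configured truth exactly (see docs/methods.md for the full argument):
discontinuers stop at their first in-window consultation and next attend
7-12 months later, so each contributes exactly one (discontinuer) block
whose clock starts at the stop; the continuer mean decline is linear in
calendar time, so a continuer block's change from baseline is the same
spline contrast regardless of its enrolment month; and the stopping
propensity depends only on time-invariant covariates the analysis observes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

from stoptrial import schema

_TRUTH_MC_SEED = 20170801  # fixed: truth() is a function of the config only
_TRUTH_MC_N = 200_000

_DEFAULT_MED_PREVALENCE = {
    "antidepressant": 0.365,
    "neuroleptic": 0.046,
    "anxiolytic": 0.143,
    "hypnotic": 0.047,
    "nootropic": 0.008,
    "antihypertensive": 0.64,
    "antidiabetic": 0.14,
    "lipid_lowering": 0.46,
}


@dataclass
class SimConfig:
    """All knobs of the synthetic registry.

    Units: time in months (the enrolment window opens at month 0), MMSE in
    points, slopes in points per month, hazards as monthly probabilities on
    the logit scale.
    """

    n_patients: int = 1000
    seed: int = 0
    admin_end: int = 83          # administrative end of follow-up
    window_months: int = 12      # enrolment window 0..11

    # covariate distributions (margins mimic a French memory-clinic cohort)
    age_mean: float = 80.5
    age_sd: float = 7.5
    p_female: float = 0.65
    education_probs: tuple[float, float, float] = (0.48, 0.37, 0.15)
    p_mrrc: float = 0.27
    p_nursing_home: float = 0.06
    med_prevalence: dict[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_MED_PREVALENCE)
    )

    # latent baseline cognition
    mmse_mean: float = 19.0
    mmse_sd: float = 4.5
    mmse_band: tuple[float, float] = (10.0, 30.0)

    # stopping propensity (logit); confounding_strength scales the covariate
    # part, 0 = randomized stopping
    propensity_intercept: float = -1.75
    prop_age: float = 0.4
    prop_mmse: float = -0.3
    prop_nursing: float = 0.6
    prop_mrrc: float = -0.45
    prop_edu_post: float = -0.3
    confounding_strength: float = 1.0

    # latent trajectory: continuer decline + covariate-driven heterogeneity
    slope: float = -0.17
    curvature: float = 0.0
    slope_confounding: float = 0.22  # extra decline per unit confounder index
    slope_sd: float = 0.02           # idiosyncratic random slope

    # discontinuation deficit delta(t), subtracted after the stop
    arm_effect_shape: str = "spline"  # "spline" | "ramp"
    arm_spline: tuple[float, float, float] = (0.181831, -0.009448, 0.009281)
    knot: float = 8.0
    ramp_drop: float = 0.8767
    ramp_extra_slope: float = 0.0233333

    sigma_e: float = 1.5  # MMSE measurement noise (before rounding)
    p_mmse_missing: float = 0.05  # visits without an MMSE assessment

    # consultation process
    first_visit_low: int = -6
    first_visit_high: int = -1
    gap_mean: float = 4.5
    gap_sd: float = 1.5
    gap_min: int = 2
    gap_max: int = 9
    stopper_return_min: int = 7
    stopper_return_max: int = 12

    # loss to follow-up: per-visit probability of not returning (logit);
    # index term = MAR on covariates, mmse term = MNAR on current cognition
    dropout_intercept: float = -3.2
    dropout_index_coef: float = 0.0
    dropout_mmse_coef: float = 0.0

    # discrete-time death process (monthly logit hazard)
    hazard_intercept: float = -4.8
    hazard_age: float = 0.35
    hazard_arm: float = 0.0953

    def validate(self) -> None:
        probs = [self.p_female, self.p_mrrc, self.p_nursing_home]
        probs += list(self.med_prevalence.values())
        probs += list(self.education_probs)
        probs.append(self.p_mmse_missing)
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.education_probs) - 1.0) > 1e-9:
            raise ValueError("education probabilities must sum to 1")
        lo, hi = self.mmse_band
        if not (0.0 <= lo < hi <= 30.0):
            raise ValueError("MMSE truncation band must lie within [0, 30]")
        if self.gap_min < 1 or self.gap_max < self.gap_min:
            raise ValueError("infeasible visit-gap configuration")
        if self.arm_effect_shape not in ("spline", "ramp"):
            raise ValueError("arm_effect_shape must be 'spline' or 'ramp'")
        if self.admin_end <= self.window_months:
            raise ValueError("admin_end must exceed the enrolment window")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def arm_deficit(config: SimConfig, t_since_stop: np.ndarray) -> np.ndarray:
    """Mean extra decline delta(t) of discontinuers, t months after the stop."""
    t = np.clip(np.asarray(t_since_stop, dtype=float), 0.0, None)
    if config.arm_effect_shape == "spline":
        a, b, c = config.arm_spline
        return a * t + b * t**2 + c * np.clip(t - config.knot, 0.0, None) ** 2
    ramp = config.ramp_drop * np.minimum(t, config.knot) / config.knot
    return ramp + config.ramp_extra_slope * np.clip(t - config.knot, 0.0, None)


def _draw_covariates(config: SimConfig, n: int, rng: np.random.Generator):
    """Covariate table plus the standardized confounder indexes."""
    cov = pd.DataFrame(
        {
            "sex_female": rng.binomial(1, config.p_female, n),
            "age": np.clip(
                rng.normal(config.age_mean, config.age_sd, n), 55.0, 105.0
            ),
            "education": rng.choice(3, size=n, p=config.education_probs),
            "mrrc": rng.binomial(1, config.p_mrrc, n),
            "nursing_home": rng.binomial(1, config.p_nursing_home, n),
        }
    )
    for name, prev in config.med_prevalence.items():
        cov[name] = rng.binomial(1, prev, n)
    lo, hi = config.mmse_band
    aa = (lo - config.mmse_mean) / config.mmse_sd
    bb = (hi - config.mmse_mean) / config.mmse_sd
    cov["base_mmse"] = sps.truncnorm.rvs(
        aa, bb, loc=config.mmse_mean, scale=config.mmse_sd,
        size=n, random_state=rng,
    )
    age_std = (cov["age"] - config.age_mean) / config.age_sd
    mmse_std = (cov["base_mmse"] - config.mmse_mean) / config.mmse_sd
    # slope index: the time-invariant part of the propensity signal (latent
    # baseline cognition deliberately excluded; see docs/methods.md)
    slope_index = (
        config.prop_age * age_std
        + config.prop_nursing * (cov["nursing_home"] - config.p_nursing_home)
        + config.prop_mrrc * (cov["mrrc"] - config.p_mrrc)
        + config.prop_edu_post
        * ((cov["education"] == 2) - config.education_probs[2])
    )
    prop_index = slope_index + config.prop_mmse * mmse_std
    return cov, np.asarray(slope_index), np.asarray(prop_index), np.asarray(
        age_std
    )


def simulate_cohort(
    config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, visits) tables following :mod:`stoptrial.schema`.

    The tables are bit-reproducible for a given config and seed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = config.n_patients
    cov, slope_index, prop_index, age_std = _draw_covariates(config, n, rng)

    # consultation schedule: pre-window first visit, then jittered gaps
    max_vis = int(np.ceil((config.admin_end + 12) / config.gap_min)) + 2
    max_vis = min(max_vis, 64)
    first = rng.integers(
        config.first_visit_low, config.first_visit_high + 1, size=n
    )
    gaps = np.clip(
        np.round(rng.normal(config.gap_mean, config.gap_sd, (n, max_vis))),
        config.gap_min,
        config.gap_max,
    ).astype(int)
    months = first[:, None] + np.concatenate(
        [np.zeros((n, 1), dtype=int), np.cumsum(gaps, axis=1)], axis=1
    )

    # decline heterogeneity and measurement noise (drawn before assignment:
    # the stopping decision below uses the *measured* score at the decision
    # visit, as a clinician would)
    slope_i = (
        config.slope
        - config.slope_confounding * slope_index
        + config.slope_sd * rng.standard_normal(n)
    )[:, None]
    eps = rng.standard_normal(months.shape)

    in_window = months >= 0
    j0 = np.argmax(in_window, axis=1)  # first in-window visit index
    rows_n = np.arange(n)
    month_j0 = months[rows_n, j0]
    latent_j0 = (
        cov["base_mmse"].to_numpy()
        + slope_i[:, 0] * month_j0
        + config.curvature * month_j0.astype(float) ** 2
    )
    measured_j0 = np.clip(
        np.round(latent_j0 + config.sigma_e * eps[rows_n, j0]), 0, 30
    )
    decision_index = slope_index + config.prop_mmse * (
        (measured_j0 - config.mmse_mean) / config.mmse_sd
    )
    p_stop = expit(
        config.propensity_intercept
        + config.confounding_strength * decision_index
    )
    stopper = rng.binomial(1, p_stop).astype(bool)

    # stoppers: stop at the first in-window visit, return 7-12 months later
    stop_month = np.where(stopper, month_j0, np.iinfo(np.int32).max)
    ret = rng.integers(
        config.stopper_return_min, config.stopper_return_max + 1, size=n
    )
    next_idx = np.minimum(j0 + 1, max_vis)
    cur_next = months[np.arange(n), next_idx]
    shift = np.where(
        stopper, np.maximum(stop_month + ret - cur_next, 0), 0
    )
    col = np.arange(months.shape[1])
    months = months + shift[:, None] * (col[None, :] > j0[:, None])

    # death: constant monthly hazard, shifted after the stop
    lp = config.hazard_intercept + config.hazard_age * age_std
    h_pre = expit(lp)
    h_post = expit(lp + config.hazard_arm)
    m_grid = np.arange(0, config.admin_end + 1)
    hmat = np.where(
        stopper[:, None] & (m_grid[None, :] > stop_month[:, None]),
        h_post[:, None],
        h_pre[:, None],
    )
    dies = rng.random((n, len(m_grid))) < hmat
    any_death = dies.any(axis=1)
    death_month = np.where(any_death, np.argmax(dies, axis=1), -1)

    # latent trajectories at visit months (same noise stream as the
    # decision visit, so the recorded score there is the decision score)
    t_since_stop = np.where(
        stopper[:, None], np.clip(months - stop_month[:, None], 0, None), 0
    )
    latent = (
        cov["base_mmse"].to_numpy()[:, None]
        + slope_i * months
        + config.curvature * months.astype(float) ** 2
        - arm_deficit(config, t_since_stop)
    )
    observed = np.clip(np.round(latent + config.sigma_e * eps), 0, 30)

    # loss to follow-up: after each visit (from the second on) the patient
    # may never return; MNAR couples the probability to current cognition
    p_drop = expit(
        config.dropout_intercept
        + config.dropout_index_coef * slope_index[:, None]
        + config.dropout_mmse_coef * (latent - config.mmse_mean)
    )
    drop_here = rng.random(latent.shape) < p_drop
    drop_here[:, 0] = False
    dropped_before = np.concatenate(
        [np.zeros((n, 1), dtype=bool), np.cumsum(drop_here, axis=1)[:, :-1] > 0],
        axis=1,
    )

    keep = (
        (months <= config.admin_end)
        & ~dropped_before
        & (~any_death[:, None] | (months < death_month[:, None]))
    )
    on_chei = np.where(
        stopper[:, None], (months <= stop_month[:, None]).astype(int), 1
    )

    mmse_obs = observed.astype(float)
    if config.p_mmse_missing > 0:
        mmse_obs[rng.random(mmse_obs.shape) < config.p_mmse_missing] = np.nan

    pid = np.array([f"P{i:06d}" for i in range(n)])
    rows = keep.nonzero()
    visits = pd.DataFrame(
        {
            "patient_id": pid[rows[0]],
            "month": months[rows],
            "mmse": mmse_obs[rows],
            "on_chei": on_chei[rows],
            "ad_diagnosis": 1,
        }
    ).sort_values(["patient_id", "month"], kind="stable")
    # jittered gaps can in principle collide after the return shift; drop dups
    visits = visits.drop_duplicates(
        subset=["patient_id", "month"], keep="first"
    ).reset_index(drop=True)

    patients = pd.DataFrame({"patient_id": pid})
    for c in ["sex_female", "age", "education", "mrrc", "nursing_home"]:
        patients[c] = cov[c].to_numpy()
    for c in config.med_prevalence:
        patients[c] = cov[c].to_numpy()
    patients["death_month"] = np.where(any_death, death_month, np.nan)
    return patients, visits


def truth(config: SimConfig) -> dict[str, float]:
    """True estimands implied by the configuration.

    Differences and delays come from the closed-form arm deficit and the
    mean continuer decline; mortality risks are standardized over the
    covariate distribution by a deterministic large-sample numerical
    average (fixed internal stream, independent of the data seed);
    ``unweighted_bias_12`` is the designed confounding bias of the naive
    (unweighted) 1-year contrast.
    """
    config.validate()
    out: dict[str, float] = {}
    for t in (12, 24, 36, 48):
        out[f"difference_{t}"] = float(arm_deficit(config, np.array([t]))[0])

    def cont_change(t: float) -> float:
        return config.slope * t + config.curvature * t**2

    # delay: months for the continuer curve to fall by an extra delta(t)
    from stoptrial.cognition import DelayNotReached, delay_from_curves

    for t in (12, 24, 36, 48):
        target = cont_change(t) - out[f"difference_{t}"]
        try:
            out[f"delay_{t}"] = delay_from_curves(
                cont_change, target, float(t), horizon=240.0, step=1.0
            )
        except DelayNotReached:
            out[f"delay_{t}"] = float("nan")

    rng = np.random.default_rng(_TRUTH_MC_SEED)
    cov, slope_index, prop_index, age_std = _draw_covariates(
        config, _TRUTH_MC_N, rng
    )
    lp = config.hazard_intercept + config.hazard_age * age_std
    h0, h1 = expit(lp), expit(lp + config.hazard_arm)
    surv0 = np.ones_like(h0)
    surv1 = np.ones_like(h1)
    out["hazard_odds_ratio"] = float(np.exp(config.hazard_arm))
    for m in range(1, 61):
        surv0 *= 1.0 - h0
        surv1 *= 1.0 - h1
        if m % 12 == 0:
            r0 = float(np.mean(1.0 - surv0))
            r1 = float(np.mean(1.0 - surv1))
            out[f"risk_continue_{m}"] = r0
            out[f"risk_discontinue_{m}"] = r1
            out[f"rr_{m}"] = r1 / r0 if r0 > 0 else float("nan")

    # stopping decision uses the measured score at the decision visit
    measured = np.clip(
        np.round(
            cov["base_mmse"].to_numpy()
            + config.sigma_e * rng.standard_normal(len(cov))
        ),
        0,
        30,
    )
    decision_index = slope_index + config.prop_mmse * (
        (measured - config.mmse_mean) / config.mmse_sd
    )
    p = expit(
        config.propensity_intercept
        + config.confounding_strength * decision_index
    )
    d_index = float(
        np.average(slope_index, weights=p)
        - np.average(slope_index, weights=1.0 - p)
    )
    # stopping selects on the measurement noise of the decision score, which
    # enters change-from-baseline with opposite sign (regression to the mean)
    eps0 = measured - cov["base_mmse"].to_numpy()
    d_eps = float(np.average(eps0, weights=p) - np.average(eps0, weights=1.0 - p))
    out["marginal_p_stop"] = float(p.mean())
    out["unweighted_bias_12"] = (
        config.slope_confounding * d_index * 12.0 + d_eps
    )
    return out


def scenario_library() -> dict[str, SimConfig]:
    """Named study conditions.

    - ``null``: no treatment effect, randomized stopping, homogeneous
      decline -- for calibration checks.
    - ``paper_like``: confounded stopping with a spline-shaped deficit of
      about 1 MMSE point at one year and 1.8 at four years, and a small
      excess death hazard among stoppers.
    - ``confounded``: the same with 1.5x stronger indication bias.
    - ``mnar_dropout``: ``paper_like`` with dropout driven by current
      (unobserved) cognition.
    - ``ramp``: ``paper_like`` with a piecewise-linear deficit, i.e. a
      trajectory shape the analysis spline does not nest -- a robustness
      probe.
    """
    paper_like = SimConfig()
    null = replace(
        paper_like,
        arm_spline=(0.0, 0.0, 0.0),
        confounding_strength=0.0,
        slope_confounding=0.0,
        hazard_arm=0.0,
    )
    confounded = replace(
        paper_like, confounding_strength=1.5, slope_confounding=0.3
    )
    mnar_dropout = replace(paper_like, dropout_mmse_coef=-0.08)
    ramp = replace(paper_like, arm_effect_shape="ramp")
    return {
        "null": null,
        "paper_like": paper_like,
        "confounded": confounded,
        "mnar_dropout": mnar_dropout,
        "ramp": ramp,
    }
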