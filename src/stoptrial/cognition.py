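"""IPTW-weighted spline mixed-model analysis of cognitive trajectories.

MMSE over follow-up is modelled with a random intercept per trial block and
fixed effects for arm, a quadratic truncated-power spline in months since
baseline with a knot at eight months (so that a rapid symptomatic change
after discontinuation and the long-run slope can differ), arm-by-spline
interactions, and trial-month dummies.  Change from baseline is a pure
spline contrast, so the arm difference at t months and its conversion into
a delay-in-decline are closed-form functions of the fitted coefficients;
inference resamples patients (all their trial blocks together) and refits
the propensity weights inside every bootstrap replicate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from stoptrial import schema
from stoptrial._mixed import MixedFit, fit_weighted_random_intercept
from stoptrial.trials import WeightedTrialDataset
from stoptrial.weighting import fit_propensity, stabilized_weights

logger = logging.getLogger(__name__)


@dataclass
class SplineBasis:
    """Quadratic truncated-power spline basis with a single knot (months).

    ``design(t) = [t, t^2, max(0, t - knot)^2]`` -- continuous with a
    continuous first derivative at the knot, and zero at t = 0 so that
    modelled change from baseline vanishes at baseline by construction.
    """

    knot: float = 8.0

    def design(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return np.stack(
            [t, t**2, np.clip(t - self.knot, 0.0, None) ** 2], axis=-1
        )

    @property
    def names(self) -> list[str]:
        return ["t", "t2", f"t_knot{self.knot:g}2"]


@dataclass
class TrajectoryModel:
    """Fitted weighted spline mixed model for MMSE trajectories."""

    beta: pd.Series
    sigma_b: float
    sigma_e: float
    basis: SplineBasis
    neg2ll: float
    n_obs: int
    n_clusters: int
    trial_month_levels: list[int] = field(default_factory=list)

    @property
    def basis_coefficients(self) -> np.ndarray:
        return self.beta[self.basis.names].to_numpy()

    @property
    def interaction_coefficients(self) -> np.ndarray:
        return self.beta[[f"arm_x_{n}" for n in self.basis.names]].to_numpy()


def _trajectory_design(
    long: pd.DataFrame,
    basis: SplineBasis,
    covariates: Sequence[str] = (),
) -> pd.DataFrame:
    B = basis.design(long["t"].to_numpy(float))
    X = pd.DataFrame({"const": np.ones(len(long))})
    X["arm"] = long["arm"].to_numpy(float)
    for j, name in enumerate(basis.names):
        X[name] = B[:, j]
    for j, name in enumerate(basis.names):
        X[f"arm_x_{name}"] = X["arm"].to_numpy() * B[:, j]
    tm = long["trial_month"].astype(int)
    for level in sorted(tm.unique())[1:]:
        X[f"trial_month_{level}"] = (tm == level).astype(float).to_numpy()
    for c in covariates:
        X[c] = long[c].astype(float).to_numpy()
    return X


def design_for_model(model: "TrajectoryModel", df: pd.DataFrame) -> np.ndarray:
    """Design matrix for new rows, with columns exactly as the fitted model.

    Covariate-adjusted models are supported as long as ``df`` carries the
    adjustment columns; trial-month dummies follow the fitted levels.
    """
    B = model.basis.design(df["t"].to_numpy(float))
    arm = df["arm"].to_numpy(float)
    cols: dict[str, np.ndarray] = {"const": np.ones(len(df)), "arm": arm}
    for j, name in enumerate(model.basis.names):
        cols[name] = B[:, j]
        cols[f"arm_x_{name}"] = arm * B[:, j]
    tm = df["trial_month"].to_numpy(int)
    for level in model.trial_month_levels:
        cols[f"trial_month_{level}"] = (tm == level).astype(float)
    out = np.empty((len(df), len(model.beta)))
    for j, name in enumerate(model.beta.index):
        out[:, j] = cols[name] if name in cols else df[name].to_numpy(float)
    return out


def fit_trajectory(
    long: pd.DataFrame,
    basis: SplineBasis | None = None,
    covariates: Sequence[str] = (),
    row_weight_col: str | None = None,
    start: tuple[float, float] | None = None,
    strict: bool = True,
) -> TrajectoryModel:
    """Fit the weighted random-intercept spline model.

    Parameters
    ----------
    long
        Long table with one row per MMSE observation: ``record_id`` (the
        random-intercept cluster), ``t``, ``arm``, ``trial_month``,
        ``mmse``, and ``weight`` (block-level analysis weight).  Blocks with
        baseline-only data contribute through their t = 0 row; no imputation
        of missing follow-up is performed.
    basis
        Spline basis; defaults to the 8-month-knot quadratic spline.
    covariates
        Optional baseline covariates to adjust for in the outcome model in
        addition to weighting (off by default: adjustment is by weighting).
    row_weight_col
        Optional column of observation-level weights (IPCW).
    start
        Warm start ``(sigma_b^2, sigma_e^2)`` for the variance components.
    strict
        Raise on optimizer non-convergence (default); the bootstrap path
        relaxes this since its failure budget is policed separately.
    """
    basis = basis or SplineBasis()
    data = long[long["mmse"].notna()]
    X = _trajectory_design(data, basis, covariates)
    fit: MixedFit = fit_weighted_random_intercept(
        X.to_numpy(),
        data["mmse"].to_numpy(float),
        data["record_id"].to_numpy(),
        cluster_weights=data["weight"].to_numpy(float)
        if "weight" in data.columns
        else None,
        row_weights=data[row_weight_col].to_numpy(float)
        if row_weight_col
        else None,
        start=start,
    )
    if strict and not fit.converged:
        raise ValueError(
            "trajectory model did not converge "
            f"(-2ll={fit.neg2ll:.2f}, n={fit.n_obs}, K={fit.n_clusters})"
        )
    return TrajectoryModel(
        beta=pd.Series(fit.beta, index=X.columns),
        sigma_b=fit.sigma_b,
        sigma_e=fit.sigma_e,
        basis=basis,
        neg2ll=fit.neg2ll,
        n_obs=fit.n_obs,
        n_clusters=fit.n_clusters,
        trial_month_levels=sorted(
            int(c.rsplit("_", 1)[1])
            for c in X.columns
            if c.startswith("trial_month_")
        ),
    )


def predict_change(
    model: TrajectoryModel, arm: int, t_grid: np.ndarray
) -> np.ndarray:
    """Mean change from baseline at each t for one arm.

    Change from baseline is the spline contrast ``B(t) (beta_basis +
    arm * beta_interaction)``; the arm main effect and trial-month terms
    are baseline-level quantities and cancel, so no further standardization
    over the trial-month distribution is needed.  ``change(arm, 0) = 0``
    by construction.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if (t_grid < 0).any():
        raise ValueError("prediction times must be nonnegative")
    B = model.basis.design(t_grid)
    coef = model.basis_coefficients + arm * model.interaction_coefficients
    return B @ coef


def decline_difference(
    change_continue: float | np.ndarray, change_discontinue: float | np.ndarray
):
    """Between-group difference in decline, positive when discontinuers
    decline more: ``change(continue) - change(discontinue)``."""
    return np.asarray(change_continue) - np.asarray(change_discontinue)


def group_difference(model: TrajectoryModel, t: float) -> float:
    """Extra decline of discontinuers at t months (MMSE points, positive)."""
    c0 = predict_change(model, 0, np.array([t]))[0]
    c1 = predict_change(model, 1, np.array([t]))[0]
    return float(decline_difference(c0, c1))


class DelayNotReached(ValueError):
    """The continuer trajectory never reaches the discontinuer level."""

    def __init__(self, horizon: float):
        self.horizon = horizon
        super().__init__(
            f"continuer decline does not reach the discontinuer level "
            f"within the {horizon:g}-month horizon"
        )


def delay_from_curves(
    change_continue: Callable[[float], float],
    target: float,
    t: float,
    horizon: float = 72.0,
    step: float = 1.0,
) -> float:
    """Months after t at which the continuer curve first reaches ``target``.

    Brackets on a monthly grid and interpolates linearly inside the
    bracketing month.  Raises :class:`DelayNotReached` if the level is not
    reached by ``horizon``.
    """
    prev_t, prev_v = t, float(change_continue(t))
    if prev_v <= target:
        return 0.0
    grid = np.arange(t + step, horizon + step / 2, step)
    for tt in grid:
        v = float(change_continue(tt))
        if v <= target:
            frac = (prev_v - target) / (prev_v - v) if v != prev_v else 1.0
            return float(prev_t + frac * (tt - prev_t) - t)
        prev_t, prev_v = tt, v
    raise DelayNotReached(horizon)


def delay_in_decline(
    model: TrajectoryModel, t: float, horizon: float = 72.0
) -> float:
    """Delay (months) by which continuers lag discontinuers' decline at t."""
    target = float(predict_change(model, 1, np.array([t]))[0])
    return delay_from_curves(
        lambda tt: float(predict_change(model, 0, np.array([tt]))[0]),
        target,
        t,
        horizon=horizon,
    )


# ---------------------------------------------------------------------------
# cluster bootstrap
# ---------------------------------------------------------------------------


@dataclass
class BootstrapResult:
    """Point estimate with percentile CI and p-value from B replicates."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    B: int
    method: str = "percentile"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"{self.estimate:.2f} [{self.ci_low:.2f}, {self.ci_high:.2f}] "
            f"(p={self.p_value:.3g}, B={self.B}, {self.method})"
        )


def summarize_bootstrap(
    estimate: float,
    replicates: np.ndarray,
    null_value: float = 0.0,
    skew_threshold: float = 0.5,
) -> BootstrapResult:
    """Percentile CI; p-value by bootstrap-t when the replicate distribution
    is near-symmetric (|skewness| < 0.5), else by the percentile method."""
    reps = np.asarray(replicates, dtype=float)
    reps = reps[np.isfinite(reps)]
    B = len(reps)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    se = float(reps.std(ddof=1)) if B > 1 else np.nan
    skew = float(sps.skew(reps)) if (B > 2 and se > 0) else 0.0
    if abs(skew) < skew_threshold and se > 0:
        z = (estimate - null_value) / se
        p = 2.0 * (1.0 - sps.norm.cdf(abs(z)))
        method = "bootstrap-t"
    else:
        frac_low = np.mean(reps <= null_value)
        frac_high = np.mean(reps >= null_value)
        p = min(1.0, 2.0 * min(frac_low, frac_high))
        method = "percentile"
    p = max(p, 1.0 / max(B, 1))
    return BootstrapResult(
        estimate=float(estimate),
        ci_low=float(lo),
        ci_high=float(hi),
        p_value=float(p),
        B=B,
        method=method,
    )


def iptw_weighter(
    covariates: Sequence[str] | None = None,
    include_trial_month: bool = True,
    truncate: tuple[float, float] | None = None,
) -> Callable[[pd.DataFrame, np.ndarray], np.ndarray]:
    """Build the default reweighting callback for the cluster bootstrap:
    refit the propensity model on the resampled records (with multiplicity
    as frequency weights) and return fresh stabilized weights."""

    def weighter(records: pd.DataFrame, freq: np.ndarray) -> np.ndarray:
        model = fit_propensity(
            records,
            covariates=list(covariates) if covariates else None,
            include_trial_month=include_trial_month,
            freq_weights=freq,
        )
        return stabilized_weights(
            model, records, truncate=truncate, freq_weights=freq
        )

    return weighter


def cluster_bootstrap(
    dataset: WeightedTrialDataset,
    statistic: Callable[[WeightedTrialDataset, np.ndarray], np.ndarray],
    B: int = 500,
    seed: int = 0,
    weighter: Callable[[pd.DataFrame, np.ndarray], np.ndarray] | None = None,
    max_failure_rate: float = 0.05,
) -> np.ndarray:
    """Nonparametric bootstrap resampling whole patients.

    The resampling unit is the unique patient: all of a patient's trial
    blocks enter a replicate with the patient's multiplicity, which accounts
    for repeated inclusion across the sequential trials.  ``weighter`` (by
    default: none, keeping the dataset's stored weights) is called per
    replicate with the records and multiplicity so that propensity-weight
    uncertainty propagates; the statistic receives the dataset and the
    per-record effective weights (multiplicity times analysis weight; zero
    drops a block).

    Returns an array of replicate values, shape (B,) or (B, k) for vector
    statistics.  Raises if more than ``max_failure_rate`` of replicates fail.
    """
    if B < 50:
        warnings.warn(f"B={B} bootstrap replicates is low", stacklevel=2)
    rng = np.random.default_rng(seed)
    patients = dataset.records["patient_id"].to_numpy()
    unique = pd.unique(patients)
    n_pat = len(unique)
    pat_idx = pd.Series(np.arange(n_pat), index=unique)
    rec_pat = pat_idx[patients].to_numpy()
    base_w = dataset.records["weight"].to_numpy(float)

    out, failures = [], 0
    for _ in range(B):
        draws = rng.integers(0, n_pat, size=n_pat)
        mult = np.bincount(draws, minlength=n_pat)[rec_pat].astype(float)
        try:
            if weighter is not None:
                keep = mult > 0
                sw = np.zeros(len(mult))
                sw[keep] = weighter(
                    dataset.records[keep], mult[keep]
                )
                eff = mult * sw
            else:
                eff = mult * base_w
            out.append(np.atleast_1d(statistic(dataset, eff)))
        except Exception as exc:  # noqa: BLE001 - failure budget below
            failures += 1
            logger.debug("bootstrap replicate failed: %s", exc)
    if failures > max_failure_rate * B:
        raise RuntimeError(
            f"{failures}/{B} bootstrap replicates failed "
            f"(budget {max_failure_rate:.0%})"
        )
    return np.squeeze(np.array(out))
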