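"""Propensity scores, stabilized IPTW, balance diagnostics, and IPCW.

Confounding by indication is addressed by weighting each block by the
inverse of its propensity score -- the probability of the treatment
strategy actually followed, given baseline covariates -- stabilized by the
marginal probability of that strategy so that weights average one.
Adequacy is judged by absolute standardized mean differences below 0.1
across all covariates.  For the dropout sensitivity analysis, inverse
probability of censoring weights reweight the remaining follow-up of blocks
similar to those lost.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from stoptrial import schema
from stoptrial.trials import WeightedTrialDataset

logger = logging.getLogger(__name__)

_EPS = 1e-10


def _propensity_design(
    records: pd.DataFrame,
    covariates: list[str],
    include_trial_month: bool = True,
    trial_month_terms: str = "quadratic",
) -> pd.DataFrame:
    """Main-effects design matrix with trial month as a baseline covariate.

    Trial month enters as linear + quadratic terms by default: stopping is
    typically concentrated early in the enrolment window, and month dummies
    then separate (some months hold a single arm).  ``"dummies"`` is
    available when every month carries both arms.
    """
    X = pd.DataFrame({"const": np.ones(len(records))}, index=records.index)
    for c in covariates:
        X[c] = records[c].astype(float).to_numpy()
    if include_trial_month:
        tm = records["trial_month"].astype(int)
        if trial_month_terms == "dummies":
            for level in sorted(tm.unique())[1:]:
                X[f"trial_month_{level}"] = (
                    (tm == level).astype(float).to_numpy()
                )
        else:
            X["trial_month"] = tm.astype(float).to_numpy()
            X["trial_month_sq"] = (tm.astype(float) ** 2).to_numpy()
    return X


@dataclass
class PropensityModel:
    """Fitted propensity model: Pr(arm = discontinue | covariates)."""

    params: pd.Series
    scores: np.ndarray
    covariates: list[str]
    include_trial_month: bool = True

    @property
    def min_score(self) -> float:
        return float(self.scores.min())

    @property
    def max_score(self) -> float:
        return float(self.scores.max())


def fit_propensity(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    include_trial_month: bool = True,
    trial_month_terms: str = "quadratic",
    freq_weights: np.ndarray | None = None,
) -> PropensityModel:
    """Fit a main-effects logistic propensity model pooled across trials.

    Parameters
    ----------
    records
        Baseline-record table (one row per block) with complete covariates.
    covariates
        Covariate columns; defaults to the cognition covariate set.
    include_trial_month
        Carry the trial month as a baseline covariate (default), per the
        pooled sequential-trials design; ``trial_month_terms`` selects
        linear+quadratic terms (default) or month dummies.
    freq_weights
        Optional per-record frequency weights (used by the cluster
        bootstrap, where resampled patients appear with multiplicity).

    Raises
    ------
    ValueError
        If all records are in one arm, or the fit is separated (some fitted
        score is numerically 0 or 1); the error names the covariate with the
        largest coefficient magnitude as the likely separator.
    """
    covariates = covariates or [
        c for c in schema.COGNITION_COVARIATES if c in records.columns
    ]
    arm = records["arm"].to_numpy(int)
    if arm.min() == arm.max():
        raise ValueError("all records in one arm; propensity model undefined")
    missing = records[covariates].isna().any(axis=1)
    if missing.any():
        # complete-case is enforced upstream; guard against silent NaNs here
        raise ValueError(
            f"{int(missing.sum())} records have missing covariates; "
            "drop or impute before fitting the propensity model"
        )
    # A binary covariate with an empty arm-by-level cell cannot be fitted by
    # maximum likelihood (its coefficient diverges).  When the cell is empty
    # merely because the covariate is sparse, drop it with a log note; when
    # a well-populated covariate separates the arms, that is a data problem
    # the caller must see.
    pbar = arm.mean()
    usable = []
    for c in covariates:
        x = records[c].to_numpy(float)
        if set(np.unique(x)) <= {0.0, 1.0}:
            cells = [
                ((arm == a) & (x == v)).sum() for a in (0, 1) for v in (0, 1)
            ]
            if min(cells) == 0:
                rare = min((x == 1).sum(), (x == 0).sum())
                if rare * min(pbar, 1 - pbar) < 10:
                    logger.info(
                        "dropping sparse covariate %r from propensity model "
                        "(empty arm-by-level cell)", c
                    )
                    continue
                raise ValueError(
                    f"propensity model separated: covariate {c!r} has an "
                    "empty arm-by-level cell"
                )
        usable.append(c)
    covariates = usable
    X = _propensity_design(
        records, covariates, include_trial_month, trial_month_terms
    )
    glm = sm.GLM(
        arm,
        X,
        family=sm.families.Binomial(),
        freq_weights=freq_weights,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = glm.fit(maxiter=100)
    scores = np.asarray(res.predict(X))
    # a score of numerically 0 (1) breaks the weight only for records that
    # actually are in arm 1 (0); elsewhere the stabilized weight stays bounded
    bad = ((scores < _EPS) & (arm == 1)) | ((scores > 1 - _EPS) & (arm == 0))
    if bad.any():
        coef = res.params.drop("const", errors="ignore")
        worst = coef.abs().idxmax()
        raise ValueError(
            f"propensity model separated (fitted scores at 0/1 on "
            f"{int(bad.sum())} records); largest coefficient on {worst!r}"
        )
    scores = np.clip(scores, _EPS / 2, 1 - _EPS / 2)
    return PropensityModel(
        params=res.params,
        scores=scores,
        covariates=list(covariates),
        include_trial_month=include_trial_month,
    )


def stabilized_weights(
    model: PropensityModel,
    records: pd.DataFrame,
    truncate: tuple[float, float] | None = None,
    freq_weights: np.ndarray | None = None,
) -> np.ndarray:
    """Stabilized IPTW: marginal strategy probability over the propensity.

    ``sw = pbar / e`` for discontinuers and ``(1 - pbar) / (1 - e)`` for
    continuers, where ``pbar`` is the marginal discontinuation proportion.
    ``truncate`` optionally clips weights at symmetric percentiles
    (e.g. ``(1, 99)``); off by default.
    """
    arm = records["arm"].to_numpy(int)
    e = model.scores
    if (e <= 0).any() or (e >= 1).any():
        raise ValueError("propensity scores must lie strictly inside (0, 1)")
    fw = np.ones(len(arm)) if freq_weights is None else np.asarray(freq_weights)
    pbar = float(np.sum(fw * arm) / np.sum(fw))
    sw = np.where(arm == 1, pbar / e, (1.0 - pbar) / (1.0 - e))
    if truncate is not None:
        lo, hi = np.percentile(sw, truncate)
        sw = np.clip(sw, lo, hi)
    return sw


def standardized_mean_difference(
    covariate: np.ndarray,
    arm: np.ndarray,
    weights: np.ndarray | None = None,
    binary: bool | None = None,
) -> float:
    """Weighted standardized mean difference between arms (arm 1 minus arm 0).

    Continuous covariates use frequency-weighted means and variances,
    ``smd = (m1 - m0) / sqrt((v1 + v0) / 2)``; binary covariates use the
    proportion-based variance ``p (1 - p)``.
    """
    x = np.asarray(covariate, dtype=float)
    a = np.asarray(arm, dtype=int)
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=float)
    if binary is None:
        binary = set(np.unique(x)) <= {0.0, 1.0}
    stats = []
    for g in (1, 0):
        xg, wg = x[a == g], w[a == g]
        mu = np.average(xg, weights=wg)
        if binary:
            var = mu * (1.0 - mu)
        else:
            var = np.average((xg - mu) ** 2, weights=wg)
        stats.append((mu, var))
    (m1, v1), (m0, v0) = stats
    pooled = (v1 + v0) / 2.0
    if pooled <= 0:
        if np.isclose(m1, m0):
            return 0.0
        raise ValueError("degenerate covariate: zero variance but unequal means")
    return float((m1 - m0) / np.sqrt(pooled))


@dataclass
class BalanceReport:
    """Per-covariate SMDs before and after weighting."""

    table: pd.DataFrame
    threshold: float = 0.1

    @property
    def max_abs_smd_weighted(self) -> float:
        return float(self.table["smd_weighted"].abs().max())

    @property
    def max_abs_smd_unweighted(self) -> float:
        return float(self.table["smd_unweighted"].abs().max())

    @property
    def acceptable(self) -> bool:
        return self.max_abs_smd_weighted < self.threshold

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def balance_report(
    records: pd.DataFrame,
    covariates: list[str],
    weights: np.ndarray,
    threshold: float = 0.1,
) -> BalanceReport:
    """Compute SMDs for every covariate before and after weighting."""
    arm = records["arm"].to_numpy(int)
    rows = []
    for c in covariates:
        x = records[c].to_numpy(float)
        binary = c in schema.BINARY_COVARIATES
        rows.append(
            {
                "covariate": c,
                "smd_unweighted": standardized_mean_difference(
                    x, arm, binary=binary
                ),
                "smd_weighted": standardized_mean_difference(
                    x, arm, weights=weights, binary=binary
                ),
            }
        )
    return BalanceReport(table=pd.DataFrame(rows), threshold=threshold)


def positivity_summary(model: PropensityModel) -> dict[str, float]:
    """Report score range and warn on near-violations of positivity."""
    n_low = int((model.scores < 0.01).sum())
    n_high = int((model.scores > 0.99).sum())
    if n_low or n_high:
        warnings.warn(
            f"propensity scores near 0/1: {n_low} below 0.01, "
            f"{n_high} above 0.99",
            stacklevel=2,
        )
    return {
        "min_score": model.min_score,
        "max_score": model.max_score,
        "n_below_0.01": n_low,
        "n_above_0.99": n_high,
    }


# ---------------------------------------------------------------------------
# inverse probability of censoring weighting (dropout sensitivity analysis)
# ---------------------------------------------------------------------------


def censor_table(dataset: WeightedTrialDataset, horizon: int = 48) -> pd.DataFrame:
    """Person-month table of remaining-in-follow-up indicators.

    A block is observed until its last visit (death ends observation the
    same way: with no linkage inside the cognition registry, deaths are
    treated like other dropouts here).  Rows run from month 1 to the first
    censored month inclusive, bounded by ``horizon`` and administrative
    censoring; ``uncensored`` is 1 while the block remains in follow-up.
    """
    rec = dataset.records
    t_admin = np.minimum(rec["t_admin"].to_numpy(float), float(horizon))
    t_obs = np.nan_to_num(rec["t_last_visit"].to_numpy(float), nan=0.0)
    t_obs = np.minimum(t_obs, t_admin)
    n_months = np.minimum(t_obs + 1, t_admin).astype(int)
    n_months = np.maximum(n_months, 1)
    idx = np.repeat(np.arange(len(rec)), n_months)
    m = np.concatenate([np.arange(1, n + 1) for n in n_months])
    uncens = (m <= t_obs[idx]).astype(int)
    return pd.DataFrame(
        {
            "record_id": rec["record_id"].to_numpy()[idx],
            "trial_month": rec["trial_month"].to_numpy()[idx],
            "arm": rec["arm"].to_numpy()[idx],
            "m": m,
            "uncensored": uncens,
        }
    )


def censoring_weights(
    dataset: WeightedTrialDataset,
    covariates: list[str] | None = None,
    horizon: int = 48,
    freq_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stabilized inverse-probability-of-censoring weights per (block, month).

    The denominator models Pr(still in follow-up at month m) by pooled
    logistic regression on baseline covariates, arm, and linear + quadratic
    time; the numerator uses arm and time only.  The weight at month ``t``
    is the cumulative product of numerator over denominator probabilities
    up to ``t``, to be multiplied into the block's analysis weight at its
    observation times.

    Returns a table ``(record_id, m, ipcw)`` for months ``1..horizon``.
    """
    covariates = covariates or [
        c for c in schema.COGNITION_COVARIATES if c in dataset.records.columns
    ]
    ct = censor_table(dataset, horizon=horizon)
    if ct.empty or ct["uncensored"].sum() == 0:
        raise ValueError("no uncensored person-months to model")
    if (ct.groupby("m")["uncensored"].max() == 0).any():
        raise ValueError("some months have no uncensored records")
    if (ct["uncensored"] == 1).all():
        # nothing to correct: no loss to follow-up before the horizon
        return ct.assign(ipcw=1.0)[["record_id", "m", "ipcw"]]
    ct = ct.merge(
        dataset.records[["record_id"] + covariates], on="record_id", how="left"
    )
    fw = None
    if freq_weights is not None:
        per_rec = pd.Series(
            np.asarray(freq_weights, float),
            index=dataset.records["record_id"].to_numpy(),
        )
        fw = per_rec[ct["record_id"]].to_numpy()
        ct = ct[fw > 0]
        fw = fw[fw > 0]
    mm = ct["m"].to_numpy(float)
    X_den = pd.DataFrame(
        {
            "const": 1.0,
            "arm": ct["arm"].to_numpy(float),
            "m": mm,
            "m2": mm**2,
        }
    )
    for c in covariates:
        X_den[c] = ct[c].to_numpy(float)
    X_num = X_den[["const", "arm", "m", "m2"]]
    y = ct["uncensored"].to_numpy(int)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_den = np.asarray(
            sm.GLM(y, X_den, family=sm.families.Binomial(), freq_weights=fw)
            .fit()
            .predict(X_den)
        )
        p_num = np.asarray(
            sm.GLM(y, X_num, family=sm.families.Binomial(), freq_weights=fw)
            .fit()
            .predict(X_num)
        )
    ct["ratio"] = p_num / p_den
    # cumulative product along months within each block
    ct["ipcw"] = (
        np.log(ct["ratio"]).groupby(ct["record_id"]).cumsum().pipe(np.exp)
    )
    return ct[["record_id", "m", "ipcw"]]


def apply_ipcw(
    dataset: WeightedTrialDataset, ipcw: pd.DataFrame
) -> pd.DataFrame:
    """Long table whose row weights fold in the IPCW at each visit time.

    Baseline rows (t = 0) keep the block's IPTW weight; each follow-up row
    at time ``t`` is weighted by ``IPTW x ipcw(record, t)``.
    """
    long = dataset.long_with_weights()
    long = long.merge(
        ipcw.rename(columns={"m": "t"}), on=["record_id", "t"], how="left"
    )
    long["ipcw"] = long["ipcw"].fillna(1.0)
    long["weight"] = long["weight"] * long["ipcw"]
    return long.drop(columns="ipcw")
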