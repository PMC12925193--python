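"""End-to-end emulation pipelines: screen, expand, weight, analyse.

These functions chain the stage modules into the two emulations (cognitive
trajectory and mortality) and the sensitivity analyses, with patient-level
cluster-bootstrap inference in which the propensity (and, when active, the
censoring) weights are re-estimated inside every replicate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from stoptrial import cognition as cg
from stoptrial import mortality as mt
from stoptrial import schema, weighting
from stoptrial.cohort import (
    EligibilityConfig,
    ScreeningLog,
    apply_subgroup_filter,
    screen_eligibility,
)
from stoptrial.mnar import (
    CompletedOutcomes,
    DeltaScan,
    find_tipping_delta,
    impute_mar_outcomes,
)
from stoptrial.trials import (
    WeightedTrialDataset,
    expand_sequential_trials,
    person_month_expand,
)

logger = logging.getLogger(__name__)


@dataclass
class EmulationConfig:
    """Settings shared by the cognition and mortality emulations."""

    eligibility: EligibilityConfig = field(default_factory=EligibilityConfig)
    subgroup: str = "none"
    admin_end: int = 83
    cognition_horizon: int = 48
    mortality_horizon: int = 60
    covariates: list[str] | None = None
    bootstrap_B: int = 500
    seed: int = 0
    ipcw: bool = False
    t_points: tuple[int, ...] = (12, 24, 36, 48)
    rr_points: tuple[int, ...] = (12, 24, 36, 48, 60)
    weight_truncate: tuple[float, float] | None = None
    outcome_covariate_adjustment: bool = False
    compute_delay: bool = True

    def resolved_covariates(self, analysis: str) -> list[str]:
        if self.covariates is not None:
            return list(self.covariates)
        if analysis == "mortality":
            return list(schema.MORTALITY_COVARIATES)
        return list(schema.COGNITION_COVARIATES)


@dataclass
class PreparedCohort:
    dataset: WeightedTrialDataset
    log: ScreeningLog
    propensity: weighting.PropensityModel
    balance: weighting.BalanceReport
    covariates: list[str]


def prepare_cohort(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    config: EmulationConfig,
    analysis: str = "cognition",
) -> PreparedCohort:
    """Screen, subgroup-filter, expand, and weight a registry extract.

    The DOMINO replication re-screens with the 5-13 MMSE band (all other
    criteria unchanged) before the subgroup filter is applied.
    """
    elig = config.eligibility
    if config.subgroup == "domino":
        elig = replace(elig, mmse_min=5, mmse_max=13)
    records, log = screen_eligibility(patients, visits, elig)
    records = apply_subgroup_filter(records, config.subgroup)
    if records.empty:
        raise ValueError("no eligible records after screening/filtering")
    covariates = [
        c
        for c in config.resolved_covariates(analysis)
        if c in records.columns or c == "baseline_mmse"
    ]
    dataset = expand_sequential_trials(
        records, visits, admin_end=config.admin_end,
        window_months=elig.window_months,
    )
    prop = weighting.fit_propensity(dataset.records, covariates=covariates)
    sw = weighting.stabilized_weights(
        prop, dataset.records, truncate=config.weight_truncate
    )
    dataset = dataset.with_weights(sw)
    balance = weighting.balance_report(dataset.records, covariates, sw)
    if not balance.acceptable:
        logger.warning(
            "max |SMD| after weighting = %.3f (threshold %.2f)",
            balance.max_abs_smd_weighted,
            balance.threshold,
        )
    return PreparedCohort(
        dataset=dataset,
        log=log,
        propensity=prop,
        balance=balance,
        covariates=covariates,
    )


def _cognition_long(
    dataset: WeightedTrialDataset,
    config: EmulationConfig,
    ipcw_table: pd.DataFrame | None,
) -> pd.DataFrame:
    long = dataset.long_with_weights()
    long = long[long["t"] <= config.cognition_horizon]
    if ipcw_table is not None:
        long = long.merge(
            ipcw_table.rename(columns={"m": "t", "ipcw": "row_w"}),
            on=["record_id", "t"],
            how="left",
        )
        long["row_w"] = long["row_w"].fillna(1.0)
    return long


@dataclass
class CognitionReport:
    model: cg.TrajectoryModel
    differences: dict[int, cg.BootstrapResult]
    delays: dict[int, cg.BootstrapResult]
    changes: pd.DataFrame  # arm x month predicted change from baseline
    balance: weighting.BalanceReport
    log: ScreeningLog
    n_records: int
    n_patients: int

    def contrast_table(self) -> pd.DataFrame:
        rows = []
        for t, res in self.differences.items():
            row = {
                "t_months": t,
                "difference": res.estimate,
                "diff_ci_low": res.ci_low,
                "diff_ci_high": res.ci_high,
                "diff_p": res.p_value,
            }
            if t in self.delays:
                d = self.delays[t]
                row.update(
                    delay_months=d.estimate,
                    delay_ci_low=d.ci_low,
                    delay_ci_high=d.ci_high,
                )
            rows.append(row)
        return pd.DataFrame(rows)


def run_cognition(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    config: EmulationConfig | None = None,
) -> CognitionReport:
    """The cognitive-trajectory emulation with bootstrap inference."""
    config = config or EmulationConfig()
    prep = prepare_cohort(patients, visits, config, analysis="cognition")
    dataset = prep.dataset
    basis = cg.SplineBasis()
    outcome_covs = tuple(prep.covariates) if config.outcome_covariate_adjustment else ()

    ipcw_table = None
    if config.ipcw:
        ipcw_table = weighting.censoring_weights(
            dataset, covariates=prep.covariates,
            horizon=config.cognition_horizon,
        )
    long = _cognition_long(dataset, config, ipcw_table)
    if outcome_covs:
        long = long.merge(
            dataset.records[["record_id", *outcome_covs]],
            on="record_id",
            how="left",
        )
    model = cg.fit_trajectory(
        long,
        basis,
        covariates=outcome_covs,
        row_weight_col="row_w" if config.ipcw else None,
    )
    warm = (model.sigma_b**2, model.sigma_e**2)
    t_points = list(config.t_points)

    def statistic(ds: WeightedTrialDataset, eff: np.ndarray) -> np.ndarray:
        ipcw_b = None
        if config.ipcw:
            ipcw_b = weighting.censoring_weights(
                ds, covariates=prep.covariates,
                horizon=config.cognition_horizon, freq_weights=eff,
            )
        rec_b = ds.records.copy()
        rec_b["weight"] = eff
        lng = _cognition_long(replace(ds, records=rec_b), config, ipcw_b)
        lng = lng[np.asarray(lng["weight"]) > 0]
        if outcome_covs:
            lng = lng.merge(
                ds.records[["record_id", *outcome_covs]],
                on="record_id",
                how="left",
            )
        m = cg.fit_trajectory(
            lng,
            basis,
            covariates=outcome_covs,
            row_weight_col="row_w" if config.ipcw else None,
            start=warm,
            strict=False,
        )
        vals = [cg.group_difference(m, t) for t in t_points]
        if config.compute_delay:
            for t in t_points:
                try:
                    vals.append(cg.delay_in_decline(m, t))
                except cg.DelayNotReached:
                    vals.append(np.nan)
        return np.array(vals)

    reps = np.asarray(
        cg.cluster_bootstrap(
            dataset,
            statistic,
            B=config.bootstrap_B,
            seed=config.seed,
            weighter=cg.iptw_weighter(
                prep.covariates, truncate=config.weight_truncate
            ),
        )
    )
    if reps.ndim == 1:
        reps = reps[:, None]
    differences, delays = {}, {}
    for j, t in enumerate(t_points):
        differences[t] = cg.summarize_bootstrap(
            cg.group_difference(model, t), reps[:, j]
        )
    if config.compute_delay:
        for j, t in enumerate(t_points):
            try:
                est = cg.delay_in_decline(model, t)
            except cg.DelayNotReached:
                est = np.nan
            delays[t] = cg.summarize_bootstrap(est, reps[:, len(t_points) + j])

    months = np.arange(0, config.cognition_horizon + 1)
    changes = pd.DataFrame(
        {
            "t_months": months,
            "change_continue": cg.predict_change(model, 0, months),
            "change_discontinue": cg.predict_change(model, 1, months),
        }
    )
    return CognitionReport(
        model=model,
        differences=differences,
        delays=delays,
        changes=changes,
        balance=prep.balance,
        log=prep.log,
        n_records=dataset.n_records,
        n_patients=dataset.n_patients,
    )


@dataclass
class MortalityReport:
    model: mt.SurvivalModel
    incidence: pd.DataFrame  # per-arm cumulative risk by month
    risk_ratios: dict[int, cg.BootstrapResult]
    balance: weighting.BalanceReport
    log: ScreeningLog
    n_records: int
    n_patients: int

    def rr_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_months": t,
                    "risk_ratio": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p": r.p_value,
                }
                for t, r in self.risk_ratios.items()
            ]
        )


def _pm_weights(
    pm: pd.DataFrame, records: pd.DataFrame, eff: np.ndarray
) -> np.ndarray:
    per_rec = pd.Series(np.asarray(eff, float), index=records["record_id"].to_numpy())
    return per_rec[pm["record_id"]].to_numpy()


def _tm_weights(records: pd.DataFrame, eff: np.ndarray) -> pd.Series:
    return pd.Series(np.asarray(eff, float)).groupby(
        records["trial_month"].to_numpy()
    ).sum()


def run_mortality(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    config: EmulationConfig | None = None,
) -> MortalityReport:
    """The all-cause-mortality emulation with bootstrap inference."""
    config = config or EmulationConfig()
    prep = prepare_cohort(patients, visits, config, analysis="mortality")
    dataset = prep.dataset
    pm = person_month_expand(dataset, horizon=config.mortality_horizon)
    base_w = dataset.records["weight"].to_numpy(float)
    model = mt.fit_pooled_logistic(
        pm, weights=_pm_weights(pm, dataset.records, base_w)
    )
    tmw = _tm_weights(dataset.records, base_w)
    rr_points = [t for t in config.rr_points if t <= config.mortality_horizon]
    warm = model.params.to_numpy()

    # hot path: the bootstrap only changes weights, so the person-month
    # design is built once and each replicate is a warm-started refit
    X_pm = mt.design_matrix(model, pm)
    y_pm = pm["y"].to_numpy(float)
    pos = pd.Series(
        np.arange(dataset.n_records),
        index=dataset.records["record_id"].to_numpy(),
    )[pm["record_id"]].to_numpy()
    tm_arr = dataset.records["trial_month"].to_numpy()

    def statistic(ds: WeightedTrialDataset, eff: np.ndarray) -> np.ndarray:
        beta = mt._weighted_logit_irls(X_pm, y_pm, eff[pos], start=warm)
        m = replace(model, params=pd.Series(beta, index=model.params.index))
        tw = pd.Series(eff).groupby(tm_arr).sum()
        return np.array([mt.risk_ratio(m, t, tw) for t in rr_points])

    reps = np.asarray(
        cg.cluster_bootstrap(
            dataset,
            statistic,
            B=config.bootstrap_B,
            seed=config.seed,
            weighter=cg.iptw_weighter(
                prep.covariates, truncate=config.weight_truncate
            ),
        )
    )
    if reps.ndim == 1:
        reps = reps[:, None]
    risk_ratios = {
        t: cg.summarize_bootstrap(mt.risk_ratio(model, t, tmw), reps[:, j], null_value=1.0)
        for j, t in enumerate(rr_points)
    }
    months = np.arange(1, config.mortality_horizon + 1)
    incidence = pd.DataFrame(
        {
            "m": months,
            "risk_continue": mt.cumulative_incidence(
                model, 0, config.mortality_horizon, tmw
            ),
            "risk_discontinue": mt.cumulative_incidence(
                model, 1, config.mortality_horizon, tmw
            ),
        }
    )
    return MortalityReport(
        model=model,
        incidence=incidence,
        risk_ratios=risk_ratios,
        balance=prep.balance,
        log=prep.log,
        n_records=dataset.n_records,
        n_patients=dataset.n_patients,
    )


def run_tipping_point(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    config: EmulationConfig | None = None,
    target_t: float = 12.0,
    n_imputations: int = 20,
    delta_step: float = 0.5,
    delta_cap: float = 15.0,
) -> tuple[DeltaScan, CompletedOutcomes]:
    """Delta-adjusted pattern-mixture tipping-point analysis at one year."""
    config = config or EmulationConfig()
    prep = prepare_cohort(patients, visits, config, analysis="cognition")
    long = _cognition_long(prep.dataset, config, None)
    model = cg.fit_trajectory(long, cg.SplineBasis())
    completed = impute_mar_outcomes(
        model,
        prep.dataset,
        target_t=target_t,
        n_imputations=n_imputations,
        seed=config.seed,
    )
    scan = find_tipping_delta(
        completed, delta_step=delta_step, delta_cap=delta_cap
    )
    return scan, completed
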