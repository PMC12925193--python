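"""Eligibility screening, discontinuation dating, and arm assignment.

The emulation enrols a patient into a monthly "trial" at every consultation
month, inside a 12-month enrolment window, at which all eligibility criteria
hold: adult age, a recorded Alzheimer's-disease diagnosis at or before the
visit, an MMSE score inside the configured band at the visit itself, ChEI
treatment recorded within the preceding six months, and a follow-up visit no
more than a year later.  Treatment status is interval-censored -- a patient
is seen on treatment at one visit and off treatment at a later one -- so
discontinuation is conservatively dated at the last visit with recorded
treatment; from that month on the patient belongs to the discontinuation arm
for every subsequent enrolment (intention to treat: later restarts are
ignored).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from stoptrial import schema

logger = logging.getLogger(__name__)

SUBGROUP_MODES = ("none", "domino", "mild", "first_only")


@dataclass
class EligibilityConfig:
    """Screening parameters.

    Parameters
    ----------
    window_months
        Length of the enrolment window; baselines fall in months
        ``0 .. window_months - 1``.
    mmse_min, mmse_max
        Inclusive MMSE eligibility band at baseline.
    chei_lookback
        A ChEI-on-treatment record must exist within this many months at or
        before the baseline visit (the baseline visit itself counts).
    max_followup_gap
        Enrolments whose first post-baseline visit is more than this many
        months after baseline are excluded (the discontinuation date would
        otherwise be too uncertain).
    min_age
        Strict lower age bound.
    """

    window_months: int = 12
    mmse_min: int = 10
    mmse_max: int = 30
    chei_lookback: int = 6
    max_followup_gap: int = 12
    min_age: float = 18.0


@dataclass
class ScreeningLog:
    """Flowchart-style exclusion counts from one screening pass."""

    n_patients: int = 0
    n_visits: int = 0
    visits_missing_ad_flag: int = 0
    patients_no_treatment_info: int = 0
    candidate_visits: int = 0
    excluded: dict[str, int] = field(default_factory=dict)
    eligible_records: int = 0
    eligible_patients: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("patients screened", self.n_patients),
            ("visits screened", self.n_visits),
            ("visits skipped: missing AD-diagnosis flag",
             self.visits_missing_ad_flag),
            ("patients dropped: no treatment information",
             self.patients_no_treatment_info),
            ("candidate enrolment visits in window", self.candidate_visits),
        ]
        rows += [(f"excluded: {k}", v) for k, v in self.excluded.items()]
        rows += [
            ("eligible (patient, month) records", self.eligible_records),
            ("eligible patients", self.eligible_patients),
        ]
        return pd.DataFrame(rows, columns=["stage", "count"])


def _validate_visits(visits: pd.DataFrame) -> None:
    if visits.duplicated(subset=["patient_id", "month"]).any():
        raise ValueError("duplicate (patient_id, month) rows in visits table")
    months = visits.groupby("patient_id", sort=False)["month"].diff()
    if (months.dropna() <= 0).any():
        raise ValueError(
            "visits must be sorted by patient with strictly increasing months"
        )


def infer_discontinuation(
    months: np.ndarray, on_chei: np.ndarray
) -> tuple[int, int | None]:
    """Date discontinuation for a single patient's visit sequence.

    Returns ``(arm, assignment_month)`` where ``arm`` is 1 (discontinue) if a
    first record of non-use exists after at least one on-treatment record, in
    which case discontinuation is dated at the month of the last on-treatment
    visit before it (conservative interval-censoring convention); otherwise
    ``(0, None)``.  Any treatment change after the first gap is ignored.

    Raises
    ------
    ValueError
        If the sequence carries no treatment information at all.
    """
    months = np.asarray(months)
    on = np.asarray(on_chei, dtype=float)
    known = ~np.isnan(on)
    if not known.any():
        raise ValueError("visit sequence carries no treatment information")
    months, on = months[known], on[known].astype(bool)
    seen_on = np.maximum.accumulate(np.where(on, 1, 0))
    stop = (~on) & (np.concatenate([[0], seen_on[:-1]]) == 1)
    if not stop.any():
        return 0, None
    k = int(np.argmax(stop))
    prior_on = np.nonzero(on[:k])[0]
    return 1, int(months[prior_on[-1]])


def _discontinuation_table(visits: pd.DataFrame) -> pd.DataFrame:
    """Per-patient discontinuation month (NaN = continuer throughout)."""
    v = visits[~visits["on_chei"].isna()].copy()
    v["on"] = (v["on_chei"].astype(float) > 0).astype(int)
    grp = v.groupby("patient_id", sort=False)
    v["seen_on_before"] = (
        grp["on"].cummax().groupby(v["patient_id"]).shift(1).fillna(0).astype(int)
    )
    # month of the last on-treatment visit so far (months increase, so a
    # group-wise forward fill carries the latest on-treatment month)
    v["last_on_month"] = (
        v["month"].where(v["on"] == 1).groupby(v["patient_id"]).ffill()
    )
    stop = v[(v["on"] == 0) & (v["seen_on_before"] == 1)]
    first_stop = stop.groupby("patient_id", sort=False).first()
    return pd.DataFrame({"disc_month": first_stop["last_on_month"]})


def screen_eligibility(
    patients: pd.DataFrame,
    visits: pd.DataFrame,
    config: EligibilityConfig | None = None,
) -> tuple[pd.DataFrame, ScreeningLog]:
    """Screen a registry extract for eligible (patient, trial month) records.

    Parameters
    ----------
    patients, visits
        Tables following :mod:`stoptrial.schema`.  Visits must be sorted by
        patient and month with no duplicate (patient, month) rows.
    config
        Screening parameters; defaults follow the emulated protocol.

    Returns
    -------
    records, log
        ``records`` holds one row per eligible enrolment: ``patient_id``,
        ``trial_month``, ``arm`` (0 = continue, 1 = discontinue),
        ``baseline_mmse``, the encoded covariates, and ``death_month``.
        ``log`` carries CONSORT-style exclusion counts.
    """
    config = config or EligibilityConfig()
    _validate_visits(visits)
    log = ScreeningLog(
        n_patients=patients["patient_id"].nunique(), n_visits=len(visits)
    )

    v = visits.copy()
    if "ad_diagnosis" not in v.columns:
        raise ValueError("visits table lacks an ad_diagnosis column")
    missing_ad = v["ad_diagnosis"].isna()
    log.visits_missing_ad_flag = int(missing_ad.sum())
    if log.visits_missing_ad_flag:
        logger.info(
            "skipping AD flag on %d visits with missing ad_diagnosis",
            log.visits_missing_ad_flag,
        )
        v.loc[missing_ad, "ad_diagnosis"] = 0

    # patients with no treatment information anywhere are unassignable
    has_info = v.groupby("patient_id", sort=False)["on_chei"].agg(
        lambda s: s.notna().any()
    )
    bad = has_info[~has_info].index
    log.patients_no_treatment_info = len(bad)
    if len(bad):
        logger.info("dropping %d patients without treatment info", len(bad))
        v = v[~v["patient_id"].isin(bad)]

    grp = v.groupby("patient_id", sort=False)
    v["ad_before"] = (
        v["ad_diagnosis"].astype(float).groupby(v["patient_id"]).cummax() > 0
    )
    on = v["on_chei"].astype(float) > 0
    v["last_on_month"] = v["month"].where(on).groupby(v["patient_id"]).ffill()
    v["next_visit_month"] = grp["month"].shift(-1)

    disc = _discontinuation_table(v)
    v = v.merge(disc, left_on="patient_id", right_index=True, how="left")
    v = v.merge(
        patients.set_index("patient_id"),
        left_on="patient_id",
        right_index=True,
        how="left",
    )

    cand = v[(v["month"] >= 0) & (v["month"] < config.window_months)].copy()
    log.candidate_visits = len(cand)

    # hierarchical exclusion counts, one criterion at a time
    checks = [
        ("age <= {:g}".format(config.min_age), cand["age"] > config.min_age),
        ("no AD diagnosis at or before visit", cand["ad_before"]),
        ("no MMSE at visit", cand["mmse"].notna()),
        (
            f"MMSE outside [{config.mmse_min}, {config.mmse_max}]",
            (cand["mmse"] >= config.mmse_min)
            & (cand["mmse"] <= config.mmse_max),
        ),
        (
            f"no ChEI use within {config.chei_lookback} months",
            cand["last_on_month"].notna()
            & (cand["month"] - cand["last_on_month"] <= config.chei_lookback),
        ),
        (
            f"first follow-up visit > {config.max_followup_gap} months away",
            cand["next_visit_month"].notna()
            & (cand["next_visit_month"] - cand["month"]
               <= config.max_followup_gap),
        ),
    ]
    keep = pd.Series(True, index=cand.index)
    for name, ok in checks:
        ok = ok.fillna(False).astype(bool)
        log.excluded[name] = int((keep & ~ok).sum())
        keep &= ok
    cand = cand[keep]

    records = pd.DataFrame(
        {
            "patient_id": cand["patient_id"].to_numpy(),
            "trial_month": cand["month"].astype(int).to_numpy(),
            "arm": (
                cand["disc_month"].notna()
                & (cand["disc_month"] <= cand["month"])
            ).astype(int).to_numpy(),
            "baseline_mmse": cand["mmse"].astype(float).to_numpy(),
        }
    )
    for col in ["age", "sex_female", "mrrc", "nursing_home"] + [
        c for c in schema.MED_FLAGS if c in cand.columns
    ]:
        records[col] = cand[col].to_numpy()
    records["education_secondary"] = (cand["education"] == 1).astype(int).to_numpy()
    records["education_post_secondary"] = (
        cand["education"] == 2
    ).astype(int).to_numpy()
    records["death_month"] = cand["death_month"].to_numpy()
    records = records.reset_index(drop=True)
    records.insert(0, "record_id", np.arange(len(records)))

    log.eligible_records = len(records)
    log.eligible_patients = records["patient_id"].nunique()
    return records, log


def apply_subgroup_filter(records: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Restrict baseline records for the sensitivity analyses.

    Modes: ``none`` (no restriction), ``domino`` (baseline MMSE 5-13, the
    replication of the donepezil-withdrawal trial's band), ``mild``
    (baseline MMSE strictly above 20), ``first_only`` (keep each patient's
    earliest enrolment only).
    """
    if mode not in SUBGROUP_MODES:
        raise ValueError(f"unknown subgroup mode {mode!r}; use {SUBGROUP_MODES}")
    if mode == "none":
        return records
    if mode == "domino":
        keep = (records["baseline_mmse"] >= 5) & (records["baseline_mmse"] <= 13)
        return records[keep].reset_index(drop=True)
    if mode == "mild":
        return records[records["baseline_mmse"] > 20].reset_index(drop=True)
    idx = records.groupby("patient_id", sort=False)["trial_month"].idxmin()
    return records.loc[sorted(idx)].reset_index(drop=True)
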