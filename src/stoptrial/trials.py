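"""Sequential-trial expansion and person-month (discrete-time) tables.

Every eligible (patient, trial month) record becomes one longitudinal block
whose clock starts at its own baseline; the blocks are stacked into a single
dataset with the trial month carried as a baseline covariate.  A patient
eligible at several months therefore participates in several emulated
trials.  The discrete-time mortality analysis additionally needs one row per
(block, follow-up month), produced by :func:`person_month_expand`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd


@dataclass
class WeightedTrialDataset:
    """Stacked sequential-trial data.

    Attributes
    ----------
    records
        One row per (patient, trial month) block: identifiers, arm,
        baseline covariates, ``t_death`` (months from baseline to death,
        NaN if none inside the administrative window), ``t_admin`` (months
        to administrative censoring), ``t_last_visit`` (months to the last
        observed visit, NaN if none) and the analysis ``weight``
        (1.0 until the weighting stage fills it).
    long
        One row per MMSE observation: ``record_id``, ``patient_id``,
        ``trial_month``, ``arm``, ``t`` (months since block baseline,
        with a ``t = 0`` row holding the baseline MMSE), ``mmse``.
    admin_end
        Administrative end of follow-up, as a calendar-month index.
    """

    records: pd.DataFrame
    long: pd.DataFrame
    admin_end: int

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def n_patients(self) -> int:
        return self.records["patient_id"].nunique()

    def with_weights(self, weights: np.ndarray) -> "WeightedTrialDataset":
        """Return a copy whose records carry the given analysis weights."""
        w = np.asarray(weights, dtype=float)
        if len(w) != len(self.records):
            raise ValueError("one weight per record required")
        if (w <= 0).any():
            raise ValueError("weights must be strictly positive")
        rec = self.records.copy()
        rec["weight"] = w
        return replace(self, records=rec)

    def long_with_weights(self) -> pd.DataFrame:
        """Long table with each block's record-level weight merged in."""
        return self.long.merge(
            self.records[["record_id", "weight"]], on="record_id", how="left"
        )


def expand_sequential_trials(
    baseline_records: pd.DataFrame,
    visits: pd.DataFrame,
    admin_end: int,
    window_months: int = 12,
) -> WeightedTrialDataset:
    """Expand eligible baseline records into stacked per-trial blocks.

    Parameters
    ----------
    baseline_records
        Output of :func:`stoptrial.cohort.screen_eligibility` (optionally
        subgroup-filtered).  Must carry ``record_id``.
    visits
        The registry visits table the records were screened from.
    admin_end
        Administrative censoring month (calendar index).  Follow-up of every
        block is truncated at ``min(death, admin_end)``.
    window_months
        Enrolment-window length, used only to validate ``admin_end``.
    """
    if admin_end < window_months:
        raise ValueError(
            f"administrative end ({admin_end}) precedes the enrolment window"
        )
    rec = baseline_records.copy().reset_index(drop=True)
    if rec["record_id"].duplicated().any():
        raise ValueError("duplicate record_id in baseline records")

    death = rec["death_month"].astype(float)
    t_death = death - rec["trial_month"]
    t_death[death > admin_end] = np.nan
    rec["t_death"] = t_death
    rec["t_admin"] = float(admin_end) - rec["trial_month"]

    key = rec[["record_id", "patient_id", "trial_month", "arm"]]
    merged = key.merge(
        visits[["patient_id", "month", "mmse"]], on="patient_id", how="left"
    )
    merged["t"] = merged["month"] - merged["trial_month"]
    fup = merged[(merged["t"] > 0) & (merged["month"] <= admin_end)]

    # months to the last visit of any kind (censoring model anchor)
    last = fup.groupby("record_id")["t"].max()
    rec["t_last_visit"] = rec["record_id"].map(last)

    obs = fup[fup["mmse"].notna()]
    # duplicate months per patient are rejected upstream; keep first defensively
    obs = obs.drop_duplicates(subset=["record_id", "t"], keep="first")

    base_rows = pd.DataFrame(
        {
            "record_id": rec["record_id"],
            "patient_id": rec["patient_id"],
            "trial_month": rec["trial_month"],
            "arm": rec["arm"],
            "t": 0,
            "mmse": rec["baseline_mmse"].astype(float),
        }
    )
    long = pd.concat(
        [
            base_rows,
            obs[["record_id", "patient_id", "trial_month", "arm", "t"]].assign(
                mmse=obs["mmse"].astype(float)
            ),
        ],
        ignore_index=True,
    ).sort_values(["record_id", "t"], kind="stable").reset_index(drop=True)

    rec["weight"] = 1.0
    return WeightedTrialDataset(records=rec, long=long, admin_end=int(admin_end))


def person_month_expand(
    dataset: WeightedTrialDataset, horizon: int = 60
) -> pd.DataFrame:
    """Expand each block into one row per follow-up month for hazard models.

    Death ascertainment is assumed registry-complete, so blocks are at risk
    from month 1 until death or administrative censoring, truncated at
    ``horizon`` months.  The event indicator ``y`` is 1 in the death month
    (a death recorded in the baseline month itself counts as an event at
    month 1) and rows stop at the event month inclusive.

    Returns a table with columns ``record_id``, ``patient_id``,
    ``trial_month``, ``arm``, ``m`` (1-based follow-up month), ``y``.
    """
    rec = dataset.records
    t_admin = np.minimum(rec["t_admin"].to_numpy(float), float(horizon))
    t_death = rec["t_death"].to_numpy(float)
    t_event = np.maximum(np.nan_to_num(t_death, nan=np.inf), 1.0)
    dies = t_event <= t_admin
    n_months = np.where(dies, np.minimum(t_event, t_admin), t_admin).astype(int)
    if (n_months < 1).any():
        raise ValueError("every block needs at least one month at risk")

    idx = np.repeat(np.arange(len(rec)), n_months)
    m = np.concatenate([np.arange(1, n + 1) for n in n_months])
    y = np.zeros(len(m), dtype=int)
    ends = np.cumsum(n_months) - 1
    y[ends[dies]] = 1
    out = pd.DataFrame(
        {
            "record_id": rec["record_id"].to_numpy()[idx],
            "patient_id": rec["patient_id"].to_numpy()[idx],
            "trial_month": rec["trial_month"].to_numpy()[idx],
            "arm": rec["arm"].to_numpy()[idx],
            "m": m,
            "y": y,
        }
    )
    return out
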