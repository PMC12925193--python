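"""Shared fixtures: tiny handcrafted registries and small simulated cohorts."""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import pytest

from stoptrial.simdata import scenario_library, simulate_cohort


def make_patient(pid: str, **kw) -> dict:
    base = dict(
        patient_id=pid,
        sex_female=1,
        age=80.0,
        education=1,
        mrrc=0,
        nursing_home=0,
        antidepressant=0,
        neuroleptic=0,
        anxiolytic=0,
        hypnotic=0,
        nootropic=0,
        antihypertensive=0,
        antidiabetic=0,
        lipid_lowering=0,
        death_month=np.nan,
    )
    base.update(kw)
    return base


def make_visits(pid: str, rows: list[tuple]) -> list[dict]:
    """rows: (month, mmse, on_chei[, ad_diagnosis])"""
    out = []
    for row in rows:
        month, mmse, on = row[:3]
        ad = row[3] if len(row) > 3 else 1
        out.append(
            dict(
                patient_id=pid, month=month, mmse=mmse, on_chei=on,
                ad_diagnosis=ad,
            )
        )
    return out


@pytest.fixture(scope="session")
def paper_like_small():
    cfg = dataclasses.replace(
        scenario_library()["paper_like"], n_patients=600
    )
    return simulate_cohort(cfg, seed=20240301)


@pytest.fixture(scope="session")
def mid_cohort():
    cfg = dataclasses.replace(
        scenario_library()["paper_like"], n_patients=2500
    )
    return simulate_cohort(cfg, seed=20240302)


@pytest.fixture()
def tiny_registry():
    """Three handcrafted patients: a continuer, a stopper, one below band."""
    patients = pd.DataFrame(
        [
            make_patient("cont"),
            make_patient("stop", age=85.0),
            make_patient("low"),
        ]
    )
    visits = pd.DataFrame(
        make_visits("cont", [(-3, 22, 1), (2, 21, 1), (8, 20, 1), (14, 19, 1)])
        + make_visits("stop", [(-4, 18, 1), (3, 17, 1), (12, 15, 0), (18, 13, 0)])
        + make_visits("low", [(-2, 9, 1), (4, 9, 1), (10, 8, 1)])
    )
    return patients, visits
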