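"""Column dictionaries for the delimited-text tables the pipeline exchanges.

Two input tables describe a registry cohort:

``patients`` -- one row per patient:

===================  =========================================================
column               meaning
===================  =========================================================
patient_id           opaque string identifier
sex_female           1 if female, 0 if male
age                  age in years at the start of the enrolment window
education            ordinal 0/1/2 = primary / secondary / post-secondary
mrrc                 1 if followed at a memory resources & research centre,
                     0 if at a general memory centre
nursing_home         1 if living in a nursing home, 0 if at home
antidepressant ...   binary medication flags (see MED_FLAGS)
death_month          calendar-month index of death (empty if alive)
===================  =========================================================

``visits`` -- one row per consultation:

===================  =========================================================
column               meaning
===================  =========================================================
patient_id           as above
month                calendar-month index (enrolment window opens at 0)
mmse                 MMSE score 0-30 (empty if not assessed)
on_chei              1 if on cholinesterase-inhibitor treatment at the visit
ad_diagnosis         1 if an Alzheimer's-disease diagnosis is recorded
===================  =========================================================

Baseline-record tables produced by :func:`stoptrial.cohort.screen_eligibility`
carry one row per (patient, trial month) enrolment with the encoded covariate
vector used by the propensity and outcome models.
"""

from __future__ import annotations

#: binary medication flags recorded in the cognition registry
PSYCHOTROPIC_FLAGS = [
    "antidepressant",
    "neuroleptic",
    "anxiolytic",
    "hypnotic",
    "nootropic",
]

#: additional cardiometabolic flags available in the mortality registry
CARDIOMETABOLIC_FLAGS = ["antihypertensive", "antidiabetic", "lipid_lowering"]

MED_FLAGS = PSYCHOTROPIC_FLAGS + CARDIOMETABOLIC_FLAGS

PATIENT_COLUMNS = (
    ["patient_id", "sex_female", "age", "education", "mrrc", "nursing_home"]
    + MED_FLAGS
    + ["death_month"]
)

VISIT_COLUMNS = ["patient_id", "month", "mmse", "on_chei", "ad_diagnosis"]

#: covariate encoding shared by the propensity and balance machinery;
#: education enters as two dummies against the primary-education reference
BASE_COVARIATES = [
    "age",
    "sex_female",
    "baseline_mmse",
    "mrrc",
    "nursing_home",
    "education_secondary",
    "education_post_secondary",
]

#: covariate set for the cognitive-trajectory emulation
COGNITION_COVARIATES = BASE_COVARIATES + PSYCHOTROPIC_FLAGS

#: covariate set for the mortality emulation (adds cardiometabolic treatment)
MORTALITY_COVARIATES = COGNITION_COVARIATES + CARDIOMETABOLIC_FLAGS

#: binary covariates, for the proportion-based standardized-difference formula
BINARY_COVARIATES = frozenset(
    ["sex_female", "mrrc", "nursing_home", "education_secondary",
     "education_post_secondary"] + MED_FLAGS
)
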