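"""Published aggregate statistics of the registry year the package targets.

These printed aggregates from the national Japanese ICU registry cohort
(fiscal 2018, adult admissions) anchor the synthetic generator defaults
and support closed-form arithmetic checks: overall SMR from observed
deaths and mean predicted risk, and the scaled-Brier identity from the
reported Brier score and mortality.
"""

from __future__ import annotations

#: Aggregates of the registry study population.
REGISTRY = {
    "n_patients": 33557,
    "n_units": 44,
    "deaths_hospital": 2728,
    "deaths_icu": 1291,
    "mean_predicted_risk": 0.170,
    "sd_predicted_risk": 0.228,
    "brier_recalibrated": 0.047,
}


def hospital_mortality() -> float:
    """Observed hospital mortality of the registry cohort."""
    return REGISTRY["deaths_hospital"] / REGISTRY["n_patients"]


def icu_mortality() -> float:
    """Observed ICU mortality of the registry cohort."""
    return REGISTRY["deaths_icu"] / REGISTRY["n_patients"]


def smr_before_recalibration() -> float:
    """Overall SMR of the original model: O / (mean risk * n)."""
    return REGISTRY["deaths_hospital"] / (
        REGISTRY["mean_predicted_risk"] * REGISTRY["n_patients"]
    )


def scaled_brier_recalibrated() -> float:
    """Scaled Brier score implied by the reported Brier and mortality."""
    p = hospital_mortality()
    return 1.0 - REGISTRY["brier_recalibrated"] / (p * (1.0 - p))
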