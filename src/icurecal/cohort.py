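"""Patient-level cohort container and delimited-text I/O.

A cohort holds, for every ICU admission, the original severity model's
predicted in-hospital death probability (``risk_orig``), its logit (the
linear predictor ``lp`` — the sole covariate of every recalibration
model), the binary hospital-death outcome, the ICU identifier and an
integer admission order used by the EWMA charts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit as inverse_logit  # re-exported

logger = logging.getLogger(__name__)

#: Internal column names of a cohort frame.
COLUMNS = ["patient_id", "unit_id", "admission_seq", "risk_orig", "lp", "died"]

#: Default mapping from internal field names to file column names.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "patient_id": "patient_id",
    "unit_id": "icu_id",
    "admission_seq": "admission_seq",
    "risk_orig": "predicted_risk",
    "died": "hospital_death",
}


class CohortError(ValueError):
    """Invalid cohort input (empty, malformed, or unmapped columns)."""


def logit(p):
    """Log-odds of a probability, ``log(p / (1 - p))``.

    Parameters
    ----------
    p : float or array-like
        Probability strictly inside (0, 1).

    Raises
    ------
    ValueError
        If any value lies outside the open unit interval.
    """
    arr = np.asarray(p, dtype=float)
    bad = ~((arr > 0.0) & (arr < 1.0))
    if np.any(bad):
        offending = arr[bad].ravel()[0] if arr.ndim else float(arr)
        raise ValueError(
            f"logit is defined only on (0, 1); got {offending!r}"
        )
    out = np.log(arr / (1.0 - arr))
    return float(out) if np.isscalar(p) or arr.ndim == 0 else out


@dataclass
class Cohort:
    """An ordered collection of ICU admissions.

    Wraps a :class:`pandas.DataFrame` with columns ``patient_id``,
    ``unit_id``, ``admission_seq``, ``risk_orig``, ``lp`` and ``died``.
    """

    data: pd.DataFrame
    n_excluded: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise CohortError(f"cohort frame lacks columns {missing}")
        if len(df) == 0:
            raise CohortError("cohort is empty")
        risk = df["risk_orig"].to_numpy(dtype=float)
        if np.any(~((risk > 0.0) & (risk < 1.0))):
            raise CohortError("risk_orig outside (0, 1) in cohort frame")
        died = df["died"].to_numpy()
        if not np.isin(died, (0, 1)).all():
            raise CohortError("died must be binary 0/1")
        if not np.allclose(df["lp"], logit(risk), rtol=1e-8, atol=1e-8):
            raise CohortError("lp inconsistent with logit(risk_orig)")

    # -- summary properties -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def n_units(self) -> int:
        return int(self.data["unit_id"].nunique())

    @property
    def unit_ids(self) -> list:
        return sorted(self.data["unit_id"].unique().tolist())

    @property
    def mortality(self) -> float:
        return float(self.data["died"].mean())

    @property
    def mean_risk_orig(self) -> float:
        return float(self.data["risk_orig"].mean())

    @property
    def lp(self) -> np.ndarray:
        return self.data["lp"].to_numpy(dtype=float)

    @property
    def died(self) -> np.ndarray:
        return self.data["died"].to_numpy(dtype=int)

    @property
    def risk_orig(self) -> np.ndarray:
        return self.data["risk_orig"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"Cohort(n={self.n}, n_units={self.n_units}, "
            f"mortality={self.mortality:.4f}, "
            f"mean_risk_orig={self.mean_risk_orig:.4f})"
        )


def make_cohort(
    risk_orig,
    died,
    unit_id=None,
    admission_seq=None,
    patient_id=None,
    **meta,
) -> Cohort:
    """Build a :class:`Cohort` from arrays (no exclusion logic)."""
    risk = np.asarray(risk_orig, dtype=float)
    n = len(risk)
    df = pd.DataFrame(
        {
            "patient_id": np.arange(n) if patient_id is None else patient_id,
            "unit_id": np.zeros(n, dtype=int) if unit_id is None else unit_id,
            "admission_seq": (
                np.arange(n) if admission_seq is None else admission_seq
            ),
            "risk_orig": risk,
            "lp": logit(risk),
            "died": np.asarray(died, dtype=int),
        }
    )
    return Cohort(df, meta=dict(meta))


def read_cohort(
    source,
    column_map: Mapping[str, str] | None = None,
    delimiter: str | None = None,
) -> Cohort:
    """Read a cohort from delimited text (comma default, tab accepted).

    Rows with a missing outcome, a missing risk, or a risk outside the
    open interval (0, 1) are dropped; the exclusion count is logged and
    recorded as ``cohort.n_excluded``.

    Parameters
    ----------
    source : path or file handle
        Delimited text with a header row.
    column_map : mapping, optional
        Maps internal names (``patient_id``, ``unit_id``,
        ``admission_seq``, ``risk_orig``, ``died``) to file column
        names; defaults to :data:`DEFAULT_COLUMN_MAP`.
    delimiter : str, optional
        Field separator; sniffed between comma and tab when omitted.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(source, sep=delimiter, engine="python" if delimiter is None else "c")
    missing = [v for v in cmap.values() if v not in df.columns]
    if missing:
        raise CohortError(
            f"mapped columns {missing} absent from input header "
            f"{list(df.columns)}"
        )
    df = df.rename(columns={v: k for k, v in cmap.items()})
    n_raw = len(df)
    risk = pd.to_numeric(df["risk_orig"], errors="coerce")
    died = pd.to_numeric(df["died"], errors="coerce")
    keep = risk.notna() & died.notna() & (risk > 0.0) & (risk < 1.0)
    n_excluded = int(n_raw - keep.sum())
    if n_excluded:
        logger.info(
            "excluded %d of %d rows (missing outcome/risk or risk outside (0,1))",
            n_excluded,
            n_raw,
        )
    df = df.loc[keep].copy()
    if len(df) == 0:
        raise CohortError("no rows retained after exclusions")
    df["risk_orig"] = risk[keep].astype(float)
    df["died"] = died[keep].astype(int)
    df["lp"] = logit(df["risk_orig"].to_numpy())
    df = df[COLUMNS].reset_index(drop=True)
    return Cohort(df, n_excluded=n_excluded)


def write_cohort(cohort: Cohort, path, column_map: Mapping[str, str] | None = None,
                 delimiter: str = ",") -> None:
    """Write a cohort as delimited text readable by :func:`read_cohort`."""
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    out = cohort.data[["patient_id", "unit_id", "admission_seq", "risk_orig", "died"]]
    out = out.rename(columns=cmap)
    out.to_csv(path, sep=delimiter, index=False)
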