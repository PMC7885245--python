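"""SMR funnel plots with overdispersion, and risk-adjusted EWMA charts.

Per-ICU observed (O) and expected (E = sum of predicted risks) deaths
give the standardized mortality ratio O/E plotted against E inside
control limits that narrow as E grows; the overdispersion factor phi is
the mean squared standardized Pearson residual across units. The EWMA
chart smooths the admission-ordered outcome sequence with weight
``lambda`` on the newest admission and compares it to limits derived
from the predicted risks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .cohort import Cohort

logger = logging.getLogger(__name__)


def summarize_units(cohort: Cohort, model, use_units: bool = True) -> pd.DataFrame:
    """Per-ICU observed/expected deaths, SMR and standardized residual.

    Returns a frame with columns ``unit_id, n_patients, observed,
    expected, variance, smr, z`` where ``variance = sum p(1-p)`` and
    ``z = (O - E) / sqrt(V)``. Unit totals conserve the cohort totals.
    """
    pred = model.predict_cohort(cohort, use_units=use_units)
    df = cohort.data.assign(_pred=pred, _var=pred * (1.0 - pred))
    agg = df.groupby("unit_id").agg(
        n_patients=("died", "size"),
        observed=("died", "sum"),
        expected=("_pred", "sum"),
        variance=("_var", "sum"),
    )
    zero_e = agg["expected"] <= 0
    if zero_e.any():
        logger.warning(
            "excluding %d unit(s) with zero expected deaths", int(zero_e.sum())
        )
        agg = agg[~zero_e]
    agg["smr"] = agg["observed"] / agg["expected"]
    agg["z"] = (agg["observed"] - agg["expected"]) / np.sqrt(agg["variance"])
    return agg.reset_index()


@dataclass
class FunnelChart:
    """SMR funnel: per-unit points, center line, limit curves, phi."""

    units: pd.DataFrame
    center: float
    mean_risk: float
    z_levels: tuple
    phi: float
    outliers: list

    def limits(self, expected, z: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        """Lower/upper SMR limit curves at ``z`` SDs for given E values.

        The curve uses the average-risk binomial approximation
        ``V(E) = E (1 - mean_risk)``; per-unit outlier decisions use
        each unit's exact variance instead.
        """
        e = np.asarray(expected, dtype=float)
        half = z * np.sqrt(e * (1.0 - self.mean_risk)) / e
        return self.center - half, self.center + half


def funnel(
    units: pd.DataFrame,
    center: float | None = None,
    z_levels: tuple = (2.0, 3.0),
    outlier_z: float = 3.0,
) -> FunnelChart:
    """Build an SMR funnel chart from :func:`summarize_units` output.

    ``center`` defaults to the realized overall SMR (sum O / sum E);
    pass ``center=1.0`` for a fixed reference line. ``phi`` is the mean
    squared standardized Pearson residual over units; units with
    ``|z| > outlier_z`` are flagged.
    """
    if len(units) < 2:
        raise ValueError("funnel needs at least 2 units")
    tot_o = float(units["observed"].sum())
    tot_e = float(units["expected"].sum())
    if center is None:
        center = tot_o / tot_e
    mean_risk = tot_e / float(units["n_patients"].sum())
    z = units["z"].to_numpy(dtype=float)
    phi = float(np.mean(z**2))
    outliers = units.loc[np.abs(z) > outlier_z, "unit_id"].tolist()
    return FunnelChart(
        units=units,
        center=float(center),
        mean_risk=mean_risk,
        z_levels=tuple(z_levels),
        phi=phi,
        outliers=outliers,
    )


@dataclass
class EwmaSeries:
    """Admission-ordered EWMA of mortality with risk-derived limits."""

    lam: float
    start: float
    z: np.ndarray = field(repr=False)
    center: np.ndarray = field(repr=False)
    variance: np.ndarray = field(repr=False)
    k_levels: tuple = (2.0, 3.0)
    excursions: list = field(default_factory=list)
    unit_id: object = None

    def limits(self, k: float = 3.0) -> tuple[np.ndarray, np.ndarray]:
        half = k * np.sqrt(self.variance)
        return self.center - half, self.center + half

    @property
    def n(self) -> int:
        return int(self.z.size)

    def as_frame(self) -> pd.DataFrame:
        lo2, hi2 = self.limits(2.0)
        lo3, hi3 = self.limits(3.0)
        return pd.DataFrame(
            {
                "t": np.arange(1, self.n + 1),
                "ewma": self.z,
                "center": self.center,
                "lower2": lo2,
                "upper2": hi2,
                "lower3": lo3,
                "upper3": hi3,
            }
        )


def _ewma_recursion(x: np.ndarray, lam: float, start: float) -> np.ndarray:
    # z_t = lam*x_t + (1-lam)*z_{t-1}, z_0 = start, via an IIR filter
    zi = lfilter([lam], [1.0, -(1.0 - lam)], x, zi=np.array([(1.0 - lam) * start]))
    return zi[0]


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Contiguous True runs as (start, end) inclusive 0-based indices."""
    if not flags.any():
        return []
    idx = np.flatnonzero(flags)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def ewma(
    cohort: Cohort,
    model,
    lam: float = 0.005,
    k_levels: tuple = (2.0, 3.0),
    start: float | None = None,
    flat_center: bool = False,
    use_units: bool = True,
    unit_id=None,
) -> EwmaSeries:
    """Risk-adjusted EWMA chart of mortality over sequential admissions.

    ``z_t = lam * y_t + (1 - lam) * z_{t-1}`` starting from the overall
    mortality; the center line applies the same recursion to the
    predicted risks (or stays flat at their mean when
    ``flat_center=True``), and the limits are
    ``center_t +/- k * sqrt(v_t)`` with the exact time-varying variance
    ``v_t = sum_i lam^2 (1-lam)^(2(t-i)) p_i (1-p_i)``. Excursions are
    contiguous runs beyond the 3-SD limits.
    """
    if not 0.0 < lam <= 1.0:
        raise ValueError("lambda must lie in (0, 1]")
    df = cohort.data
    if unit_id is not None:
        df = df[df["unit_id"] == unit_id]
        if len(df) == 0:
            raise ValueError(f"no admissions for unit {unit_id!r}")
    seq = df["admission_seq"].to_numpy()
    if np.unique(seq).size != seq.size:
        raise ValueError("admission_seq contains duplicates; ordering undefined")
    order = np.argsort(seq, kind="stable")
    y = df["died"].to_numpy(dtype=float)[order]
    sub = Cohort(df.iloc[order].reset_index(drop=True)) if unit_id is not None else cohort
    pred = model.predict_cohort(sub, use_units=use_units)
    if unit_id is None:
        pred = pred[order]
    if start is None:
        start = float(y.mean())
    z = _ewma_recursion(y, lam, start)
    if flat_center:
        center = np.full_like(z, float(pred.mean()))
    else:
        center = _ewma_recursion(pred, lam, start)
    pq = pred * (1.0 - pred)
    # v_t follows the same IIR recursion with coefficient (1-lam)^2
    v = lfilter([lam**2], [1.0, -((1.0 - lam) ** 2)], pq)
    kmax = max(k_levels)
    hi = center + kmax * np.sqrt(v)
    lo = center - kmax * np.sqrt(v)
    excursions = _runs((z > hi) | (z < lo))
    return EwmaSeries(
        lam=lam,
        start=start,
        z=z,
        center=center,
        variance=v,
        k_levels=tuple(k_levels),
        excursions=excursions,
        unit_id=unit_id,
    )


def per_unit_ewma(
    cohort: Cohort,
    model,
    lam: float = 0.005,
    k_levels: tuple = (2.0, 3.0),
    min_n: int = 30,
) -> dict:
    """Per-ICU EWMA charts, each started at that unit's mean mortality."""
    charts = {}
    for unit in cohort.unit_ids:
        sub = cohort.data[cohort.data["unit_id"] == unit]
        if len(sub) < min_n:
            logger.warning(
                "unit %r has only %d admissions; EWMA chart is unstable",
                unit, len(sub),
            )
        charts[unit] = ewma(
            cohort, model, lam=lam, k_levels=k_levels,
            start=float(sub["died"].mean()), unit_id=unit,
        )
    return charts
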