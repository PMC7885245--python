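"""Discrimination, calibration, information criteria and internal validation.

The battery computed for each recalibrated model: AUROC (Mann-Whitney
form), Brier and scaled Brier scores, a modified Hosmer-Lemeshow test
suited to large cohorts, decile calibration tables, calibration slope
and intercept, AIC, and bootstrap optimism-corrected AUROC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit

from .cohort import Cohort, logit, make_cohort
from .recalibrate import (
    ConvergenceError,
    DegenerateOutcomeError,
    HierarchicalGamModel,
    IdentifiabilityError,
)

logger = logging.getLogger(__name__)


class ValidationError(RuntimeError):
    """Internal validation failed (too many failed bootstrap fits)."""


def _check_binary(died: np.ndarray) -> None:
    if died.min() == died.max():
        raise ValueError("outcome vector needs both deaths and survivors")


def auroc(pred, died) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    ``P(pred_death > pred_survivor) + 0.5 * P(tie)``, computed from the
    rank statistics of the pooled predictions.
    """
    pred = np.asarray(pred, dtype=float)
    died = np.asarray(died)
    _check_binary(died)
    r = stats.rankdata(pred)
    n1 = int(died.sum())
    n0 = died.size - n1
    return float((r[died == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def brier(pred, died) -> float:
    """Mean squared difference between predicted probability and outcome."""
    pred = np.asarray(pred, dtype=float)
    died = np.asarray(died, dtype=float)
    if pred.size == 0:
        raise ValueError("empty input")
    return float(np.mean((pred - died) ** 2))


def scaled_brier(pred, died) -> float:
    """Brier score rescaled against the outcome-prevalence null model.

    ``1 - brier / (pbar * (1 - pbar))`` with ``pbar`` the observed event
    rate; interpretable like a Pearson R-squared.
    """
    died = np.asarray(died, dtype=float)
    pbar = float(died.mean())
    if pbar in (0.0, 1.0):
        raise ValueError("scaled Brier score undefined for a one-class outcome")
    return 1.0 - brier(pred, died) / (pbar * (1.0 - pbar))


def _quantile_groups(pred: np.ndarray, groups: int) -> np.ndarray:
    """Group labels 0..groups-1 by predicted-risk deciles, stable in ties."""
    order = np.argsort(pred, kind="stable")
    g = np.empty(pred.size, dtype=int)
    g[order] = (np.arange(pred.size) * groups) // pred.size
    return g


@dataclass
class HLResult:
    """Modified Hosmer-Lemeshow test result.

    ``stat``/``p`` carry the large-sample modification when it applies
    (subsample standardization); the unmodified whole-sample statistic
    is always reported alongside.
    """

    stat: float
    df: int
    p: float
    stat_unmodified: float
    p_unmodified: float
    modified: bool
    n: int
    groups: int


def _hl_statistic(pred, died, groups):
    g = _quantile_groups(pred, groups)
    stat = 0.0
    used = 0
    carry_o = carry_e = carry_n = 0.0
    for k in range(groups):
        mask = g == k
        n_g = carry_n + mask.sum()
        if n_g == 0:
            continue
        O = carry_o + died[mask].sum()
        E = carry_e + pred[mask].sum()
        if E <= 0 or E >= n_g:
            # merge a degenerate group into the next one
            carry_o, carry_e, carry_n = O, E, n_g
            continue
        carry_o = carry_e = carry_n = 0.0
        stat += (O - E) ** 2 / (E * (1.0 - E / n_g))
        used += 1
    df = max(used - 2, 1)
    return float(stat), int(df)


def modified_hosmer_lemeshow(
    pred,
    died,
    groups: int = 10,
    reference_n: int = 25000,
    n_subsamples: int = 11,
    seed: int | None = None,
) -> HLResult:
    """Hosmer-Lemeshow test with a large-sample modification.

    Deciles of predicted risk; ``H = sum (O-E)^2 / (E (1 - E/n_g))``,
    compared to chi-square with ``groups - 2`` degrees of freedom. The
    plain test is overpowered in large cohorts, so when
    ``n > reference_n`` the statistic is standardized to the reference
    size by evaluating it on repeated random subsamples of
    ``reference_n`` patients and reporting the median statistic and
    p value.
    """
    pred = np.asarray(pred, dtype=float)
    died = np.asarray(died, dtype=float)
    n = pred.size
    if n < groups:
        raise ValueError(f"need at least {groups} observations")
    stat_u, df = _hl_statistic(pred, died, groups)
    p_u = float(stats.chi2.sf(stat_u, df))
    if n <= reference_n:
        return HLResult(stat_u, df, p_u, stat_u, p_u, False, n, groups)
    rng = np.random.default_rng(seed)
    stats_sub, ps = [], []
    for _ in range(n_subsamples):
        idx = rng.choice(n, size=reference_n, replace=False)
        s, d = _hl_statistic(pred[idx], died[idx], groups)
        stats_sub.append(s)
        ps.append(float(stats.chi2.sf(s, d)))
    return HLResult(
        float(np.median(stats_sub)), df, float(np.median(ps)),
        stat_u, p_u, True, n, groups,
    )


def calibration_table(pred, died, groups: int = 10) -> pd.DataFrame:
    """Per-decile mean predicted risk and observed mortality."""
    pred = np.asarray(pred, dtype=float)
    died = np.asarray(died, dtype=float)
    g = _quantile_groups(pred, groups)
    rows = []
    for k in range(groups):
        mask = g == k
        rows.append(
            {
                "decile": k + 1,
                "n": int(mask.sum()),
                "mean_pred": float(pred[mask].mean()),
                "observed": float(died[mask].mean()),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CalibrationResult:
    """Weak-calibration summary of a prediction vector.

    ``intercept_in_the_large`` fixes the slope at 1 (offset regression:
    calibration-in-the-large); ``intercept``/``slope`` come from the
    joint free-slope logistic regression of the outcome on
    ``logit(pred)``. Perfect calibration is slope 1, intercepts 0.
    """

    slope: float
    intercept: float
    intercept_in_the_large: float


def calibration_slope_intercept(pred, died) -> CalibrationResult:
    """Calibration slope and intercepts of predictions against outcomes."""
    pred = np.clip(np.asarray(pred, dtype=float), 1e-12, 1 - 1e-12)
    died = np.asarray(died)
    _check_binary(died)
    lp = logit(pred)
    X = np.column_stack([np.ones_like(lp), lp])
    free = sm.GLM(died, X, family=sm.families.Binomial()).fit()
    fixed = sm.GLM(
        died, np.ones((lp.size, 1)), family=sm.families.Binomial(), offset=lp
    ).fit()
    return CalibrationResult(
        slope=float(free.params[1]),
        intercept=float(free.params[0]),
        intercept_in_the_large=float(fixed.params[0]),
    )


def aic(model, cohort: Cohort) -> float:
    """Akaike information criterion: ``-2 loglik + 2 k``.

    ``k`` is the parameter count (1 for the offset update, 2 for the
    logistic update) or the effective degrees of freedom of the
    penalized hierarchical fit.
    """
    return -2.0 * model.log_likelihood(cohort) + 2.0 * model.k_params


@dataclass
class OptimismResult:
    """Bootstrap (Harrell) optimism correction of the AUROC."""

    apparent: float
    optimism: float
    corrected: float
    n_boot: int
    n_failed: int


def optimism_corrected_auroc(
    fit_fn,
    cohort: Cohort,
    n_boot: int = 5000,
    seed: int | None = None,
    max_failed_frac: float = 0.1,
    cluster: bool = False,
) -> OptimismResult:
    """Optimism-corrected AUROC by Harrell's bootstrap.

    For each resample (patients drawn with replacement; set
    ``cluster=True`` to resample whole ICUs instead): refit, take the
    AUROC on the resample minus the refit model's AUROC on the original
    cohort; the mean of these differences is the optimism, subtracted
    from the apparent AUROC. Non-convergent resamples are dropped and
    counted; more than ``max_failed_frac`` failures aborts.
    """
    model = fit_fn(cohort)
    apparent = auroc(model.predict_cohort(cohort), cohort.died)
    rng = np.random.default_rng(seed)
    optimisms = []
    n_failed = 0
    df = cohort.data
    unit_groups = {u: g.index.to_numpy() for u, g in df.groupby("unit_id")} if cluster else None
    for _ in range(n_boot):
        if cluster:
            units = rng.choice(list(unit_groups), size=len(unit_groups), replace=True)
            idx = np.concatenate([unit_groups[u] for u in units])
        else:
            idx = rng.integers(0, cohort.n, size=cohort.n)
        boot = Cohort(df.iloc[idx].reset_index(drop=True))
        try:
            m_b = fit_fn(boot)
            a_boot = auroc(m_b.predict_cohort(boot), boot.died)
            a_orig = auroc(m_b.predict_cohort(cohort), cohort.died)
        except (DegenerateOutcomeError, IdentifiabilityError, ConvergenceError,
                ValueError) as err:
            n_failed += 1
            logger.debug("bootstrap resample failed: %s", err)
            continue
        optimisms.append(a_boot - a_orig)
    if n_failed > max_failed_frac * n_boot:
        raise ValidationError(
            f"{n_failed}/{n_boot} bootstrap fits failed (> {max_failed_frac:.0%})"
        )
    optimism = float(np.mean(optimisms)) if optimisms else 0.0
    return OptimismResult(
        apparent=apparent,
        optimism=optimism,
        corrected=apparent - optimism,
        n_boot=len(optimisms),
        n_failed=n_failed,
    )


def posterior_corrected_auroc(
    model: HierarchicalGamModel,
    cohort: Cohort,
    n_sims: int = 10000,
    seed: int | None = None,
) -> OptimismResult:
    """Posterior-simulation optimism for the hierarchical update.

    Coefficient vectors are drawn from the Laplace-approximate Gaussian
    posterior of the penalized fit; optimism is the mean shortfall of
    the drawn models' AUROC against the point-estimate AUROC on the
    observed outcomes. Requires the model fitted on ``cohort`` with its
    covariance retained.
    """
    if model.covariance is None:
        raise ValueError("model was fitted without keep_covariance=True")
    rng = np.random.default_rng(seed)
    B = model.basis.design(cohort.lp)
    codes, unit_labels = pd.factorize(cohort.data["unit_id"], sort=True)
    u_hat = np.array([model.unit_effects[str(lab)] for lab in unit_labels])
    beta_hat = np.concatenate([[model.beta0], model.spline_coefs, u_hat])
    apparent = auroc(model.predict_cohort(cohort), cohort.died)
    L = np.linalg.cholesky(
        model.covariance + 1e-12 * np.eye(len(beta_hat))
    )
    k_f = model.spline_coefs.size
    optimisms = np.empty(n_sims)
    for s in range(n_sims):
        beta_s = beta_hat + L @ rng.standard_normal(beta_hat.size)
        eta = beta_s[0] + B @ beta_s[1 : 1 + k_f] + beta_s[1 + k_f :][codes]
        optimisms[s] = apparent - auroc(expit(eta), cohort.died)
    optimism = float(optimisms.mean())
    return OptimismResult(apparent, optimism, apparent - optimism, n_sims, 0)


@dataclass
class PerformanceReport:
    """The full metric battery for one model on one cohort."""

    n: int
    auroc: float
    brier: float
    scaled_brier: float
    hl_stat: float
    hl_df: int
    hl_p: float
    cal_slope: float
    cal_intercept: float
    cal_intercept_in_the_large: float
    aic: float
    smr: float
    calibration_points: pd.DataFrame = field(repr=False)
    auroc_optimism_corrected: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration_points"] = self.calibration_points.to_dict("records")
        return d


def performance_report(
    model,
    cohort: Cohort,
    fit_fn=None,
    n_boot: int | None = None,
    groups: int = 10,
    reference_n: int = 25000,
    seed: int | None = None,
    use_units: bool = True,
) -> PerformanceReport:
    """Compute the full metric battery for ``model`` on ``cohort``.

    Pass ``fit_fn`` and ``n_boot`` to add the bootstrap
    optimism-corrected AUROC.
    """
    pred = model.predict_cohort(cohort, use_units=use_units)
    died = cohort.died
    hl = modified_hosmer_lemeshow(
        pred, died, groups=groups, reference_n=reference_n, seed=seed
    )
    cal = calibration_slope_intercept(pred, died)
    corrected = None
    if fit_fn is not None and n_boot:
        corrected = optimism_corrected_auroc(
            fit_fn, cohort, n_boot=n_boot, seed=seed
        ).corrected
    return PerformanceReport(
        n=cohort.n,
        auroc=auroc(pred, died),
        brier=brier(pred, died),
        scaled_brier=scaled_brier(pred, died),
        hl_stat=hl.stat,
        hl_df=hl.df,
        hl_p=hl.p,
        cal_slope=cal.slope,
        cal_intercept=cal.intercept,
        cal_intercept_in_the_large=cal.intercept_in_the_large,
        aic=aic(model, cohort),
        smr=float(died.sum() / pred.sum()),
        calibration_points=calibration_table(pred, died, groups=groups),
        auroc_optimism_corrected=corrected,
    )
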