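"""Risk-model updates: intercept offset, logistic recalibration, hierarchical GAM.

All three updates take the original model's linear predictor ``lp`` (the
logit of its predicted death probability) as the only covariate:

* **Offset-intercept update** — ``logit(p) = b0 + lp`` with the slope
  fixed at 1. Re-levels the predictions so mean predicted mortality
  equals observed mortality (calibration-in-the-large; in-sample SMR 1).
* **Logistic recalibration** — ``logit(p) = b0 + b1 * lp``, the ordinary
  two-parameter logistic fit; targets calibration slope 1, intercept 0.
* **Hierarchical generalized additive update** —
  ``logit(p) = b0 + f(lp) + u_i`` with ``f`` a penalized cubic spline
  and ``u_i ~ N(0, sigma_u^2)`` a random intercept per ICU, absorbing
  nonlinear miscalibration and between-unit heterogeneity.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy.special import expit

from .cohort import Cohort
from .splines import PenalizedBSplineBasis

logger = logging.getLogger(__name__)

__all__ = [
    "OffsetInterceptModel",
    "LogisticRecalModel",
    "HierarchicalGamModel",
    "fit_offset_intercept",
    "fit_logistic_recal",
    "fit_hierarchical_gam",
    "original_model",
    "load_model",
    "DegenerateOutcomeError",
    "IdentifiabilityError",
    "ConvergenceError",
]


class DegenerateOutcomeError(ValueError):
    """All-dead or all-alive cohort: the intercept MLE diverges."""


class IdentifiabilityError(ValueError):
    """A coefficient is not identified (e.g. constant lp)."""


class ConvergenceError(RuntimeError):
    """Iterative fit failed to converge."""


def _check_outcomes(died: np.ndarray) -> None:
    if died.min() == died.max():
        raise DegenerateOutcomeError(
            "cohort needs at least one death and one survivor"
        )


def _bernoulli_loglik(p: np.ndarray, y: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


class _BaseModel:
    """Shared prediction / serialization plumbing."""

    kind: str = ""

    def linear_predictor(self, lp, unit_id=None):
        raise NotImplementedError

    def predict_risk(self, lp, unit_id=None):
        """Recalibrated death probability for linear predictor ``lp``.

        ``unit_id`` is honoured only by the hierarchical model; units
        unseen at fitting time receive the population-level prediction
        (random effect 0).
        """
        return expit(self.linear_predictor(lp, unit_id))

    def predict_cohort(self, cohort: Cohort, use_units: bool = True) -> np.ndarray:
        """Per-record predicted risks for a whole cohort."""
        units = cohort.data["unit_id"].to_numpy() if use_units else None
        return self.predict_risk(cohort.lp, units)

    def log_likelihood(self, cohort: Cohort, use_units: bool = True) -> float:
        """In-sample Bernoulli log-likelihood of the fitted model."""
        return _bernoulli_loglik(
            self.predict_cohort(cohort, use_units=use_units), cohort.died
        )

    @property
    def k_params(self) -> float:
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass
class OffsetInterceptModel(_BaseModel):
    """Intercept-only update: ``logit(p) = beta0 + lp`` (slope fixed at 1)."""

    beta0: float
    kind = "offset-intercept"

    def linear_predictor(self, lp, unit_id=None):
        return self.beta0 + np.asarray(lp, dtype=float)

    @property
    def k_params(self) -> float:
        return 1.0

    def to_dict(self) -> dict:
        return {"kind": self.kind, "beta0": self.beta0}


@dataclass
class LogisticRecalModel(_BaseModel):
    """Two-parameter update: ``logit(p) = beta0 + beta1 * lp``."""

    beta0: float
    beta1: float
    kind = "logistic-recalibration"

    def linear_predictor(self, lp, unit_id=None):
        return self.beta0 + self.beta1 * np.asarray(lp, dtype=float)

    @property
    def k_params(self) -> float:
        return 2.0

    def to_dict(self) -> dict:
        return {"kind": self.kind, "beta0": self.beta0, "beta1": self.beta1}


def original_model() -> OffsetInterceptModel:
    """The identity update (beta0 = 0): the original model's own predictions."""
    return OffsetInterceptModel(beta0=0.0)


def fit_offset_intercept(cohort: Cohort) -> OffsetInterceptModel:
    """Fit the intercept-offset update by maximum likelihood.

    The MLE solves the monotone score equation
    ``sum(expit(beta0 + lp_i)) = sum(died_i)``, so the fitted model has
    in-sample SMR exactly 1.
    """
    _check_outcomes(cohort.died)
    glm = sm.GLM(
        cohort.died,
        np.ones((cohort.n, 1)),
        family=sm.families.Binomial(),
        offset=cohort.lp,
    )
    res = glm.fit()
    model = OffsetInterceptModel(beta0=float(res.params[0]))
    resid = cohort.died.sum() - model.predict_cohort(cohort).sum()
    if abs(resid) > 1e-6 * max(1.0, cohort.died.sum()):
        raise ConvergenceError(
            f"offset-intercept score equation violated (residual {resid:.3g})"
        )
    return model


def fit_logistic_recal(cohort: Cohort) -> LogisticRecalModel:
    """Fit the two-parameter logistic recalibration by maximum likelihood."""
    _check_outcomes(cohort.died)
    lp = cohort.lp
    if np.ptp(lp) < 1e-12:
        raise IdentifiabilityError(
            "lp is constant: the slope beta1 is not identifiable "
            "(use the offset-intercept update instead)"
        )
    X = np.column_stack([np.ones_like(lp), lp])
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.GLM(cohort.died, X, family=sm.families.Binomial()).fit()
        except (sm.tools.sm_exceptions.PerfectSeparationError,
                sm.tools.sm_exceptions.PerfectSeparationWarning) as err:
            raise ConvergenceError(
                f"logistic recalibration did not converge: {err}"
            ) from err
    params = np.asarray(res.params, dtype=float)
    if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 1e3):
        raise ConvergenceError(
            f"logistic recalibration diverged (estimates {params}); "
            "possible complete separation"
        )
    return LogisticRecalModel(beta0=float(params[0]), beta1=float(params[1]))


# ---------------------------------------------------------------------------
# hierarchical generalized additive update
# ---------------------------------------------------------------------------

_RHO_BOUND = 14.0  # |log lambda| clamp during smoothing-parameter search


@dataclass
class HierarchicalGamModel(_BaseModel):
    """Hierarchical generalized additive update.

    ``logit(p) = beta0 + f(lp) + u_i`` with a penalized cubic B-spline
    ``f`` (sum-to-zero constrained) and ridge-penalized ICU intercepts
    ``u_i`` whose penalty weight maps to ``1 / sigma2_u``.
    """

    beta0: float
    basis: PenalizedBSplineBasis
    spline_coefs: np.ndarray
    unit_effects: dict
    smoothing: dict  # {"lambda_f": .., "lambda_u": ..}
    sigma2_u: float
    edf: float
    loglik: float
    covariance: np.ndarray | None = field(default=None, repr=False)
    kind = "hierarchical-gam"

    def smooth(self, lp) -> np.ndarray:
        """The fitted smooth ``f(lp)`` (sum-to-zero over the fitting sample)."""
        return self.basis.design(np.atleast_1d(np.asarray(lp, dtype=float))) @ self.spline_coefs

    def _unit_offset(self, lp_len: int, unit_id) -> np.ndarray:
        if unit_id is None:
            return np.zeros(lp_len)
        units = np.atleast_1d(unit_id)
        if units.size == 1 and lp_len > 1:
            units = np.repeat(units, lp_len)
        return np.array([self.unit_effects.get(_key(u), 0.0) for u in units])

    def linear_predictor(self, lp, unit_id=None):
        lp_arr = np.atleast_1d(np.asarray(lp, dtype=float))
        eta = self.beta0 + self.smooth(lp_arr) + self._unit_offset(lp_arr.size, unit_id)
        return float(eta[0]) if np.isscalar(lp) or np.asarray(lp).ndim == 0 else eta

    @property
    def k_params(self) -> float:
        # effective degrees of freedom (trace of the influence matrix,
        # intercept column included)
        return self.edf

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "beta0": self.beta0,
            "spline_basis": self.basis.to_dict(),
            "spline_coefs": self.spline_coefs.tolist(),
            "unit_effects": {str(k): v for k, v in self.unit_effects.items()},
            "smoothing": self.smoothing,
            "sigma2_u": self.sigma2_u,
            "edf": self.edf,
            "loglik": self.loglik,
        }


def _key(u):
    return str(u)


def _assemble_penalty(p, sl_f, sl_u, S_f, lam_f, lam_u):
    S = np.zeros((p, p))
    S[sl_f, sl_f] = lam_f * S_f
    idx = np.arange(sl_u.start, sl_u.stop)
    S[idx, idx] += lam_u
    return S


def _penalized_deviance(X, y, S, beta):
    mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
    return -2.0 * _bernoulli_loglik(mu, y) + float(beta @ S @ beta)


def _pirls(X, y, S, beta_init, max_iter=200, tol=1e-8):
    """Penalized IRLS for Bernoulli likelihood; returns (beta, H, pdev, ok).

    Step-halving keeps the penalized deviance monotone, which stabilizes
    the weakly penalized corner of the smoothing-parameter search where
    the spline can head toward separation.
    """
    beta = beta_init.copy()
    pdev_old = _penalized_deviance(X, y, S, beta)
    H = None
    for _ in range(max_iter):
        eta = X @ beta
        mu = np.clip(expit(eta), 1e-10, 1 - 1e-10)
        w = mu * (1 - mu)
        z = eta + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X
        try:
            proposal = np.linalg.solve(H + S, XtW @ z)
        except np.linalg.LinAlgError:
            proposal = np.linalg.solve(H + S + 1e-8 * np.eye(len(beta)), XtW @ z)
        step = proposal - beta
        pdev = _penalized_deviance(X, y, S, proposal)
        halvings = 0
        while pdev > pdev_old + 1e-12 and halvings < 30:
            step *= 0.5
            proposal = beta + step
            pdev = _penalized_deviance(X, y, S, proposal)
            halvings += 1
        beta = proposal
        if abs(pdev - pdev_old) < tol * (abs(pdev) + 0.1):
            mu = np.clip(expit(X @ beta), 1e-10, 1 - 1e-10)
            w = mu * (1 - mu)
            H = (X.T * w) @ X
            return beta, H, pdev, True
        pdev_old = pdev
    return beta, H, pdev_old, False


def fit_hierarchical_gam(
    cohort: Cohort,
    basis_dim: int = 10,
    max_outer: int = 150,
    keep_covariance: bool = True,
) -> HierarchicalGamModel:
    """Fit the hierarchical generalized additive update.

    The penalized Bernoulli log-likelihood
    ``l(beta) - 0.5*lambda_f*b_f' S b_f - 0.5*lambda_u*sum(u_i^2)``
    is maximized by penalized IRLS; the two smoothing parameters are
    chosen by Laplace-approximate restricted marginal likelihood (LAML)
    via Nelder-Mead on the log scale, with a coarse grid fallback.
    ``sigma2_u = 1 / lambda_u``; ``edf`` is the trace of the influence
    matrix.

    Requires at least two ICUs and ``basis_dim + 2`` distinct lp values.
    """
    _check_outcomes(cohort.died)
    if cohort.n_units < 2:
        raise IdentifiabilityError("hierarchical update needs >= 2 units")
    lp = cohort.lp
    y = cohort.died.astype(float)
    basis = PenalizedBSplineBasis(lp, dim=basis_dim)
    B = basis.design(lp)
    codes, unit_labels = pd.factorize(cohort.data["unit_id"], sort=True)
    m = len(unit_labels)
    n = cohort.n
    U = np.zeros((n, m))
    U[np.arange(n), codes] = 1.0
    X = np.column_stack([np.ones(n), B, U])
    p = X.shape[1]
    sl_f = slice(1, 1 + B.shape[1])
    sl_u = slice(1 + B.shape[1], p)
    S_f = basis.penalty()
    eig = np.linalg.eigvalsh(S_f)
    rank_f = int(np.sum(eig > eig.max() * 1e-10))

    warm = {"beta": np.zeros(p)}
    warm["beta"][0] = float(np.log(y.mean() / (1 - y.mean())))

    def neg_laml(rho):
        rho = np.clip(rho, -_RHO_BOUND, _RHO_BOUND)
        lam_f, lam_u = np.exp(rho)
        S = _assemble_penalty(p, sl_f, sl_u, S_f, lam_f, lam_u)
        beta, H, pdev, ok = _pirls(X, y, S, warm["beta"])
        if not ok or not np.isfinite(pdev):
            return np.inf
        warm["beta"] = beta
        sign, logdet = np.linalg.slogdet(H + S)
        if sign <= 0:
            return np.inf
        ll = _bernoulli_loglik(expit(X @ beta), y)
        # log pseudo-determinant of the penalty, lambda-dependent part only
        log_pdet_S = rank_f * rho[0] + m * rho[1]
        return -ll + 0.5 * float(beta @ S @ beta) + 0.5 * logdet - 0.5 * log_pdet_S

    x0 = np.array([0.0, 2.0])
    res = optimize.minimize(
        neg_laml,
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-2, "fatol": 1e-3, "maxfev": max_outer},
    )
    rho_hat = np.clip(res.x, -_RHO_BOUND, _RHO_BOUND)
    if not np.isfinite(res.fun):
        # fallback: coarse LAML grid (generalized search when the outer
        # optimizer fails to find a finite objective)
        logger.warning("smoothing-parameter search failed; using grid fallback")
        grid = np.linspace(-8, 8, 5)
        vals = [(neg_laml([rf, ru]), rf, ru) for rf in grid for ru in grid]
        vals = [v for v in vals if np.isfinite(v[0])]
        if not vals:
            raise ConvergenceError("hierarchical GAM fit failed on the LAML grid")
        _, rf, ru = min(vals)
        rho_hat = np.array([rf, ru])

    lam_f, lam_u = np.exp(rho_hat)
    S = _assemble_penalty(p, sl_f, sl_u, S_f, lam_f, lam_u)
    beta, H, pdev, ok = _pirls(X, y, S, warm["beta"])
    if not ok:
        raise ConvergenceError(
            f"penalized IRLS failed to converge (last penalized deviance {pdev:.6g})"
        )
    Vinv = np.linalg.inv(H + S)
    edf = float(np.trace(Vinv @ H))
    loglik = _bernoulli_loglik(expit(X @ beta), y)
    unit_effects = {
        _key(lab): float(b) for lab, b in zip(unit_labels, beta[sl_u])
    }
    return HierarchicalGamModel(
        beta0=float(beta[0]),
        basis=basis,
        spline_coefs=np.asarray(beta[sl_f], dtype=float),
        unit_effects=unit_effects,
        smoothing={"lambda_f": float(lam_f), "lambda_u": float(lam_u)},
        sigma2_u=float(1.0 / lam_u),
        edf=edf,
        loglik=float(loglik),
        covariance=Vinv if keep_covariance else None,
    )


# ---------------------------------------------------------------------------
# deserialization
# ---------------------------------------------------------------------------

def model_from_dict(d: dict) -> _BaseModel:
    kind = d["kind"]
    if kind == OffsetInterceptModel.kind:
        return OffsetInterceptModel(beta0=d["beta0"])
    if kind == LogisticRecalModel.kind:
        return LogisticRecalModel(beta0=d["beta0"], beta1=d["beta1"])
    if kind == HierarchicalGamModel.kind:
        return HierarchicalGamModel(
            beta0=d["beta0"],
            basis=PenalizedBSplineBasis.from_dict(d["spline_basis"]),
            spline_coefs=np.asarray(d["spline_coefs"], dtype=float),
            unit_effects=dict(d["unit_effects"]),
            smoothing=d["smoothing"],
            sigma2_u=d["sigma2_u"],
            edf=d["edf"],
            loglik=d["loglik"],
        )
    raise ValueError(f"unknown model kind {kind!r}")


#: Model-number -> fitting function, as numbered in registry reports.
FITTERS = {
    1: fit_offset_intercept,
    2: fit_logistic_recal,
    3: fit_hierarchical_gam,
}


def load_model(path) -> _BaseModel:
    """Load a model saved with ``model.save(path)``."""
    with open(path) as fh:
        return model_from_dict(json.load(fh))
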