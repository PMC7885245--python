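"""Penalized cubic B-spline basis for smooth recalibration curves.

The smooth ``f(lp)`` of the hierarchical model uses a cubic B-spline
basis with interior knots at quantiles of the observed linear
predictor, the exact integrated-squared-second-derivative roughness
penalty, and a sum-to-zero identifiability constraint over the fitting
sample (the constant is carried by the model intercept instead).
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline

_DEGREE = 3
# 2-point Gauss-Legendre is exact for the piecewise-quadratic integrand
# (products of piecewise-linear second derivatives of cubics).
_GAUSS_X = np.array([-1.0, 1.0]) / np.sqrt(3.0)
_GAUSS_W = np.array([1.0, 1.0])


class PenalizedBSplineBasis:
    """Cubic B-spline basis with roughness penalty and centering constraint.

    Parameters
    ----------
    x : array-like
        Sample of covariate values; knots are placed at its quantiles.
    dim : int
        Number of unconstrained basis functions (>= 4); the constrained
        basis has ``dim - 1`` columns.
    """

    def __init__(self, x, dim: int = 10):
        x = np.asarray(x, dtype=float)
        if dim < 4:
            raise ValueError("basis dimension must be at least 4")
        if np.unique(x).size < dim + 2:
            raise ValueError(
                f"need at least dim + 2 = {dim + 2} distinct covariate "
                f"values, got {np.unique(x).size}"
            )
        self.dim = int(dim)
        lo, hi = float(x.min()), float(x.max())
        n_interior = dim - _DEGREE - 1
        probs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(np.unique(x), probs)
        self.knots = np.concatenate(
            [[lo] * (_DEGREE + 1), interior, [hi] * (_DEGREE + 1)]
        )
        self._lo, self._hi = lo, hi
        # centering constraint: columns of the constrained basis average
        # to zero over the construction sample
        raw = self._raw_design(x)
        c = raw.mean(axis=0)
        # orthonormal null-space basis of the 1 x dim constraint row
        _, _, vt = np.linalg.svd(c[None, :])
        self.transform = vt[1:].T  # (dim, dim-1)
        self._penalty = None

    @classmethod
    def _from_parts(cls, knots, transform):
        obj = cls.__new__(cls)
        obj.knots = np.asarray(knots, dtype=float)
        obj.transform = np.asarray(transform, dtype=float)
        obj.dim = obj.knots.size - _DEGREE - 1
        obj._lo = float(obj.knots[0])
        obj._hi = float(obj.knots[-1])
        obj._penalty = None
        return obj

    @property
    def n_coefs(self) -> int:
        """Number of constrained coefficients."""
        return self.transform.shape[1]

    def _raw_design(self, x) -> np.ndarray:
        # evaluation is clamped to the knot range: recalibration is only
        # trusted on the support of the fitting sample
        xc = np.clip(np.asarray(x, dtype=float), self._lo, self._hi)
        return BSpline.design_matrix(xc, self.knots, _DEGREE).toarray()

    def design(self, x) -> np.ndarray:
        """Constrained design matrix, shape ``(len(x), dim - 1)``."""
        return self._raw_design(x) @ self.transform

    def penalty(self) -> np.ndarray:
        """Constrained roughness penalty ``Z' S Z`` (exact integral)."""
        if self._penalty is None:
            spl = BSpline(self.knots, np.eye(self.dim), _DEGREE)
            d2 = spl.derivative(2)
            S = np.zeros((self.dim, self.dim))
            breaks = np.unique(self.knots)
            for a, b in zip(breaks[:-1], breaks[1:]):
                half = 0.5 * (b - a)
                mid = 0.5 * (a + b)
                for gx, gw in zip(_GAUSS_X, _GAUSS_W):
                    row = np.atleast_1d(d2(mid + half * gx))
                    S += gw * half * np.outer(row, row)
            self._penalty = self.transform.T @ S @ self.transform
        return self._penalty

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "type": "cubic-bspline",
            "dim": self.dim,
            "knots": self.knots.tolist(),
            "transform": self.transform.tolist(),
            "constraint": "sum-to-zero over fitting sample",
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PenalizedBSplineBasis":
        return cls._from_parts(d["knots"], d["transform"])
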