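"""scikit-learn style estimators for survival-curve fitting.

:class:`UMACurve` implements the parameterised-logit linear regression for the
two-parameter logistic-in-dose survival model: the transform
``y = ln[S/(A-S)]`` maps model-exact data onto a straight line
``y = gamma0 - gamma*D`` when ``A = n/(n-1)``, so the fit is a one-dimensional
search over the logit ceiling ``A`` maximising the R^2 of an ordinary
least-squares line through the transformed points.  Three branches are
searched:

* positive-A branch (``A > 1``, recovers ``n > 1``), transform ``ln[S/(A-S)]``;
* negative-A branch (``A < 0``, recovers ``0 < n < 1``), transform ``ln[S/(S-A)]``;
* the ``n = 1`` boundary, a plain regression of ``ln S`` on ``D``.

The branch with the best R^2 wins; the boundary model is preferred when it is
within ``tie_tolerance`` of the best (parsimony).  In every branch
``n = |A| * exp(gamma0)`` with the sign convention above.

:class:`LQCurve` is the linear-quadratic comparison fit
``-ln S = alpha*D + beta*D**2`` (zero intercept) used to exhibit the
bending-curve discrepancy at high dose.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import minimize_scalar
from sklearn.base import BaseEstimator, RegressorMixin

from .exceptions import ConvergenceError, DataError
from . import model

__all__ = ["UMACurve", "LQCurve"]

# below this RMS residual on the logit line the fit is numerically exact
# (experimental survival errors are orders of magnitude larger) and
# standardized residuals are structured round-off, not outliers
_RESID_FLOOR = 1e-6


def _columnize(X) -> np.ndarray:
    x = np.asarray(X, dtype=float)
    if x.ndim == 2:
        if x.shape[1] != 1:
            raise DataError(f"expected a single dose column, got shape {x.shape}")
        x = x[:, 0]
    elif x.ndim != 1:
        raise DataError(f"doses must be 1-D or a single column, got ndim={x.ndim}")
    if not np.all(np.isfinite(x)):
        raise DataError("doses must be finite")
    if np.any(x < 0):
        raise DataError("doses must be non-negative")
    return x


def _line_fit(x: np.ndarray, y: np.ndarray, w: np.ndarray | None = None):
    """Weighted least-squares line through (x, y); returns slope, intercept, R^2, residuals."""
    if w is None:
        w = np.ones_like(x)
    wsum = w.sum()
    xm = np.sum(w * x) / wsum
    ym = np.sum(w * y) / wsum
    sxx = np.sum(w * (x - xm) ** 2)
    if sxx == 0:
        raise DataError("degenerate design: all doses identical")
    slope = np.sum(w * (x - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    res = y - (intercept + slope * x)
    ss_res = np.sum(w * res**2)
    ss_tot = np.sum(w * (y - ym) ** 2)
    if ss_tot > 0:
        r2 = 1.0 - ss_res / ss_tot
    else:
        r2 = 1.0 if ss_res == 0 else 0.0
    return slope, intercept, r2, res


class UMACurve(RegressorMixin, BaseEstimator):
    """Estimate (gamma, n) from a clonogenic assay by parameterised-logit regression.

    Parameters
    ----------
    a_max : float
        Upper bound of the |A| search interval (both branches).
    a_margin : float
        Relative margin by which the positive-branch A must exceed the largest
        admissible survival value.
    n_scan : int
        Number of log-spaced points in the coarse scan over A before the
        bracketed golden-type refinement.
    outlier_threshold : float
        Absolute standardized logit residual above which a point is flagged;
        residuals are standardized by the robust MAD scale so that a gross
        outlier cannot mask itself.
    tie_tolerance : float
        R^2 margin within which the one-parameter n=1 boundary model is
        preferred over an interior-A fit.
    weighting : {"delta", "ols", "sd"}
        Regression weights on the logit scale.  ``"delta"`` (default) assumes
        homoscedastic errors on ln S and propagates them through the
        transform (w = (dy/d ln S)^-2 = ((A-S)/A)^2 on the positive branch) —
        the GLS weights implied by a multiplicative lognormal error model.
        ``"ols"`` is unweighted least squares on the transformed values.
        ``"sd"`` uses per-point 1/sd^2 weights delta-propagated through the
        transform; it falls back to ``"delta"`` when no sd column is given.
    flag_outliers : bool
        Whether to flag outliers and attach a refit without them.

    Attributes
    ----------
    gamma_ : float
        First-order activation constant, Gy^-1 (negative of the logit slope).
    n_ : float
        Reaction-rate ratio, ``|A_| * exp(gamma0_)`` (1.0 on the boundary branch).
    A_ : float
        Fitted logit ceiling (``inf`` on the n=1 branch).
    gamma0_ : float
        Logit-line intercept.
    r_squared_ : float
        Coefficient of determination on the transformed (logit) scale.
    branch_ : str
        One of ``"logit_pos"``, ``"logit_neg"``, ``"exponential"``.
    residuals_ : ndarray
        Per-point logit residuals (NaN for points excluded by S >= A).
    outlier_mask_ : ndarray of bool
        Flagged points (large standardized residual, or inadmissible S >= A).
    refit_ : UMACurve or None
        Fit with flagged points removed, when any were flagged.
    """

    def __init__(
        self,
        a_max: float = 100.0,
        a_margin: float = 1e-6,
        n_scan: int = 50,
        outlier_threshold: float = 2.5,
        tie_tolerance: float = 1e-6,
        weighting: str = "delta",
        flag_outliers: bool = True,
    ):
        self.a_max = a_max
        self.a_margin = a_margin
        self.n_scan = n_scan
        self.outlier_threshold = outlier_threshold
        self.tie_tolerance = tie_tolerance
        self.weighting = weighting
        self.flag_outliers = flag_outliers

    # -- transforms -------------------------------------------------------

    def _weights(self, s, sd, dy_dlns):
        """Regression weights for logit values with slope dy/d(ln S) = dy_dlns."""
        if self.weighting == "ols":
            return None
        if self.weighting == "sd" and sd is not None:
            sd = np.asarray(sd, dtype=float)
            if np.all(np.isfinite(sd)) and np.all(sd > 0):
                return (s / (sd * np.abs(dy_dlns))) ** 2
        if self.weighting not in ("delta", "sd"):
            raise DataError(f"unknown weighting {self.weighting!r}")
        return 1.0 / np.asarray(dy_dlns, dtype=float) ** 2

    def _eval_pos(self, A, d, s, sd):
        mask = s < A * (1.0 - 1e-12)
        if mask.sum() < 3 or np.unique(d[mask]).size < 3:
            return None
        dm, sm = d[mask], s[mask]
        y = np.log(sm) - np.log(A - sm)
        w = self._weights(sm, None if sd is None else sd[mask], A / (A - sm))
        slope, intercept, r2, res = _line_fit(dm, y, w)
        return {"r2": r2, "slope": slope, "intercept": intercept, "A": A,
                "mask": mask, "res": res, "w": w, "branch": "logit_pos"}

    def _eval_neg(self, A, d, s, sd):
        # A < 0, S - A > 0 for every positive survival value
        y = np.log(s) - np.log(s - A)
        w = self._weights(s, sd, -A / (s - A))
        slope, intercept, r2, res = _line_fit(d, y, w)
        mask = np.ones_like(s, dtype=bool)
        return {"r2": r2, "slope": slope, "intercept": intercept, "A": A,
                "mask": mask, "res": res, "w": w, "branch": "logit_neg"}

    def _scan_refine(self, grid, evaluate):
        """Coarse scan over A followed by bounded golden-type refinement."""
        results = [evaluate(A) for A in grid]
        scores = np.array([-np.inf if r is None else r["r2"] for r in results])
        if not np.any(np.isfinite(scores)):
            return None
        i = int(np.argmax(scores))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        best = results[i]
        if hi > lo:
            def neg_r2(A):
                r = evaluate(A)
                return 1.0 if r is None else -r["r2"]

            opt = minimize_scalar(neg_r2, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            refined = evaluate(float(opt.x))
            if refined is not None and refined["r2"] >= best["r2"]:
                best = refined
        return best

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y, sd=None):
        """Fit doses ``X`` (Gy) against surviving fractions ``y``.

        ``sd`` are optional per-point standard deviations of the surviving
        fraction, used only when ``weighted=True``.
        """
        d = _columnize(X)
        s = np.asarray(y, dtype=float)
        if s.shape != d.shape:
            raise DataError(f"doses and survival have mismatched shapes {d.shape} vs {s.shape}")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise DataError("surviving fractions must be finite and positive")
        if d.size < 3:
            raise DataError(f"at least 3 points are required, got {d.size}")
        if np.unique(d).size < 3:
            raise DataError("at least 3 distinct doses are required")
        if sd is not None:
            sd = np.asarray(sd, dtype=float)
            if sd.shape != d.shape:
                raise DataError("sd must match the data length")

        candidates = []

        # n = 1 boundary: plain regression of ln S on D
        slope, intercept, r2, res = _line_fit(
            d, np.log(s), self._weights(s, sd, np.ones_like(s))
        )
        exp_fit = {"r2": r2, "slope": slope, "intercept": intercept, "A": math.inf,
                   "mask": np.ones_like(s, dtype=bool), "res": res,
                   "w": self._weights(s, sd, np.ones_like(s)), "branch": "exponential"}
        candidates.append(exp_fit)

        # positive branch: A in (max admissible S, a_max]
        s_le1 = s[s <= 1.0]
        a_floor = max(1.0, float(s_le1.max()) if s_le1.size else 0.0) * (1.0 + self.a_margin)
        if a_floor < self.a_max:
            grid = np.geomspace(a_floor, self.a_max, self.n_scan)
            pos = self._scan_refine(grid, lambda A: self._eval_pos(A, d, s, sd))
            if pos is not None:
                candidates.append(pos)

        # negative branch: A in [-a_max, 0), recovers 0 < n < 1
        grid = -np.geomspace(1e-3, self.a_max, self.n_scan)[::-1]  # ascending, all < 0
        neg = self._scan_refine(grid, lambda A: self._eval_neg(A, d, s, sd))
        if neg is not None:
            candidates.append(neg)

        best = max(candidates, key=lambda c: c["r2"])
        if not math.isfinite(best["r2"]):
            raise ConvergenceError("logit ceiling search found no admissible fit")
        if exp_fit["r2"] >= best["r2"] - self.tie_tolerance:
            best = exp_fit  # parsimony: one fewer parameter

        self.branch_ = best["branch"]
        self.A_ = best["A"]
        self.gamma0_ = float(best["intercept"])
        self.gamma_ = float(-best["slope"])
        if best["branch"] == "exponential":
            self.n_ = 1.0
        else:
            self.n_ = float(abs(best["A"]) * math.exp(self.gamma0_))
        self.r_squared_ = float(best["r2"])

        residuals = np.full(d.size, np.nan)
        residuals[best["mask"]] = best["res"]
        self.residuals_ = residuals
        self.outlier_mask_ = ~best["mask"]
        self.refit_ = None
        self.n_features_in_ = 1

        if self.flag_outliers:
            self._flag_and_refit(d, s, sd, best)
        return self

    def _flag_and_refit(self, d, s, sd, best):
        res = best["res"]
        if best.get("w") is not None:
            # whitened residuals: comparable scales under weighted regression
            res = res * np.sqrt(best["w"] / np.mean(best["w"]))
        if res.size > 2:
            # MAD scale resists masking by the outlier itself; RMS fallback
            # when more than half the residuals are numerically zero
            med = float(np.median(res))
            sigma = 1.4826 * float(np.median(np.abs(res - med)))
            if sigma <= _RESID_FLOOR:
                sigma = float(np.sqrt(np.sum(res**2) / (res.size - 2)))
                med = 0.0
            if sigma > _RESID_FLOOR:
                z = np.zeros(d.size)
                z[best["mask"]] = (res - med) / sigma
                self.outlier_mask_ |= np.abs(z) > self.outlier_threshold
        keep = ~self.outlier_mask_
        if self.outlier_mask_.any() and keep.sum() >= 3 and np.unique(d[keep]).size >= 3:
            sub = UMACurve(**{**self.get_params(), "flag_outliers": False})
            sub.fit(d[keep], s[keep], None if sd is None else sd[keep])
            self.refit_ = sub

    def predict(self, X):
        """Predicted surviving fractions at doses ``X`` from the fitted curve."""
        d = _columnize(X)
        params = model.UMAParameters(self.gamma_, self.n_)
        return np.asarray(model.survival(params, d))

    def params_(self, label: str = "") -> model.UMAParameters:
        """Fitted parameters as a :class:`~umasurv.model.UMAParameters`."""
        return model.UMAParameters(self.gamma_, self.n_, label)


class LQCurve(RegressorMixin, BaseEstimator):
    """Linear-quadratic comparison fit: -ln S = alpha*D + beta*D**2, zero intercept.

    Attributes
    ----------
    alpha_ : float, Gy^-1
    beta_ : float, Gy^-2
    r_squared_ : float
        1 - SS_res/SS_tot on the -ln S scale (centred total sum of squares).
    residuals_ : ndarray
    """

    def fit(self, X, y):
        d = _columnize(X)
        s = np.asarray(y, dtype=float)
        if s.shape != d.shape:
            raise DataError("doses and survival have mismatched shapes")
        if not np.all(np.isfinite(s)) or np.any(s <= 0):
            raise DataError("surviving fractions must be finite and positive")
        if d.size < 3:
            raise DataError(f"at least 3 points are required, got {d.size}")
        Z = np.column_stack([d, d**2])
        if np.linalg.matrix_rank(Z) < 2:
            raise DataError("singular design: need at least two distinct positive doses")
        t = -np.log(s)
        coef, *_ = np.linalg.lstsq(Z, t, rcond=None)
        self.alpha_, self.beta_ = (float(c) for c in coef)
        fitted = Z @ coef
        self.residuals_ = t - fitted
        ss_res = float(np.sum(self.residuals_**2))
        ss_tot = float(np.sum((t - t.mean()) ** 2))
        self.r_squared_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        d = _columnize(X)
        return np.exp(-(self.alpha_ * d + self.beta_ * d**2))
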