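"""Survival-table containers and functional wrappers over the curve estimators.

The substantive fitting logic lives in :mod:`umasurv.estimators`
(:class:`~umasurv.estimators.UMACurve`, :class:`~umasurv.estimators.LQCurve`);
this module provides the assay-table dataclass, the result records, the raw
logit transform, and a plain-text/JSON fit report.
"""

from __future__ import annotations

import dataclasses
import json
import math
from typing import Optional

import numpy as np

from . import model
from .estimators import LQCurve, UMACurve
from .exceptions import DataError, DomainError

__all__ = [
    "SurvivalAssayData",
    "LogitFitResult",
    "LQFitResult",
    "logit_transform",
    "fit_uma",
    "fit_lq",
    "fit_report",
]


@dataclasses.dataclass
class SurvivalAssayData:
    """A clonogenic-assay table: doses (Gy), surviving fractions, optional SDs."""

    doses: np.ndarray
    survival: np.ndarray
    sd: Optional[np.ndarray] = None
    label: str = ""

    def __post_init__(self) -> None:
        self.doses = np.asarray(self.doses, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        if self.doses.ndim != 1 or self.survival.ndim != 1:
            raise DataError("doses and survival must be one-dimensional")
        if self.doses.shape != self.survival.shape:
            raise DataError("doses and survival must have the same length")
        if not np.all(np.isfinite(self.doses)) or np.any(self.doses < 0):
            raise DataError("doses must be finite and non-negative")
        if not np.all(np.isfinite(self.survival)) or np.any(self.survival <= 0):
            raise DataError("surviving fractions must be finite and positive")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if self.sd.shape != self.doses.shape:
                raise DataError("sd must have the same length as doses")

    def __len__(self) -> int:
        return self.doses.size


@dataclasses.dataclass
class LogitFitResult:
    """Result of the parameterised-logit fit.

    ``n = A * exp(gamma0)`` on the positive branch, ``-A * exp(gamma0)`` on
    the negative (0 < n < 1) branch, and exactly 1 on the exponential
    boundary; for n > 1 fits ``A ~ n/(n-1)`` (the transform identity).
    """

    A: float
    gamma0: float
    gamma: float
    n: float
    r_squared: float
    residuals: np.ndarray
    outlier_mask: np.ndarray
    branch: str
    refit_without_outliers: Optional["LogitFitResult"] = None

    def params(self, label: str = "") -> model.UMAParameters:
        return model.UMAParameters(self.gamma, self.n, label)

    def to_dict(self) -> dict:
        d = {
            "A": self.A,
            "gamma0": self.gamma0,
            "gamma": self.gamma,
            "n": self.n,
            "r_squared": self.r_squared,
            "residuals": [None if not math.isfinite(r) else r for r in self.residuals],
            "outlier_mask": [bool(b) for b in self.outlier_mask],
            "branch": self.branch,
            "refit_without_outliers": (
                None
                if self.refit_without_outliers is None
                else self.refit_without_outliers.to_dict()
            ),
        }
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)


@dataclasses.dataclass
class LQFitResult:
    """Linear-quadratic comparison fit -ln S = alpha*D + beta*D**2."""

    alpha: float
    beta: float
    r_squared: float
    residuals: np.ndarray

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "r_squared": self.r_squared,
            "residuals": list(self.residuals),
        }


def logit_transform(data: SurvivalAssayData, A: float) -> np.ndarray:
    """Parameterised logit transform of the survival values at ceiling ``A``.

    Positive branch (A > 0): y = ln[S/(A-S)], which requires S < A at every
    point.  Negative branch (A < 0): y = ln[S/(S-A)], always finite.  With
    ``A = n/(n-1)`` the transform maps model-exact data onto the straight
    line ``y = ln|n-1| - gamma*D``.
    """
    s = data.survival
    if A > 0:
        bad = np.nonzero(s >= A)[0]
        if bad.size:
            raise DomainError(
                f"survival value {s[bad[0]]:g} at dose {data.doses[bad[0]]:g} Gy "
                f"is >= the logit ceiling A={A:g}"
            )
        return np.log(s) - np.log(A - s)
    if A < 0:
        return np.log(s) - np.log(s - A)
    raise DomainError("logit ceiling A must be non-zero")


def _result_from_estimator(est: UMACurve) -> LogitFitResult:
    refit = None
    if est.refit_ is not None:
        refit = _result_from_estimator(est.refit_)
    return LogitFitResult(
        A=est.A_,
        gamma0=est.gamma0_,
        gamma=est.gamma_,
        n=est.n_,
        r_squared=est.r_squared_,
        residuals=est.residuals_,
        outlier_mask=est.outlier_mask_,
        branch=est.branch_,
        refit_without_outliers=refit,
    )


def fit_uma(
    data: SurvivalAssayData,
    *,
    a_max: float = 100.0,
    n_scan: int = 50,
    outlier_threshold: float = 2.5,
    tie_tolerance: float = 1e-6,
    weighting: str = "delta",
) -> LogitFitResult:
    """Fit (gamma, n) to an assay table by parameterised-logit regression.

    Thin wrapper over :class:`~umasurv.estimators.UMACurve`; see its docstring
    for the search strategy and the meaning of the options.
    """
    est = UMACurve(
        a_max=a_max,
        n_scan=n_scan,
        outlier_threshold=outlier_threshold,
        tie_tolerance=tie_tolerance,
        weighting=weighting,
    )
    est.fit(data.doses, data.survival, sd=data.sd)
    return _result_from_estimator(est)


def fit_lq(data: SurvivalAssayData) -> LQFitResult:
    """Least-squares linear-quadratic fit of -ln S on (D, D^2), zero intercept."""
    est = LQCurve().fit(data.doses, data.survival)
    return LQFitResult(
        alpha=est.alpha_, beta=est.beta_, r_squared=est.r_squared_, residuals=est.residuals_
    )


def fit_report(fit: LogitFitResult, data: SurvivalAssayData) -> str:
    """Human-readable fit summary with derived sensitivities and the outlier audit."""
    lines = []
    label = data.label or "(unlabelled assay)"
    lines.append(f"Parameterised-logit survival fit: {label}")
    lines.append(f"  branch      : {fit.branch}")
    lines.append(f"  A           : {fit.A:.6g}")
    lines.append(f"  gamma0      : {fit.gamma0:.6g}")
    lines.append(f"  gamma       : {fit.gamma:.6g} Gy^-1")
    lines.append(f"  n           : {fit.n:.6g}")
    lines.append(f"  R^2 (logit) : {fit.r_squared:.10f}")
    try:
        p = fit.params()
        lines.append(f"  RS(0)       : {model.rs(p, 0.0):.3f} Gy^-1")
        lines.append(f"  GRS         : {model.grs(p):.3f} Gy^-1")
    except DomainError:
        lines.append("  RS(0)/GRS   : undefined outside the clinical branch")
    lines.append("  residuals (logit scale):")
    for i, (d, s) in enumerate(zip(data.doses, data.survival)):
        r = fit.residuals[i]
        flag = "  OUTLIER" if fit.outlier_mask[i] else ""
        rtxt = "excluded" if not math.isfinite(r) else f"{r:+.4e}"
        lines.append(f"    D={d:6.2f} Gy  S={s:.4e}  r={rtxt}{flag}")
    n_out = int(fit.outlier_mask.sum())
    if n_out == 0 or fit.refit_without_outliers is None:
        lines.append("  refit without outliers: identical (no outliers flagged)")
    else:
        rf = fit.refit_without_outliers
        lines.append(f"  outliers flagged: {n_out}")
        lines.append(
            f"  refit without outliers: gamma={rf.gamma:.6g} Gy^-1, n={rf.n:.6g}, "
            f"A={rf.A:.6g}, R^2={rf.r_squared:.10f}"
        )
    return "\n".join(lines)
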