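"""Closed-form unified multi-activation (UMA) survival model.

The model describes a clonogenic cell-survival curve S(D) as the solution of a
logistic equation in the dose domain,

    dS/dD = -gamma * S - kappa * S**2,        S(0) = 1,

where ``gamma`` (Gy^-1) is the first-order activation constant of the
radiation-triggered death pathways and ``kappa = delta * N0`` (Gy^-1) is the
aggregate second-order load.  The closed form is

    S(D) = n / (exp(gamma * D) - 1 + n),      n = gamma / (gamma + kappa),

with ``n`` the dimensionless ratio of the first-order reaction rate to the
total reaction rate.  ``n > 1`` gives the familiar shouldered curve (net
repair through second-order reactions, ``kappa < 0``), ``n = 1`` the pure
exponential, and ``0 < n < 1`` the inverted shoulder.  Clinical applications
use the branch ``gamma > 0, n > 0``; the full sign space of the two
parameters is classified by :func:`classify_regime`.

All doses are in Gy and all sensitivities in Gy^-1.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from typing import Union

import numpy as np

from .exceptions import DomainError, InvalidParameterError

__all__ = [
    "UMAParameters",
    "Regime",
    "RegimeClassification",
    "survival",
    "log_survival",
    "survival_course",
    "survival_second_order_only",
    "rs",
    "grs",
    "classify_regime",
    "delta_from_population",
    "n_from_rates",
]

ArrayLike = Union[float, np.ndarray]

LN2 = math.log(2.0)


@dataclasses.dataclass(frozen=True)
class UMAParameters:
    """One cell line's survival-curve parameter pair.

    Parameters
    ----------
    gamma : float
        First-order activation constant in Gy^-1.  Positive on the clinical
        branch.
    n : float
        Ratio of the first-order reaction rate to the total reaction rate
        (dimensionless).  Positive on the clinical branch.
    label : str, optional
        Free-text cell-line identifier.
    """

    gamma: float
    n: float
    label: str = ""

    def __post_init__(self) -> None:
        if not (math.isfinite(self.gamma) and math.isfinite(self.n)):
            raise InvalidParameterError(
                f"gamma and n must be finite, got gamma={self.gamma}, n={self.n}"
            )

    @property
    def kappa(self) -> float:
        """Second-order load kappa = delta*N0 = gamma*(1-n)/n, in Gy^-1."""
        if self.n == 0:
            raise DomainError("kappa is undefined at n=0 (second-order-only regime)")
        return self.gamma * (1.0 - self.n) / self.n

    @property
    def is_clinical(self) -> bool:
        """True on the clinical branch gamma > 0, n > 0."""
        return self.gamma > 0 and self.n > 0

    def to_dict(self) -> dict:
        return {"label": self.label, "gamma_per_Gy": self.gamma, "n": self.n}

    @classmethod
    def from_dict(cls, d: dict) -> "UMAParameters":
        return cls(gamma=float(d["gamma_per_Gy"]), n=float(d["n"]), label=str(d.get("label", "")))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "UMAParameters":
        return cls.from_dict(json.loads(text))


class Regime(str, enum.Enum):
    """Qualitative behaviour of the survival curve by (gamma, n) sign pattern."""

    SECOND_ORDER_DOMINATED_DEATH = "second_order_dominated_death"  # n < 0
    SECOND_ORDER_ONLY = "second_order_only"  # n = 0 (gamma = 0)
    INVERTED_SHOULDER = "inverted_shoulder"  # 0 < n < 1
    PURE_EXPONENTIAL = "pure_exponential"  # n = 1, gamma >= 0
    SHOULDERED_DEATH = "shouldered_death"  # n > 1, gamma >= 0
    NET_GROWTH = "net_growth"  # n >= 1, gamma < 0


@dataclasses.dataclass(frozen=True)
class RegimeClassification:
    regime: Regime
    survival_range: tuple[float, float]
    range_description: str


def _as_dose(dose: ArrayLike) -> np.ndarray:
    d = np.asarray(dose, dtype=float)
    if not np.all(np.isfinite(d)):
        raise InvalidParameterError("dose values must be finite")
    if np.any(d < 0):
        raise DomainError("dose must be non-negative")
    return d


def _maybe_scalar(out: np.ndarray, dose: ArrayLike) -> ArrayLike:
    return float(out) if np.ndim(dose) == 0 else out


def log_survival(params: UMAParameters, dose: ArrayLike) -> ArrayLike:
    """Natural log of the surviving fraction, overflow-safe for gamma*D >> 700.

    On the clinical branch the denominator exp(gamma*D) - 1 + n is evaluated in
    log space so that e.g. ``gamma*D = 800`` returns ``ln n - 800 - ...``
    without ever materialising ``exp(800)``.
    """
    d = _as_dose(dose)
    g, n = params.gamma, params.n
    x = g * d
    if g > 0 and n > 0:
        if n == 1.0:
            out = -x
        elif n > 1.0:
            out = math.log(n) - np.logaddexp(x, math.log(n - 1.0))
        else:
            # x >= 0 > ln(1-n), so the argument of log1p stays in (-1, 0]
            out = math.log(n) - (x + np.log1p(-(1.0 - n) * np.exp(-x)))
        return _maybe_scalar(out, dose)

    if g == 0:
        if n > 0:
            return _maybe_scalar(np.zeros_like(d), dose)
        raise DomainError(
            "survival is undefined for gamma=0, n<=0; "
            "use survival_second_order_only for the n=0 regime"
        )

    # Full deduction space (gamma < 0): exp(gamma*D) <= 1, no overflow concern.
    if n < 1.0:
        # denominator crosses zero where exp(gamma*D) = 1 - n
        d_sing = math.log(1.0 - n) / g
        if d_sing > 0 and np.any(d >= d_sing * (1.0 - 1e-12)):
            raise DomainError(
                f"survival denominator changes sign at the singular dose "
                f"D = {d_sing:.6g} Gy for gamma={g}, n={n}"
            )
    den = np.expm1(x) + n
    if np.any(den == 0):
        raise DomainError(f"survival denominator vanishes for gamma={g}, n={n}")
    s = n / den
    if np.any(s <= 0):
        raise DomainError(f"non-positive survival for gamma={g}, n={n}")
    return _maybe_scalar(np.log(s), dose)


def survival(params: UMAParameters, dose: ArrayLike) -> ArrayLike:
    """Surviving fraction S(D) = n / (exp(gamma*D) - 1 + n).

    Equals 1 at D = 0 for every admissible parameter pair and is strictly
    decreasing in D on the clinical branch.
    """
    return np.exp(log_survival(params, dose)) if np.ndim(dose) else math.exp(
        log_survival(params, dose)
    )


def _check_fractions(m) -> int:
    if not float(m).is_integer() or m < 1:
        raise DomainError(f"fraction count m must be an integer >= 1, got {m!r}")
    return int(m)


def survival_course(params: UMAParameters, m: int, dose_per_fraction: ArrayLike) -> ArrayLike:
    """Surviving fraction after m equal fractions, S(m, D) = S(D)**m.

    Computed as exp(m * ln S) so that courses like 5 x 10 Gy on a steep curve
    (S**m ~ 1e-15) keep full relative precision.
    """
    m = _check_fractions(m)
    ls = log_survival(params, dose_per_fraction)
    out = np.exp(np.asarray(ls, dtype=float) * m)
    return _maybe_scalar(out, dose_per_fraction)


def survival_second_order_only(kappa: float, dose: ArrayLike) -> ArrayLike:
    """Survival in the second-order-only regime (gamma = 0): S = 1/(kappa*D + 1).

    ``kappa = delta*N0`` must be positive, otherwise S would turn negative at
    D > -1/kappa.
    """
    if not math.isfinite(kappa) or kappa <= 0:
        raise DomainError(f"kappa must be positive and finite, got {kappa!r}")
    d = _as_dose(dose)
    return _maybe_scalar(1.0 / (kappa * d + 1.0), dose)


def rs(params: UMAParameters, dose: ArrayLike) -> ArrayLike:
    """Intrinsic radiosensitivity RS(D) = -d ln S / dD = gamma / (1 + (n-1) e^{-gamma D}).

    RS(0) = gamma/n (the non-zero initial slope); RS -> gamma as D -> infinity
    for gamma > 0 (the straight multi-target-like tail).
    """
    d = _as_dose(dose)
    g, n = params.gamma, params.n
    with np.errstate(over="ignore"):
        den = 1.0 + (n - 1.0) * np.exp(-g * d)
    if np.any(den <= 0) or not np.all(np.isfinite(den)):
        raise DomainError(
            f"radiosensitivity denominator non-positive or overflowed for gamma={g}, n={n}"
        )
    return _maybe_scalar(g / den, dose)


def grs(params: UMAParameters) -> float:
    """Global radiosensitivity: reciprocal of the mean inactivation dose.

    GRS = 1 / integral_0^inf S(D) dD = gamma*(n-1) / (n*ln n) for n != 1,
    continuously extended to gamma at n = 1.  Defined for gamma > 0, n > 0.
    """
    g, n = params.gamma, params.n
    if n <= 0:
        raise DomainError(f"GRS requires n > 0, got n={n}")
    if g <= 0:
        raise DomainError(f"GRS requires gamma > 0, got gamma={g}")
    if n == 1.0:
        return g
    return g * (n - 1.0) / (n * math.log(n))


def classify_regime(gamma: float, n: float) -> RegimeClassification:
    """Classify (gamma, n) into one of the six qualitative survival regimes.

    Total over finite reals; exactly one regime per input.  The attainable
    survival interval excludes the initial condition S(0) = 1.
    """
    if not (math.isfinite(gamma) and math.isfinite(n)):
        raise InvalidParameterError("gamma and n must be finite")
    if n < 0:
        lo = n / (n - 1.0)
        return RegimeClassification(
            Regime.SECOND_ORDER_DOMINATED_DEATH, (lo, 1.0), f"S in [{lo:.6g}, 1)"
        )
    if n == 0:
        return RegimeClassification(Regime.SECOND_ORDER_ONLY, (0.0, 1.0), "S in (0, 1)")
    if n < 1:
        return RegimeClassification(Regime.INVERTED_SHOULDER, (0.0, 1.0), "S in (0, 1)")
    if n == 1:
        if gamma < 0:
            return RegimeClassification(
                Regime.NET_GROWTH, (1.0, math.inf), "S = exp(-gamma*D) > 1"
            )
        return RegimeClassification(Regime.PURE_EXPONENTIAL, (0.0, 1.0), "S in (0, 1)")
    # n > 1
    if gamma < 0:
        hi = n / (n - 1.0)
        return RegimeClassification(Regime.NET_GROWTH, (1.0, hi), f"S in (1, {hi:.6g})")
    return RegimeClassification(Regime.SHOULDERED_DEATH, (0.0, 1.0), "S in (0, 1)")


def delta_from_population(params: UMAParameters, N0: float) -> float:
    """Per-cell second-order activation constant delta = gamma*(1-n)/(n*N0).

    Negative for n > 1 (second-order reactions repair), positive for 0 < n < 1
    (second-order reactions kill).  ``N0`` is the reference cell count of the
    assay.
    """
    if not math.isfinite(N0) or N0 <= 0:
        raise DomainError(f"N0 must be positive and finite, got {N0!r}")
    if params.n == 0:
        raise DomainError("delta_from_population is undefined at n=0")
    return params.gamma * (1.0 - params.n) / (params.n * N0)


def n_from_rates(gamma: float, kappa: float) -> float:
    """Reaction-rate ratio n = gamma / (gamma + kappa); inverse of the kappa relation."""
    den = gamma + kappa
    if den == 0:
        raise DomainError("gamma + kappa must be non-zero")
    return gamma / den
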