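"""Clinical dose-response layer: BED, EQD2, Poisson TCP/NTCP and derived quantities.

Everything here operates on the clinical branch (gamma > 0, n > 0) of the
survival model.  A fractionated course of ``m`` fractions of ``D`` Gy kills to
``S(D)**m`` (complete sublethal-damage repair between fractions), and all
quantities follow analytically:

* BED(m, D)  -- the single dose with the same end-of-course survival,
  ``ln[1 - n + (e^{gamma D} - 1 + n)^m / n^{m-1}] / gamma``;
* EQD2(m, D) -- the total dose of the iso-effective 2 Gy-per-fraction course;
* TCP/NTCP   -- Poisson response ``exp(-N0 * S(D)**m)`` in the expected number
  of surviving clonogens (the same sigmoid serves tumour control and
  normal-tissue complication, with different N0 and sensitivity);
* D50, TD50, BED50 -- dose per fraction / total dose / BED at 50% response,
  from ``S(D50)**m = ln2 / N0``;
* Gamma50    -- response-curve steepness per unit total dose at the 50% point,
  ``(ln2 / 2) * RS(D50)``;
* iso-survival fraction-number conversion (m fractions of D -> i fractions).

Expressions with ``e^{gamma D}`` terms are evaluated in log space so that
SBRT-scale arguments (gamma*D of several hundred) never overflow.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Optional, Sequence

import numpy as np

from .exceptions import DomainError
from .model import LN2, UMAParameters, grs, log_survival, rs, survival, survival_course

__all__ = [
    "FractionationScheme",
    "TCPContext",
    "DoseResponseSummary",
    "bed",
    "eqd2",
    "poisson_tcp",
    "tcp",
    "d50",
    "td50",
    "bed50",
    "gamma50",
    "td_for_probability",
    "convert_fraction_number",
    "summary_table",
]

GAMMA50_COEFF = LN2 / 2.0  # exact ln2/2 = 0.34657...


@dataclasses.dataclass(frozen=True)
class FractionationScheme:
    """m equal fractions of ``dose_per_fraction`` Gy."""

    m: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if not float(self.m).is_integer() or self.m < 1:
            raise DomainError(f"fraction count m must be an integer >= 1, got {self.m!r}")
        object.__setattr__(self, "m", int(self.m))
        if not math.isfinite(self.dose_per_fraction) or self.dose_per_fraction < 0:
            raise DomainError("dose per fraction must be finite and non-negative")

    @property
    def total_dose(self) -> float:
        return self.m * self.dose_per_fraction


@dataclasses.dataclass(frozen=True)
class TCPContext:
    """Clonogen count and endpoint for Poisson response calculations.

    ``clonogen_count`` is the target cell (or cluster) number N0 entering the
    Poisson exponent; the endpoint only labels whether the sigmoid is read as
    tumour control or normal-tissue complication.
    """

    clonogen_count: float
    endpoint: str = "tumour_control"

    _ENDPOINTS = ("tumour_control", "normal_tissue_complication")

    def __post_init__(self) -> None:
        if not math.isfinite(self.clonogen_count) or self.clonogen_count <= 0:
            raise DomainError("clonogen count N0 must be positive and finite")
        if self.endpoint not in self._ENDPOINTS:
            raise DomainError(f"endpoint must be one of {self._ENDPOINTS}")


def _require_clinical(params: UMAParameters) -> None:
    if not params.is_clinical:
        raise DomainError(
            f"dose-response quantities require the clinical branch gamma>0, n>0; "
            f"got gamma={params.gamma}, n={params.n}"
        )


def _log_denominator(params: UMAParameters, dose: float) -> float:
    """ln(e^{gamma D} - 1 + n), overflow-safe, for the clinical branch."""
    x = params.gamma * dose
    n = params.n
    if n == 1.0:
        return x
    if n > 1.0:
        return float(np.logaddexp(x, math.log(n - 1.0)))
    return x + math.log1p(-(1.0 - n) * math.exp(-x))


def bed(params: UMAParameters, scheme: FractionationScheme) -> float:
    """Biologically effective dose: the single dose matching the course survival.

    BED = ln[1 - n + (e^{gamma D} - 1 + n)^m / n^{m-1}] / gamma, evaluated in
    log space; satisfies survival(BED) == survival_course(m, D).
    """
    _require_clinical(params)
    n, g = params.n, params.gamma
    m, D = scheme.m, scheme.dose_per_fraction
    term = m * _log_denominator(params, D) - (m - 1) * math.log(n)
    if n > 1.0:
        arg = -(n - 1.0) * math.exp(-term)
        if arg <= -1.0:
            raise DomainError("BED argument non-positive (outside the clinical branch)")
        inner = term + math.log1p(arg)
    elif n == 1.0:
        inner = term
    else:
        inner = float(np.logaddexp(term, math.log(1.0 - n)))
    return inner / g


def eqd2(params: UMAParameters, scheme: FractionationScheme) -> float:
    """Equivalent total dose in 2 Gy fractions with the same biological effect.

    EQD2 = 2m * [ln(e^{gamma D}-1+n) - ln n] / [ln(e^{2 gamma}-1+n) - ln n].
    """
    _require_clinical(params)
    den = _log_denominator(params, 2.0) - math.log(params.n)
    if den == 0:
        raise DomainError("EQD2 denominator vanishes (gamma must be positive)")
    num = _log_denominator(params, scheme.dose_per_fraction) - math.log(params.n)
    return 2.0 * scheme.m * num / den


def poisson_tcp(clonogen_count: float, total_surviving_fraction: float) -> float:
    """Poisson control/complication probability exp(-N0 * S_total)."""
    if not math.isfinite(clonogen_count) or clonogen_count <= 0:
        raise DomainError("clonogen count N0 must be positive and finite")
    if not 0 < total_surviving_fraction <= 1:
        raise DomainError("total surviving fraction must lie in (0, 1]")
    return math.exp(-clonogen_count * total_surviving_fraction)


def tcp(params: UMAParameters, ctx: TCPContext, scheme: FractionationScheme) -> float:
    """TCP (or NTCP, by the same formula) of a fractionated course."""
    _require_clinical(params)
    s_total = survival_course(params, scheme.m, scheme.dose_per_fraction)
    return math.exp(-ctx.clonogen_count * s_total)


def d50(params: UMAParameters, m: int, ctx: TCPContext) -> float:
    """Dose per fraction at 50% response: solution of tcp = 1/2.

    Derived from S(D50)**m = ln2/N0:
    D50 = ln(1 + n * [(N0/ln2)^{1/m} - 1]) / gamma.
    """
    _require_clinical(params)
    if not float(m).is_integer() or m < 1:
        raise DomainError(f"fraction count m must be an integer >= 1, got {m!r}")
    N0 = ctx.clonogen_count
    if N0 <= LN2:
        raise DomainError(f"N0 must exceed ln2 for a 50% point to exist, got {N0}")
    q = math.exp((math.log(N0) - math.log(LN2)) / m)  # (N0/ln2)^(1/m)
    return math.log1p(params.n * (q - 1.0)) / params.gamma


def td50(params: UMAParameters, m: int, ctx: TCPContext) -> float:
    """Total dose at 50% response, m * D50."""
    return m * d50(params, m, ctx)


def bed50(params: UMAParameters, m: int, ctx: TCPContext) -> float:
    """BED of the 50%-response course: bed at (m, D50)."""
    return bed(params, FractionationScheme(m, d50(params, m, ctx)))


def gamma50(params: UMAParameters, m: int, ctx: TCPContext) -> float:
    """Steepness of the response curve per unit total dose at the 50% point.

    Analytically (ln2/2) * RS(D50): the total-dose derivative of
    exp(-N0 * S(TD/m)**m) evaluated where N0*S**m = ln2.
    """
    return GAMMA50_COEFF * rs(params, d50(params, m, ctx))


def td_for_probability(params: UMAParameters, m: int, ctx: TCPContext,
                       target: Optional[float] = None) -> float:
    """Total dose for ~80% tumour control or ~20% normal-tissue complication.

    Linearises the sigmoid at its midpoint: TD50 + 0.3/Gamma50 for the tumour
    endpoint (target 0.8), TD50 - 0.3/Gamma50 for the normal-tissue endpoint
    (target 0.2).  ``target`` defaults from ``ctx.endpoint``.
    """
    if target is None:
        target = 0.8 if ctx.endpoint == "tumour_control" else 0.2
    if target not in (0.8, 0.2):
        raise DomainError("target must be 0.8 (tumour) or 0.2 (normal tissue)")
    sign = 1.0 if target == 0.8 else -1.0
    return td50(params, m, ctx) + sign * 0.3 / gamma50(params, m, ctx)


def convert_fraction_number(params: UMAParameters, scheme: FractionationScheme,
                            i: int) -> float:
    """Iso-survival dose per fraction when re-fractionating m x D into i fractions.

    D_i = (1/gamma) * ln(1 + n * [S(D)^{-m/i} - 1]); by construction
    survival(D_i)**i == survival(D)**m.
    """
    _require_clinical(params)
    if not float(i).is_integer() or i < 1:
        raise DomainError(f"target fraction count must be an integer >= 1, got {i!r}")
    t = -(scheme.m / i) * log_survival(params, scheme.dose_per_fraction)
    n = params.n
    # ln(1 + n*(e^t - 1)) = ln(n e^t + (1-n)), log-space for large t
    if t < 500.0:
        inner = math.log1p(n * math.expm1(t))
    elif n >= 1.0:
        inner = t + math.log(n) + math.log1p(-(n - 1.0) / n * math.exp(-t))
    else:
        inner = float(np.logaddexp(t + math.log(n), math.log(1.0 - n)))
    return inner / params.gamma


@dataclasses.dataclass
class DoseResponseSummary:
    """One cell line's row of derived clinical quantities for a given course.

    Probabilities are stored as fractions; ``as_dict`` can render them as
    percentages at table precision.  ``error`` is set (and the numeric fields
    left None) when the inputs fall outside the clinical branch.
    """

    label: str
    gamma: float
    n: float
    scheme: FractionationScheme
    target_fractions: int
    survival_per_fraction: Optional[float] = None
    rs0: Optional[float] = None
    grs: Optional[float] = None
    bed: Optional[float] = None
    eqd2: Optional[float] = None
    tcp: Optional[dict] = None  # N0 -> probability
    d50: Optional[dict] = None
    bed50: Optional[dict] = None
    gamma50: Optional[dict] = None
    dose_converted: Optional[float] = None
    error: Optional[str] = None

    def as_dict(self, percent: bool = True) -> dict:
        """Flat record; TCP optionally as percent for table parity."""
        out = {
            "label": self.label,
            "gamma_per_Gy": self.gamma,
            "n": self.n,
            "m": self.scheme.m,
            "dose_per_fraction_Gy": self.scheme.dose_per_fraction,
            "error": self.error,
        }
        if self.error is not None:
            return out
        out.update(
            {
                "S(D)": self.survival_per_fraction,
                "RS(0)_per_Gy": self.rs0,
                "GRS_per_Gy": self.grs,
                "BED_Gy": self.bed,
                "EQD2_Gy": self.eqd2,
            }
        )
        for N0, p in self.tcp.items():
            out[f"TCP(N0={N0:g})" + ("_pct" if percent else "")] = 100.0 * p if percent else p
        for N0, v in self.d50.items():
            out[f"D50_Gy(N0={N0:g})"] = v
        for N0, v in self.bed50.items():
            out[f"BED50_Gy(N0={N0:g})"] = v
        for N0, v in self.gamma50.items():
            out[f"Gamma50_per_Gy(N0={N0:g})"] = v
        out[f"D_{self.target_fractions}fx_Gy"] = self.dose_converted
        return out


def summary_table(
    cell_lines: Sequence[UMAParameters],
    scheme: FractionationScheme,
    clonogen_counts: Sequence[float],
    target_fractions: int = 3,
) -> list[DoseResponseSummary]:
    """One summary row per cell line; rows that fail are marked, not fatal."""
    rows = []
    for p in cell_lines:
        row = DoseResponseSummary(
            label=p.label, gamma=p.gamma, n=p.n, scheme=scheme,
            target_fractions=int(target_fractions),
        )
        try:
            row.survival_per_fraction = survival(p, scheme.dose_per_fraction)
            row.rs0 = rs(p, 0.0)
            row.grs = grs(p)
            row.bed = bed(p, scheme)
            row.eqd2 = eqd2(p, scheme)
            row.tcp, row.d50, row.bed50, row.gamma50 = {}, {}, {}, {}
            for N0 in clonogen_counts:
                ctx = TCPContext(N0)
                row.tcp[N0] = tcp(p, ctx, scheme)
                row.d50[N0] = d50(p, scheme.m, ctx)
                row.bed50[N0] = bed50(p, scheme.m, ctx)
                row.gamma50[N0] = gamma50(p, scheme.m, ctx)
            row.dose_converted = convert_fraction_number(p, scheme, target_fractions)
        except DomainError as exc:
            row.error = str(exc)
        rows.append(row)
    return rows
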