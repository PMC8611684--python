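"""In-text parameter fixtures, a noisy clonogenic-assay generator, and the ODE oracle.

The fixture sets are the published (gamma, n) pairs: five lung-cancer cell
lines (an SBRT-oriented panel spanning squamous, large-cell, small-cell and
adeno histologies) and four skin lines (three fibroblast strains of differing
genetic background plus adipose-derived stem cells).  No public assay tables
exist for the underlying curves, so tests run on synthetic assays sampled
from the closed form with multiplicative lognormal noise -- survival curves
live on a log scale, so a log-normal error model is the natural default.

:func:`ode_oracle` integrates the defining logistic initial-value problem
dS/dD = -gamma*S - kappa*S**2 numerically and is the brute-force reference
the closed form is validated against.
"""

from __future__ import annotations

import dataclasses
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import ConvergenceError, DomainError
from .fitting import SurvivalAssayData
from .model import UMAParameters, survival

__all__ = [
    "NoiseModel",
    "DEFAULT_DOSES",
    "fixtures_table1",
    "fixtures_skin",
    "get_fixture",
    "sample_assay",
    "ode_oracle",
]

# the published assay range: 0..12 Gy in 1 Gy steps
DEFAULT_DOSES = np.arange(0.0, 13.0)

_TABLE1 = (
    UMAParameters(0.90, 12.00, "SW1573 24 h DP"),
    UMAParameters(0.33, 3.20, "HX147"),
    UMAParameters(0.44, 4.00, "HX149M"),
    UMAParameters(0.45, 4.00, "HX144"),
    UMAParameters(0.59, 4.50, "HC12"),
)

_SKIN = (
    UMAParameters(0.67, 2.00, "Li106 normal fibroblast"),
    UMAParameters(1.08, 2.00, "GM1142 retinoblastoma"),
    UMAParameters(2.27, 2.00, "CRCL1343 ataxia telangiectasia"),
    UMAParameters(0.90, 1.20, "adipose-derived stem cells"),
)


def fixtures_table1() -> tuple[UMAParameters, ...]:
    """The five lung-cancer cell-line parameter pairs."""
    return _TABLE1


def fixtures_skin() -> tuple[UMAParameters, ...]:
    """The three skin-fibroblast strains and the adipose-derived stem cells."""
    return _SKIN


def get_fixture(label: str) -> UMAParameters:
    """Look up a fixture by (case-insensitive) label or its leading token."""
    want = label.strip().lower()
    for p in _TABLE1 + _SKIN:
        full = p.label.lower()
        if want == full or want == full.split()[0]:
            return p
    raise KeyError(f"no fixture cell line named {label!r}")


@dataclasses.dataclass(frozen=True)
class NoiseModel:
    """Multiplicative lognormal noise on the surviving fraction.

    ``sigma_log`` is the standard deviation of the additive Gaussian
    perturbation of ln S; ``replicates`` independent draws per dose are
    averaged on the log scale.  The same seed always reproduces the same
    assay.
    """

    sigma_log: float = 0.05
    seed: int = 0
    replicates: int = 1

    def __post_init__(self) -> None:
        if self.sigma_log < 0:
            raise DomainError("sigma_log must be non-negative")
        if self.replicates < 1:
            raise DomainError("replicates must be >= 1")


def sample_assay(
    params: UMAParameters,
    doses: Optional[Sequence[float]] = None,
    noise: NoiseModel = NoiseModel(),
) -> SurvivalAssayData:
    """Draw a synthetic clonogenic assay S_i = S(D_i) * exp(eps_i).

    eps ~ Normal(0, sigma_log^2); with ``replicates > 1`` the replicate
    log-survivals are averaged and their sample SD (on the survival scale,
    delta method) fills the ``sd`` column.
    """
    d = DEFAULT_DOSES.copy() if doses is None else np.asarray(doses, dtype=float)
    s_true = np.asarray(survival(params, d), dtype=float)
    rng = np.random.default_rng(noise.seed)
    eps = rng.normal(0.0, noise.sigma_log, size=(noise.replicates, d.size))
    log_s = np.log(s_true) + eps
    mean_log = log_s.mean(axis=0)
    s = np.exp(mean_log)
    sd = None
    if noise.replicates > 1:
        sd = s * log_s.std(axis=0, ddof=1)
    return SurvivalAssayData(doses=d, survival=s, sd=sd, label=params.label)


def ode_oracle(gamma: float, kappa: float, dose_grid: Sequence[float]) -> np.ndarray:
    """Numerically integrate dS/dD = -gamma*S - kappa*S**2, S(0)=1.

    Integrated in log-survival (u = ln S, du/dD = -gamma - kappa*e^u) so the
    step control tracks *relative* accuracy even where S underflows toward
    1e-20; local tolerance 1e-12.  Returns S on ``dose_grid``.
    """
    d = np.asarray(dose_grid, dtype=float)
    if d.ndim != 1 or d.size == 0 or np.any(np.diff(d) <= 0) or d[0] < 0:
        raise DomainError("dose_grid must be strictly increasing and start at >= 0")

    def rhs(_, u):
        return [-gamma - kappa * np.exp(u[0])]

    t_span = (0.0, float(d[-1]) if d[-1] > 0 else 1e-12)
    sol = solve_ivp(
        rhs, t_span, [0.0], t_eval=np.clip(d, 0.0, t_span[1]),
        method="DOP853", rtol=1e-12, atol=1e-12,
    )
    if not sol.success:
        raise ConvergenceError(f"ODE integration failed: {sol.message}")
    return np.exp(sol.y[0])
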