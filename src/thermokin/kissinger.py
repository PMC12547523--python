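"""Kissinger frequency-factor estimation and activation thermodynamics.

The Kissinger relation links the DTG peak temperature Tp at each heating rate
β to the kinetic pair (Ea, A):

    ln(β / Tp²) = −Ea/(R·Tp) + ln(A·R/Ea)

Regressing ln(β/Tp²) on 1/Tp over several heating rates yields Ea from the
slope and A from the intercept. Given an Ea from an isoconversional method,
the same stationarity condition evaluated at a single (β, Tp) pair gives the
per-rate frequency factor

    A = β·Ea·exp(Ea/(R·Tp)) / (R·Tp²)

Transition-state theory then provides the activation thermodynamics:

    ΔG = Ea + R·Tp·ln(Kb·Tp / (h·A))      (A in s⁻¹)
    ΔH = Ea − R·T(α)
    ΔS = (ΔH − ΔG) / Tm

where Kb and h are the Boltzmann and Planck constants, T(α) the temperature
at the conversion being characterized, and Tm a reference (DTG peak)
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .constants import KB, PLANCK, R
from .thermogram import PeakInfo

__all__ = [
    "KissingerResult",
    "FrequencyFactorResult",
    "ThermoParams",
    "kissinger_regression",
    "frequency_factor",
    "frequency_factors",
    "thermo_params",
]


@dataclass(frozen=True)
class KissingerResult:
    Ea: float  # J/mol
    A: float  # 1/min
    r2: float
    slope: float
    intercept: float


@dataclass(frozen=True)
class FrequencyFactorResult:
    """Per-heating-rate A values and their geometric-mean representative."""

    per_beta_A: dict  # beta -> A, 1/min
    A: float  # geometric mean, 1/min
    Ea_used: float  # J/mol
    Tp_used: dict  # beta -> Tp, K


@dataclass(frozen=True)
class ThermoParams:
    """Activation thermodynamics at one conversion level (SI, J-based)."""

    alpha: float
    dG: float  # J/mol
    dH: float  # J/mol
    dS: float  # J/(mol K)
    T_alpha: float
    Tp: float
    Tm: float


def kissinger_regression(peaks: list[PeakInfo]) -> KissingerResult:
    """OLS of ln(β/Tp²) on 1/Tp; Ea = −slope·R, A = (Ea/R)·exp(intercept)."""
    if len(peaks) < 3:
        raise ValueError(f"need >= 3 peaks at distinct heating rates, got {len(peaks)}")
    betas = np.array([p.beta for p in peaks])
    tps = np.array([p.Tp for p in peaks])
    for b in np.unique(betas):
        tp_b = tps[betas == b]
        if len(tp_b) > 1 and np.ptp(tp_b) > 1e-9:
            raise ValueError(f"conflicting peak temperatures for beta={b:g}")
    ub, idx = np.unique(betas, return_index=True)
    if len(ub) < 3:
        raise ValueError("need >= 3 distinct heating rates")
    betas, tps = betas[np.sort(idx)], tps[np.sort(idx)]
    x = 1.0 / tps
    y = np.log(betas / tps**2)
    res = linregress(x, y)
    Ea = -res.slope * R
    A = Ea / R * np.exp(res.intercept)
    return KissingerResult(Ea=float(Ea), A=float(A), r2=float(res.rvalue**2),
                           slope=float(res.slope), intercept=float(res.intercept))


def frequency_factor(Ea: float, beta: float, Tp: float) -> float:
    """A = β·Ea·exp(Ea/(R·Tp)) / (R·Tp²), min⁻¹."""
    if Ea <= 0 or beta <= 0 or Tp <= 0:
        raise ValueError("Ea, beta and Tp must all be positive")
    return beta * Ea * np.exp(Ea / (R * Tp)) / (R * Tp**2)


def frequency_factors(Ea: float, peaks: list[PeakInfo]) -> FrequencyFactorResult:
    """Per-β frequency factors for one Ea, combined by geometric mean.

    A is exponentially sensitive to Ea/(R·Tp), so individual per-rate values
    spread widely; the geometric mean is the natural central value on the
    log scale where the Arrhenius law is linear.
    """
    if not peaks:
        raise ValueError("no peaks supplied")
    per = {p.beta: frequency_factor(Ea, p.beta, p.Tp) for p in peaks}
    gmean = float(np.exp(np.mean(np.log(list(per.values())))))
    return FrequencyFactorResult(
        per_beta_A=per, A=gmean, Ea_used=Ea, Tp_used={p.beta: p.Tp for p in peaks}
    )


def thermo_params(
    Ea: float,
    A: float,
    T_alpha: float,
    Tp: float,
    Tm: float,
    alpha: float = np.nan,
    a_time_unit: str = "s",
) -> ThermoParams:
    """Activation ΔG, ΔH, ΔS from (Ea, A) and characteristic temperatures.

    Parameters
    ----------
    Ea : float
        Activation energy, J/mol.
    A : float
        Pre-exponential factor, min⁻¹.
    T_alpha : float
        Temperature characterizing this conversion level (used in ΔH), K.
    Tp : float
        DTG peak temperature (used in ΔG), K.
    Tm : float
        Reference temperature for the entropy closure ΔS = (ΔH − ΔG)/Tm, K.
    a_time_unit : {"s", "min"}
        With "s" (default) A is converted min⁻¹ → s⁻¹ before forming
        Kb·Tp/(h·A), keeping the ratio dimensionless; "min" uses A as given,
        the convention some published tables follow.

    The closures ΔH = Ea − R·T_alpha and ΔS = (ΔH − ΔG)/Tm hold exactly by
    construction.
    """
    if min(T_alpha, Tp, Tm) <= 0:
        raise ValueError("temperatures must be positive")
    if A <= 0 or Ea <= 0:
        raise ValueError("Ea and A must be positive")
    if a_time_unit not in ("s", "min"):
        raise ValueError("a_time_unit must be 's' or 'min'")
    A_eff = A / 60.0 if a_time_unit == "s" else A
    dG = Ea + R * Tp * np.log(KB * Tp / (PLANCK * A_eff))
    dH = Ea - R * T_alpha
    dS = (dH - dG) / Tm
    return ThermoParams(alpha=float(alpha), dG=float(dG), dH=float(dH),
                        dS=float(dS), T_alpha=float(T_alpha), Tp=float(Tp),
                        Tm=float(Tm))
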