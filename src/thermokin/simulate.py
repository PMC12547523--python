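"""Synthetic thermogram generation with known single-step Arrhenius kinetics.

Integrates the non-isothermal rate law

    dα/dT = (A/β) · f(α) · exp(−Ea / (R·T))

for a chosen kinetic triplet (Ea, A, f) over a linear heating program, and
maps the conversion curve back to a mass-loss record. Because the generating
triplet is known exactly, these thermograms serve as ground truth for
parameter-recovery tests of the model-free estimators.

The default scenario mirrors a single dominant decomposition stage of a
pharmaceutical powder: 10 mg initial mass, main stage roughly 490–780 K,
heating rates 10/20/30/40 K·min⁻¹.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

from .constants import R
from .exceptions import IntegrationError
from .models import ReactionModel
from .thermogram import ConversionCurve, Thermogram

__all__ = [
    "KineticTriplet",
    "HeatingProgram",
    "NoiseSpec",
    "simulate_conversion",
    "conversion_to_thermogram",
    "add_noise",
    "predict_peak_temperature",
    "DEFAULT_BETAS",
]

logger = logging.getLogger(__name__)

#: heating rates of the default multi-rate scenario, K·min⁻¹
DEFAULT_BETAS = (10.0, 20.0, 30.0, 40.0)

_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class KineticTriplet:
    """(Ea, A, f): activation energy J·mol⁻¹, pre-exponential min⁻¹, model."""

    Ea: float
    A: float
    model: ReactionModel = field(default_factory=lambda: ReactionModel("F1"))

    def __post_init__(self):
        if self.Ea <= 0:
            raise ValueError(f"Ea must be positive, got {self.Ea}")
        if self.A <= 0:
            raise ValueError(f"A must be positive, got {self.A}")

    def rate_constant(self, T):
        """Arrhenius k(T) = A·exp(−Ea/RT), min⁻¹."""
        return self.A * np.exp(-self.Ea / (R * np.asarray(T, dtype=float)))


@dataclass(frozen=True)
class HeatingProgram:
    """Linear ramp: β in K·min⁻¹ over [T_start, T_end] sampled every ``step`` K."""

    beta: float
    T_start: float = 450.0
    T_end: float = 850.0
    step: float = 0.25

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        if self.T_end <= self.T_start:
            raise ValueError("T_end must exceed T_start")
        if not (0 < self.step <= (self.T_end - self.T_start) / 50):
            raise ValueError("step must be positive and <= (T_end - T_start)/50")

    def grid(self) -> np.ndarray:
        return np.arange(self.T_start, self.T_end + 0.5 * self.step, self.step)


@dataclass(frozen=True)
class NoiseSpec:
    """Multiplicative Gaussian mass noise plus linear baseline drift.

    mass_noise_sd is the relative sd of the multiplicative term; drift is the
    baseline slope per K as a fraction of the initial mass.
    """

    mass_noise_sd: float = 0.0
    drift: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.mass_noise_sd < 0:
            raise ValueError("mass_noise_sd must be non-negative")


def simulate_conversion(
    triplet: KineticTriplet,
    program: HeatingProgram,
    rtol: float = 1e-8,
    atol: float = 1e-12,
) -> ConversionCurve:
    """Integrate dα/dT = (A/β)·f(α)·exp(−Ea/RT) over the heating program.

    Uses adaptive stiff-capable integration (LSODA); the returned rate is the
    right-hand side evaluated on the solution, not a finite difference.
    α is clamped to [0, 1] and made non-decreasing; reaching completion before
    T_end is allowed (the clamp is logged).
    """
    A_over_beta = triplet.A / program.beta
    Ea = triplet.Ea
    f = triplet.model.f

    def rhs(T, y):
        a = min(max(y[0], 0.0), _CLAMP)
        return (A_over_beta * f(a) * np.exp(-Ea / (R * T)),)

    grid = program.grid()
    sol = solve_ivp(
        rhs,
        (grid[0], grid[-1]),
        [0.0],
        method="LSODA",
        t_eval=grid,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(
            f"kinetic ODE integration failed for Ea={triplet.Ea:g} J/mol, "
            f"A={triplet.A:g} 1/min, model={triplet.model.model_id}, "
            f"beta={program.beta:g} K/min: {sol.message}"
        )
    alpha = sol.y[0]
    if np.any(alpha[:-1] > _CLAMP):
        logger.warning(
            "conversion reached completion before T_end=%g K; clamped to 1",
            program.T_end,
        )
    alpha = np.clip(np.maximum.accumulate(alpha), 0.0, 1.0)
    rate = A_over_beta * f(np.minimum(alpha, _CLAMP)) * np.exp(-Ea / (R * grid))
    rate[alpha >= _CLAMP] = 0.0
    return ConversionCurve(temperature=grid, alpha=alpha, rate=rate, beta=program.beta)


def conversion_to_thermogram(
    curve: ConversionCurve, w0: float = 10.0, wf: float = 1.5, beta: float | None = None
) -> Thermogram:
    """Invert α = (w0 − wt)/(w0 − wf): mass(T) = w0 − α(T)·(w0 − wf).

    Time starts at zero: t = (T − T_start)/β, minutes.
    """
    if wf < 0 or w0 <= wf:
        raise ValueError(f"need w0 > wf >= 0, got w0={w0}, wf={wf}")
    beta = curve.beta if beta is None else beta
    T = curve.temperature
    mass = w0 - curve.alpha * (w0 - wf)
    time = (T - T[0]) / beta
    return Thermogram(
        time=time,
        temperature=T.copy(),
        mass=mass,
        beta=beta,
        meta={"w0_mg": w0, "wf_mg": wf, "synthetic": True},
    )


def add_noise(tg: Thermogram, spec: NoiseSpec) -> Thermogram:
    """Apply mass_i·(1 + ε_i) + drift·(T_i − T_0)·w0, ε ~ N(0, mass_noise_sd).

    Deterministic under a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    eps = rng.normal(0.0, spec.mass_noise_sd, size=len(tg.mass))
    w0 = tg.mass[0]
    mass = tg.mass * (1.0 + eps) + spec.drift * (tg.temperature - tg.temperature[0]) * w0
    meta = dict(tg.meta)
    meta["noise"] = {"mass_noise_sd": spec.mass_noise_sd, "drift": spec.drift,
                     "seed": spec.seed}
    return Thermogram(time=tg.time.copy(), temperature=tg.temperature.copy(),
                      mass=mass, beta=tg.beta, meta=meta)


def predict_peak_temperature(triplet: KineticTriplet, beta: float) -> float:
    """Analytic DTG peak temperature for a first-order model.

    Solves the stationarity condition of dα/dT:

        Ea·β / (R·Tp²) = A·exp(−Ea / (R·Tp))

    In log form the residual is strictly decreasing in T, so the root is
    unique; it is bracketed and solved to relative tolerance 1e-12.
    """
    if not triplet.model.is_first_order:
        raise ValueError(
            f"peak-temperature oracle is only defined for the F1 model, "
            f"got {triplet.model.model_id}"
        )
    if beta <= 0:
        raise ValueError("beta must be positive")
    Ea, A = triplet.Ea, triplet.A

    def residual(T):
        return np.log(Ea * beta / R) - 2.0 * np.log(T) + Ea / (R * T) - np.log(A)

    lo, hi = 50.0, 5000.0
    while residual(hi) > 0 and hi < 1e7:
        hi *= 2
    if residual(lo) <= 0 or residual(hi) >= 0:
        raise IntegrationError(
            f"could not bracket the DTG peak for Ea={Ea:g}, A={A:g}, beta={beta:g}"
        )
    return float(brentq(residual, lo, hi, rtol=1e-12, xtol=1e-10))
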