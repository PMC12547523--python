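"""Thermogram containers and conversion/rate processing.

Turns raw (time, temperature, mass) records into conversion curves
α(T) = (w0 − wt)/(w0 − wf), estimates the decomposition rate dα/dT by
smoothed local-polynomial (Savitzky–Golay) differentiation, locates the
DTG peak, and extracts iso-conversional temperatures and rates across
heating rates.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

from .exceptions import BoundaryPeakError, ThermokinError

__all__ = [
    "Thermogram",
    "ConversionCurve",
    "PeakInfo",
    "IsoTemperatureTable",
    "compute_conversion",
    "find_peak",
    "detect_main_stage",
    "temperatures_at_conversions",
    "rates_at_conversions",
]

logger = logging.getLogger(__name__)


@dataclass
class Thermogram:
    """One constant-heating-rate TGA run.

    time in minutes, temperature in K (both strictly increasing), mass in mg,
    beta (the heating rate) in K·min⁻¹.
    """

    time: np.ndarray
    temperature: np.ndarray
    mass: np.ndarray
    beta: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        n = len(self.temperature)
        if not (len(self.time) == len(self.mass) == n):
            raise ValueError("time, temperature and mass must have equal lengths")
        if n < 50:
            raise ValueError(f"thermogram needs >= 50 samples, got {n}")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature must be strictly increasing")
        if self.beta <= 0:
            raise ValueError("heating rate beta must be positive")


@dataclass
class ConversionCurve:
    """Conversion α(T) and its rate dα/dT for one heating rate."""

    temperature: np.ndarray
    alpha: np.ndarray
    rate: np.ndarray
    beta: float

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)

    def temperature_at(self, alpha):
        """Invert α(T) by monotone (PCHIP) interpolation."""
        a, t = _strictly_increasing(self.alpha, self.temperature)
        return PchipInterpolator(a, t)(alpha)


@dataclass(frozen=True)
class PeakInfo:
    """DTG peak: temperature of maximum decomposition rate."""

    Tp: float
    peak_rate: float
    beta: float


@dataclass
class IsoTemperatureTable:
    """Temperatures T(α; β): one row per conversion level, one column per β."""

    alpha_grid: np.ndarray
    T: np.ndarray
    betas: np.ndarray

    def __post_init__(self):
        self.alpha_grid = np.asarray(self.alpha_grid, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.T.shape != (len(self.alpha_grid), len(self.betas)):
            raise ValueError("T must be (n_alpha, n_beta)")
        if len(self.betas) < 3:
            raise ValueError("need at least 3 heating rates")


def _strictly_increasing(x: np.ndarray, *others: np.ndarray):
    """Subsample to indices where x strictly increases (keeps first of ties)."""
    keep = np.concatenate(([0], np.nonzero(np.diff(x) > 0)[0] + 1))
    if len(keep) < 2:
        raise ThermokinError("curve has no strictly increasing span")
    return (x[keep], *(o[keep] for o in others))


def _sg_derivative(x: np.ndarray, y: np.ndarray, window: int, polyorder: int = 2):
    """Savitzky–Golay first derivative, tolerant of non-uniform sampling.

    Non-uniform grids are handled by monotone resampling onto a uniform grid,
    differentiating there, and interpolating back.
    """
    n = len(x)
    window = min(window, n if n % 2 == 1 else n - 1)
    if window < polyorder + 2:
        return np.gradient(y, x)
    dx = np.diff(x)
    if np.allclose(dx, dx[0], rtol=1e-6, atol=0.0):
        return savgol_filter(y, window, polyorder, deriv=1, delta=dx[0])
    xu = np.linspace(x[0], x[-1], n)
    yu = PchipInterpolator(x, y)(xu)
    du = savgol_filter(yu, window, polyorder, deriv=1, delta=xu[1] - xu[0])
    return PchipInterpolator(xu, du)(x)


def compute_conversion(
    tg: Thermogram,
    w0: float | None = None,
    wf: float | None = None,
    window: tuple[float, float] | None = None,
    smooth_window: int = 11,
) -> ConversionCurve:
    """Convert a thermogram to α(T) with its rate dα/dT.

    Parameters
    ----------
    tg : Thermogram
        The raw run.
    w0, wf : float, optional
        Initial and final reference masses in mg. When omitted they are taken
        from the mass at the window boundaries, so α spans [0, 1] over the
        analysed stage.
    window : (T_lo, T_hi), optional
        Temperature bounds (K) restricting the analysis to the main
        decomposition stage.
    smooth_window : int
        Odd Savitzky–Golay window (points) for rate estimation.

    Noise-induced inversions of α are removed by isotonic clipping (running
    maximum); the total clipped magnitude is logged.
    """
    T, m = tg.temperature, tg.mass
    if window is not None:
        lo, hi = window
        if lo >= hi:
            raise ValueError("window bounds must satisfy T_lo < T_hi")
        if lo > T[-1] or hi < T[0]:
            raise ValueError(
                f"window ({lo}, {hi}) K lies outside the data range "
                f"({T[0]:.1f}, {T[-1]:.1f}) K"
            )
        mask = (T >= lo) & (T <= hi)
        if mask.sum() < 5:
            raise ValueError("window selects fewer than 5 samples")
        T, m = T[mask], m[mask]
    if w0 is None:
        w0 = float(m[0])
    if wf is None:
        wf = float(m[-1])
    if w0 <= wf:
        raise ValueError(f"w0 ({w0}) must exceed wf ({wf})")

    alpha = (w0 - m) / (w0 - wf)
    iso = np.maximum.accumulate(alpha)
    clipped = float(np.sum(iso - alpha))
    if clipped > 0:
        logger.info("isotonic clipping adjusted alpha by total %.3e", clipped)
    alpha = np.clip(iso, 0.0, 1.0)
    rate = _sg_derivative(T, alpha, smooth_window)
    return ConversionCurve(temperature=T, alpha=alpha, rate=rate, beta=tg.beta)


def detect_main_stage(curve: ConversionCurve, frac: float = 0.05) -> tuple[float, float]:
    """Bounds of the contiguous region where dα/dT exceeds ``frac`` of its max.

    Used as the default analysis window so slow tails do not dominate the
    w0/wf normalisation.
    """
    r = curve.rate
    thresh = frac * np.max(r)
    above = r >= thresh
    ipk = int(np.argmax(r))
    lo = ipk
    while lo > 0 and above[lo - 1]:
        lo -= 1
    hi = ipk
    while hi < len(r) - 1 and above[hi + 1]:
        hi += 1
    return float(curve.temperature[lo]), float(curve.temperature[hi])


def find_peak(curve: ConversionCurve, refine: bool = True) -> PeakInfo:
    """Locate the DTG peak (global maximum of dα/dT; ties -> lowest T).

    With ``refine`` a parabola through the three samples around the argmax
    gives sub-grid peak location.
    """
    r = curve.rate
    if r is None or len(r) == 0:
        raise ThermokinError("curve carries no rate")
    i = int(np.argmax(r))
    if i == 0 or i == len(r) - 1:
        raise BoundaryPeakError(
            f"rate maximum at window boundary (index {i}); no interior DTG peak"
        )
    Tp, rp = float(curve.temperature[i]), float(r[i])
    if refine:
        t3 = curve.temperature[i - 1 : i + 2]
        r3 = r[i - 1 : i + 2]
        denom = (r3[0] - 2 * r3[1] + r3[2])
        if denom < 0:  # proper local maximum
            # vertex of the interpolating parabola on a possibly uneven grid
            coef = np.polyfit(t3 - Tp, r3, 2)
            dt = -coef[1] / (2 * coef[0])
            if abs(dt) <= max(Tp - t3[0], t3[2] - Tp):
                Tp = Tp + float(dt)
                rp = float(np.polyval(coef, dt))
    return PeakInfo(Tp=Tp, peak_rate=rp, beta=curve.beta)


def _interp_at_alpha(curve: ConversionCurve, values: np.ndarray, alpha_grid, what: str):
    a, v = _strictly_increasing(curve.alpha, values)
    interp = PchipInterpolator(a, v)
    out = np.full(len(alpha_grid), np.nan)
    for j, ag in enumerate(alpha_grid):
        if a[0] <= ag <= a[-1]:
            out[j] = interp(ag)
        else:
            warnings.warn(
                f"alpha={ag:g} outside the span [{a[0]:.4f}, {a[-1]:.4f}] of the "
                f"beta={curve.beta:g} curve; {what} cell left missing",
                stacklevel=3,
            )
    return out


def temperatures_at_conversions(
    curves: list[ConversionCurve], alpha_grid
) -> IsoTemperatureTable:
    """Iso-conversional temperatures T(α; β) by monotone interpolation.

    Column order follows the order of ``curves``. Conversions outside a
    curve's span yield NaN cells with a warning.
    """
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    betas = np.array([c.beta for c in curves], dtype=float)
    if len(set(betas.tolist())) < 3:
        raise ValueError("need at least 3 distinct heating rates")
    T = np.column_stack(
        [_interp_at_alpha(c, c.temperature, alpha_grid, "temperature") for c in curves]
    )
    return IsoTemperatureTable(alpha_grid=alpha_grid, T=T, betas=betas)


def rates_at_conversions(curves: list[ConversionCurve], alpha_grid) -> np.ndarray:
    """Rates dα/dT at each (α, β), matching temperatures_at_conversions layout."""
    alpha_grid = np.asarray(alpha_grid, dtype=float)
    if len({c.beta for c in curves}) < 3:
        raise ValueError("need at least 3 distinct heating rates")
    return np.column_stack(
        [_interp_at_alpha(c, c.rate, alpha_grid, "rate") for c in curves]
    )
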