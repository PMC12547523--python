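"""Model-free (isoconversional) activation-energy estimation.

At each conversion level α the temperature T(α; β) required to reach α shifts
with the heating rate β. Each method linearizes the temperature integral (or,
for Friedman, the differential rate law) so that an ordinary least-squares fit
of a method-specific ordinate against 1/T across heating rates yields Ea(α)
from the slope:

=========  ======================  ==========================
method     ordinate                Ea from slope
=========  ======================  ==========================
KAS        ln(β / T²)              Ea = −slope · R
FWO        ln β                    Ea = −slope · R / 1.052
Starink    ln(β / T^1.92)          Ea = −slope · R / 1.0037
Friedman   ln(β · dα/dT)           Ea = −slope · R
=========  ======================  ==========================

FWO uses the Doyle approximation (constants 5.331 and 1.052); Starink uses
exponent 1.92 with factor 1.0037. Friedman needs no temperature-integral
approximation but requires the rate dα/dT at each (α, β).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

from .constants import R
from .exceptions import SingularDesignError
from .thermogram import IsoTemperatureTable

__all__ = [
    "IsoMethod",
    "IsoFit",
    "EaProfile",
    "ProfileSummary",
    "METHODS",
    "get_method",
    "fit_isoconversional",
    "summarize_profile",
]

#: Doyle approximation constants used by the FWO linearization
DOYLE_INTERCEPT = 5.331
DOYLE_SLOPE_FACTOR = 1.052

#: Starink linearization constants
STARINK_EXPONENT = 1.92
STARINK_SLOPE_FACTOR = 1.0037


@dataclass(frozen=True)
class IsoMethod:
    """One model-free linearization: ordinate transform and slope→Ea factor."""

    name: str
    needs_rate: bool
    slope_factor: float  # Ea = -slope * R / slope_factor

    def ordinate(self, beta, T, rate=None):
        beta = np.asarray(beta, dtype=float)
        T = np.asarray(T, dtype=float)
        if self.name == "KAS":
            return np.log(beta / T**2)
        if self.name == "FWO":
            return np.log(beta)
        if self.name == "STARINK":
            return np.log(beta / T**STARINK_EXPONENT)
        if self.name == "FRIEDMAN":
            if rate is None:
                raise ValueError("Friedman requires dα/dT values")
            return np.log(beta * np.asarray(rate, dtype=float))
        raise ValueError(f"unknown method {self.name}")

    def slope_to_ea(self, slope: float) -> float:
        return -slope * R / self.slope_factor


METHODS: dict[str, IsoMethod] = {
    "KAS": IsoMethod("KAS", needs_rate=False, slope_factor=1.0),
    "FWO": IsoMethod("FWO", needs_rate=False, slope_factor=DOYLE_SLOPE_FACTOR),
    "STARINK": IsoMethod("STARINK", needs_rate=False, slope_factor=STARINK_SLOPE_FACTOR),
    "FRIEDMAN": IsoMethod("FRIEDMAN", needs_rate=True, slope_factor=1.0),
}


def get_method(name: str | IsoMethod) -> IsoMethod:
    if isinstance(name, IsoMethod):
        return name
    key = name.strip().upper()
    aliases = {"FRD": "FRIEDMAN", "OFW": "FWO"}
    key = aliases.get(key, key)
    if key not in METHODS:
        raise ValueError(f"unknown isoconversional method {name!r}; "
                         f"choose from {sorted(METHODS)}")
    return METHODS[key]


@dataclass(frozen=True)
class IsoFit:
    """Per-conversion regression result."""

    alpha: float
    slope: float
    intercept: float
    Ea: float  # J/mol
    r2: float
    n_points: int


@dataclass
class EaProfile:
    """Ea(α) profile of one method over the conversion grid."""

    method: str
    fits: list[IsoFit] = field(default_factory=list)

    @property
    def alphas(self) -> np.ndarray:
        return np.array([f.alpha for f in self.fits])

    @property
    def Ea(self) -> np.ndarray:
        """Activation energies, J/mol."""
        return np.array([f.Ea for f in self.fits])

    @property
    def mean_Ea(self) -> float:
        return float(np.mean(self.Ea))

    @classmethod
    def from_ea_values(cls, method: str, alphas, ea_values) -> "EaProfile":
        """Wrap externally tabulated per-conversion Ea values (J/mol)."""
        fits = [
            IsoFit(alpha=float(a), slope=np.nan, intercept=np.nan,
                   Ea=float(e), r2=np.nan, n_points=0)
            for a, e in zip(alphas, ea_values, strict=True)
        ]
        return cls(method=get_method(method).name, fits=fits)


def fit_isoconversional(
    method: str | IsoMethod,
    table: IsoTemperatureTable,
    rates: np.ndarray | None = None,
) -> EaProfile:
    """Fit Ea(α) by per-conversion OLS of the method ordinate against 1/T.

    Missing (NaN) cells are dropped per conversion level; a level with fewer
    than 3 usable heating rates is skipped with a warning.
    """
    method = get_method(method)
    if method.needs_rate and rates is None:
        raise ValueError(f"{method.name} requires the rate matrix dα/dT(α, β)")
    betas = table.betas
    if len(np.unique(betas)) < 2:
        raise SingularDesignError("all heating rates identical; design is singular")
    if len(betas) < 3:
        raise ValueError("need at least 3 heating rates")

    fits = []
    for i, alpha in enumerate(table.alpha_grid):
        T_row = table.T[i]
        rate_row = rates[i] if rates is not None else None
        ok = np.isfinite(T_row)
        if rate_row is not None:
            ok &= np.isfinite(rate_row) & (rate_row > 0)
        if ok.sum() < 3:
            warnings.warn(
                f"alpha={alpha:g}: only {int(ok.sum())} usable heating rates; skipped"
            )
            continue
        x = 1.0 / T_row[ok]
        y = method.ordinate(betas[ok], T_row[ok],
                            rate_row[ok] if rate_row is not None else None)
        if np.ptp(x) == 0:
            raise SingularDesignError(f"alpha={alpha:g}: identical temperatures")
        res = linregress(x, y)
        fits.append(
            IsoFit(
                alpha=float(alpha),
                slope=float(res.slope),
                intercept=float(res.intercept),
                Ea=method.slope_to_ea(res.slope),
                r2=float(res.rvalue**2),
                n_points=int(ok.sum()),
            )
        )
    return EaProfile(method=method.name, fits=fits)


@dataclass(frozen=True)
class ProfileSummary:
    """Mean/min/max of a per-conversion quantity plus its per-α table."""

    mean: float
    min: float
    max: float
    table: pd.DataFrame

    @property
    def mean_Ea(self) -> float:  # convenience alias when summarizing Ea
        return self.mean


def summarize_profile(profile: EaProfile | np.ndarray, alphas=None) -> ProfileSummary:
    """Arithmetic mean and range of a per-conversion column.

    Accepts an :class:`EaProfile` (summarizes Ea, J/mol) or any per-conversion
    value sequence (e.g. a tabulated ΔH or ΔS column).
    """
    if isinstance(profile, EaProfile):
        if not profile.fits:
            raise ValueError("empty profile")
        values = profile.Ea
        alphas = profile.alphas
    else:
        values = np.asarray(profile, dtype=float)
        if values.size == 0:
            raise ValueError("empty profile")
        if alphas is None:
            alphas = np.arange(len(values), dtype=float)
    table = pd.DataFrame({"alpha": np.asarray(alphas, dtype=float), "value": values})
    return ProfileSummary(
        mean=float(np.mean(values)),
        min=float(np.min(values)),
        max=float(np.max(values)),
        table=table,
    )
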