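"""CSV and YAML I/O.

Thermogram dialect: headered CSV with columns ``time_min, temperature_K,
mass_mg`` (or ``temperature_C`` when written/read with ``units="C"``), one
file per heating rate. Result tables are headered CSVs with fixed float
formatting so reruns are byte-identical.
"""

from __future__ import annotations

import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .constants import T0_CELSIUS
from .isoconversional import EaProfile
from .thermogram import IsoTemperatureTable, Thermogram
from .yields import YieldSet

__all__ = [
    "write_thermogram_csv",
    "read_thermogram_csv",
    "write_ea_profiles_csv",
    "write_iso_table_csv",
    "write_thermo_csv",
    "write_yields_csv",
    "load_config",
    "save_config",
    "sha256_of",
]

FLOAT_FMT = "%.10g"


def write_thermogram_csv(tg: Thermogram, path, units: str = "K") -> Path:
    path = Path(path)
    if units == "K":
        temp, col = tg.temperature, "temperature_K"
    elif units == "C":
        temp, col = tg.temperature - T0_CELSIUS, "temperature_C"
    else:
        raise ValueError("units must be 'K' or 'C'")
    df = pd.DataFrame({"time_min": tg.time, col: temp, "mass_mg": tg.mass})
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return path


def read_thermogram_csv(path, units: str = "K", beta: float | None = None,
                        meta: dict | None = None) -> Thermogram:
    """Read the thermogram dialect; converts °C to K internally.

    When ``beta`` is omitted it is estimated as the slope of temperature
    against time.
    """
    df = pd.read_csv(path)
    cols = {c.strip(): c for c in df.columns}
    if "temperature_K" in cols:
        temp = df[cols["temperature_K"]].to_numpy(float)
        if units == "C":  # file header wins over the flag
            pass
    elif "temperature_C" in cols:
        temp = df[cols["temperature_C"]].to_numpy(float) + T0_CELSIUS
    elif "temperature" in cols:
        temp = df[cols["temperature"]].to_numpy(float)
        if units == "C":
            temp = temp + T0_CELSIUS
        elif units != "K":
            raise ValueError("units must be 'K' or 'C'")
    else:
        raise ValueError(f"{path}: no temperature column found")
    time = df[cols["time_min"]].to_numpy(float)
    mass = df[cols["mass_mg"]].to_numpy(float)
    if beta is None:
        beta = float(np.polyfit(time, temp, 1)[0])
    return Thermogram(time=time, temperature=temp, mass=mass, beta=beta,
                      meta=dict(meta or {}, source=str(path)))


def write_ea_profiles_csv(profiles: dict[str, EaProfile], path,
                          A_per_min: dict | None = None) -> Path:
    """Columns: method, alpha, Ea_kJ_mol, A_per_min, r2, n_points."""
    rows = []
    for name, prof in profiles.items():
        for fit in prof.fits:
            a_val = (A_per_min or {}).get((name, fit.alpha), np.nan)
            rows.append({
                "method": name, "alpha": fit.alpha,
                "Ea_kJ_mol": fit.Ea / 1e3, "A_per_min": a_val,
                "r2": fit.r2, "n_points": fit.n_points,
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)
    return Path(path)


def write_iso_table_csv(table: IsoTemperatureTable, path) -> Path:
    """α row index, one temperature column per heating rate."""
    df = pd.DataFrame(table.T, index=pd.Index(table.alpha_grid, name="alpha"),
                      columns=[f"T_K_beta_{b:g}" for b in table.betas])
    df.to_csv(path, float_format=FLOAT_FMT)
    return Path(path)


def write_thermo_csv(df: pd.DataFrame, path) -> Path:
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return Path(path)


def write_yields_csv(ys: YieldSet, path) -> Path:
    df = pd.DataFrame([
        {"product": "char", "yield_wt_pct": ys.pct_char, "mass_g": ys.W_char},
        {"product": "liquid", "yield_wt_pct": ys.pct_liquid, "mass_g": ys.W_liquid},
        {"product": "gas", "yield_wt_pct": ys.pct_gas, "mass_g": ys.W_gas},
    ])
    df.to_csv(path, index=False, float_format=FLOAT_FMT)
    return Path(path)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def save_config(config: dict, path) -> Path:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
    return Path(path)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
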