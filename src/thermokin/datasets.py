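"""Worked-example inputs: reported values from a metformin pyrolysis study.

A published microwave-assisted pyrolysis study of metformin pharmaceutical
powder reports per-conversion kinetic/thermodynamic tables and three-phase
product masses. Those printed values serve here as worked-example inputs for
the summary and mass-balance operations (the underlying instrument records
are not public).
"""

from __future__ import annotations

import numpy as np

from .yields import ComponentWeighing

__all__ = [
    "ALPHA_GRID",
    "metformin_ea_kJ_mol",
    "metformin_kas_thermo",
    "metformin_dtg_peaks_C",
    "metformin_yield_weighings",
    "METFORMIN_FEED_G",
]

#: conversion grid of the reported per-conversion tables
ALPHA_GRID = np.arange(1, 9) / 10.0

_EA_KJ_MOL = {
    "KAS": [103.599, 111.845, 116.806, 99.061, 92.809, 94.962, 93.937, 98.724],
    "FWO": [106.95, 115.065, 120.013, 103.422, 97.739, 99.994, 99.231, 104.062],
    "FRIEDMAN": [110.963, 106.753, 127.706, 86.736, 135.786, 92.668, 94.805, 133.758],
    "STARINK": [103.572, 111.799, 116.751, 99.084, 92.866, 95.02, 94.007, 98.788],
}

# KAS per-conversion activation enthalpy and entropy columns
_KAS_DH_KJ_MOL = [99.018, 107.112, 111.947, 94.028, 87.63, 89.67, 88.527, 93.172]
_KAS_DS_J_MOLK = [-86.1, -72.08, -63.79, -94.53, -105.56, -102.02, -103.99, -95.84]

#: DTG peak temperatures (°C) by heating rate (K/min) of the metformin runs
_DTG_PEAKS_C = {10.0: 330.4, 20.0: 334.7, 30.0: 337.1, 40.0: 341.7}

#: metformin powder fed to the microwave pyrolysis reactor, g
METFORMIN_FEED_G = 10.0


def metformin_ea_kJ_mol(method: str) -> tuple[np.ndarray, np.ndarray]:
    """(alpha, Ea kJ/mol) columns of the reported per-conversion table."""
    key = {"FRD": "FRIEDMAN"}.get(method.upper(), method.upper())
    return ALPHA_GRID.copy(), np.array(_EA_KJ_MOL[key])


def metformin_kas_thermo() -> dict:
    """Reported KAS per-conversion ΔH (kJ/mol) and ΔS (J/(mol·K)) columns."""
    return {
        "alpha": ALPHA_GRID.copy(),
        "dH_kJ_mol": np.array(_KAS_DH_KJ_MOL),
        "dS_J_molK": np.array(_KAS_DS_J_MOLK),
    }


def metformin_dtg_peaks_C() -> dict[float, float]:
    """DTG peak temperature (°C) per heating rate (K/min)."""
    return dict(_DTG_PEAKS_C)


def metformin_yield_weighings() -> list[ComponentWeighing]:
    """Before/after weighings reproducing the reported product masses.

    The study reports 4.66 g of condensed liquid and 0.36 g of char from 10 g
    of powder; the per-component split of the liquid across the condensation
    train is not reported, so the full liquid mass is assigned to the
    condenser (the balance is unaffected).
    """
    return [
        ComponentWeighing("condenser", before=120.0, after=124.66),
        ComponentWeighing("elbow_joint", before=35.0, after=35.0),
        ComponentWeighing("adopter_joint", before=28.0, after=28.0),
        ComponentWeighing("flask", before=95.0, after=95.0),
        ComponentWeighing("round_bottom_flask", before=210.0, after=210.36),
    ]
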