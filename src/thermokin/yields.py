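"""Three-phase pyrolysis product yields from component weighings.

Liquid mass is the summed before/after weight gain of the condensation train
(condenser, elbow joint, adopter joint, collection flask); char is the weight
gain of the reactor (round-bottom) flask; gas is obtained by difference from
the fed mass, so the three weight-percent yields close to exactly 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MassBalanceError

__all__ = [
    "ComponentWeighing",
    "YieldSet",
    "LIQUID_COMPONENTS",
    "CHAR_COMPONENT",
    "compute_yields",
    "summarize_replicates",
]

LIQUID_COMPONENTS = ("condenser", "elbow_joint", "adopter_joint", "flask")
CHAR_COMPONENT = "round_bottom_flask"
_KNOWN = set(LIQUID_COMPONENTS) | {CHAR_COMPONENT}


@dataclass(frozen=True)
class ComponentWeighing:
    """Before/after mass (g) of one apparatus component."""

    component: str
    before: float
    after: float

    def __post_init__(self):
        if self.component not in _KNOWN:
            raise ValueError(
                f"unknown component {self.component!r}; expected one of {sorted(_KNOWN)}"
            )
        if self.before < 0 or self.after < 0:
            raise ValueError("weighings must be non-negative")

    @property
    def delta(self) -> float:
        return self.after - self.before


@dataclass(frozen=True)
class YieldSet:
    """Product masses (g) and weight-percent yields of one pyrolysis run."""

    W_feed: float
    W_liquid: float
    W_char: float
    W_gas: float
    pct_liquid: float
    pct_char: float
    pct_gas: float


def compute_yields(weighings: list[ComponentWeighing], W_feed: float) -> YieldSet:
    """Mass balance over the condensation train and reactor flask.

    Gas is always computed by difference, so pct_liquid + pct_char + pct_gas
    equals 100 exactly.
    """
    if W_feed <= 0:
        raise ValueError("W_feed must be positive")
    liquid_parts = [w for w in weighings if w.component in LIQUID_COMPONENTS]
    char_parts = [w for w in weighings if w.component == CHAR_COMPONENT]
    if not liquid_parts:
        raise ValueError("no liquid-train component weighings supplied")
    if len(char_parts) != 1:
        raise ValueError("exactly one round_bottom_flask weighing is required")

    W_liquid = float(sum(w.delta for w in liquid_parts))
    W_char = float(char_parts[0].delta)
    for total, parts, label in ((W_liquid, liquid_parts, "liquid"),
                                (W_char, char_parts, "char")):
        if total < 0:
            bad = ", ".join(w.component for w in parts if w.delta < 0)
            raise ValueError(
                f"computed {label} mass is negative ({total:g} g); "
                f"check weighings for: {bad}"
            )
    if W_liquid + W_char > W_feed:
        raise MassBalanceError(
            f"liquid ({W_liquid:g} g) + char ({W_char:g} g) exceeds the fed mass "
            f"({W_feed:g} g)"
        )
    W_gas = W_feed - (W_liquid + W_char)
    pct_liquid = 100.0 * W_liquid / W_feed
    pct_char = 100.0 * W_char / W_feed
    pct_gas = 100.0 - (pct_liquid + pct_char)
    return YieldSet(W_feed=W_feed, W_liquid=W_liquid, W_char=W_char, W_gas=W_gas,
                    pct_liquid=pct_liquid, pct_char=pct_char, pct_gas=pct_gas)


def summarize_replicates(runs: list[YieldSet]) -> pd.DataFrame:
    """Mean ± sample sd of masses and yields across replicate runs."""
    if not runs:
        raise ValueError("no replicate runs supplied")
    rows = []
    for product, mass_attr, pct_attr in (
        ("char", "W_char", "pct_char"),
        ("liquid", "W_liquid", "pct_liquid"),
        ("gas", "W_gas", "pct_gas"),
    ):
        masses = np.array([getattr(r, mass_attr) for r in runs])
        pcts = np.array([getattr(r, pct_attr) for r in runs])
        rows.append({
            "product": product,
            "yield_wt_pct_mean": pcts.mean(),
            "yield_wt_pct_sd": pcts.std(ddof=1) if len(runs) > 1 else 0.0,
            "mass_g_mean": masses.mean(),
            "mass_g_sd": masses.std(ddof=1) if len(runs) > 1 else 0.0,
        })
    return pd.DataFrame(rows)
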