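"""Solid-state reaction models f(α) for single-step decomposition kinetics.

The catalogue covers the standard ICTAC families used in model-free
thermal-analysis studies:

==========  =============================================  =====================
family      f(α)                                           examples
==========  =============================================  =====================
Fn          (1 − α)^n                                      F0.5, F1, F2
An          m (1 − α) [−ln(1 − α)]^((m−1)/m)               A2, A3 (Avrami–Erofeev)
D1          1 / (2α)                                       1-D diffusion
D2          [−ln(1 − α)]^−1                                2-D diffusion
D3          3 (1 − α)^(2/3) / (2 [1 − (1 − α)^(1/3)])      3-D diffusion (Jander)
Rk          k (1 − α)^((k−1)/k)                            R2, R3 (contracting)
==========  =============================================  =====================

f(α) is strictly positive on the open interval (0, 1) for every family;
evaluation clamps α away from the endpoints so the rate law stays finite
where f diverges (D1, D2, D3) or vanishes (An) at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReactionModel", "MODEL_FAMILIES"]

# clamp width keeping f finite at the interval endpoints
_ALPHA_EPS = 1e-12

MODEL_FAMILIES = ("F", "A", "D1", "D2", "D3", "R")


def _parse_model_id(model_id: str) -> tuple[str, dict]:
    mid = model_id.strip().upper()
    if mid.startswith("F"):
        n = float(mid[1:]) if len(mid) > 1 else 1.0
        return "F", {"n": n}
    if mid.startswith("A") and len(mid) > 1:
        m = float(mid[1:])
        if m <= 0:
            raise ValueError(f"Avrami exponent must be positive, got {m}")
        return "A", {"m": m}
    if mid in ("D1", "D2", "D3"):
        return mid, {}
    if mid.startswith("R") and len(mid) > 1:
        k = float(mid[1:])
        if k <= 0:
            raise ValueError(f"contracting-geometry exponent must be positive, got {k}")
        return "R", {"k": k}
    raise ValueError(
        f"unknown reaction model {model_id!r}; expected Fn, An, D1, D2, D3 or Rk"
    )


@dataclass(frozen=True)
class ReactionModel:
    """Differential mechanism function f(α) of a solid-state reaction model.

    Construct from a catalogue identifier, e.g. ``ReactionModel("F1")`` for
    first-order decay or ``ReactionModel("A2")`` for 2-D nucleation.
    """

    model_id: str
    family: str = field(init=False)
    parameters: dict = field(init=False)

    def __post_init__(self):
        family, params = _parse_model_id(self.model_id)
        object.__setattr__(self, "family", family)
        object.__setattr__(self, "parameters", params)
        object.__setattr__(self, "model_id", self.model_id.strip().upper())

    @property
    def is_first_order(self) -> bool:
        return self.family == "F" and self.parameters["n"] == 1.0

    def f(self, alpha):
        """Evaluate f(α); α is clamped to (0, 1) open interval."""
        a = np.clip(np.asarray(alpha, dtype=float), _ALPHA_EPS, 1.0 - _ALPHA_EPS)
        if self.family == "F":
            out = (1.0 - a) ** self.parameters["n"]
        elif self.family == "A":
            m = self.parameters["m"]
            out = m * (1.0 - a) * (-np.log1p(-a)) ** ((m - 1.0) / m)
        elif self.family == "D1":
            out = 1.0 / (2.0 * a)
        elif self.family == "D2":
            out = 1.0 / (-np.log1p(-a))
        elif self.family == "D3":
            one_third = (1.0 - a) ** (1.0 / 3.0)
            out = 1.5 * one_third**2 / (1.0 - one_third)
        else:  # R family
            k = self.parameters["k"]
            out = k * (1.0 - a) ** ((k - 1.0) / k)
        return out if np.ndim(alpha) else float(out)

    __call__ = f
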