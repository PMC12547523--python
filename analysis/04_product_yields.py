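#!/usr/bin/env python
"""Three-phase product yields from the reported component weighings.

Balances the condensation-train and reactor-flask weighings of the metformin
microwave-pyrolysis experiment (4.66 g liquid, 0.36 g char from 10 g powder)
into char/liquid/gas weight-percent yields, gas by difference. Writes
results/yields.csv.
"""

from pathlib import Path

from thermokin import compute_yields
from thermokin.datasets import METFORMIN_FEED_G, metformin_yield_weighings
from thermokin.io import write_yields_csv

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ys = compute_yields(metformin_yield_weighings(), METFORMIN_FEED_G)
    print(f"feed: {ys.W_feed:g} g metformin powder")
    for name, mass, pct in (("char", ys.W_char, ys.pct_char),
                            ("liquid", ys.W_liquid, ys.pct_liquid),
                            ("gas (by difference)", ys.W_gas, ys.pct_gas)):
        print(f"  {name:<20} {mass:5.2f} g   {pct:5.1f} wt%")
    print(f"  closure: {ys.pct_char + ys.pct_liquid + ys.pct_gas:.1f} wt%")
    print(f"-> {write_yields_csv(ys, OUT / 'yields.csv')}")


if __name__ == "__main__":
    main()
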