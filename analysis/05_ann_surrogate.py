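#!/usr/bin/env python
"""Train the neural-network mass-loss surrogate on the simulated curves.

Builds the 840-row (temperature, heating rate) → fractional-mass-loss dataset
(4 curves × 210 grid points), trains a one-hidden-layer 4-neuron network with
validation-selected L2 regularization under a 60/20/20 split, and reports the
fit metrics. Writes results/ann_model.json and results/ann_metrics.json.
"""

import json
from pathlib import Path

from thermokin import (AnnSpec, HeatingProgram, KineticTriplet, build_dataset,
                       predict, simulate_conversion, train_ann)

OUT = Path(__file__).resolve().parents[1] / "results"
BETAS = (10.0, 20.0, 30.0, 40.0)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    triplet = KineticTriplet(Ea=105e3, A=1e9)
    curves = [simulate_conversion(triplet, HeatingProgram(beta=b)) for b in BETAS]
    data = build_dataset(curves, 840)
    model, metrics = train_ann(data, AnnSpec(hidden_layers=(4,), seed=7))
    print(f"dataset: {len(data)} rows (4 curves x 210 temperature grid points)")
    print(f"selected L2 weight: {metrics.l2:g}; best epoch {metrics.best_epoch}")
    for split in ("train", "val", "test"):
        print(f"  {split:<5} mse = {getattr(metrics, 'mse_' + split):.3e}   "
              f"r = {getattr(metrics, 'r_' + split):.5f}")
    for T in (500.0, 580.0, 650.0):
        print(f"  predicted mass-loss fraction at {T:g} K, 20 K/min: "
              f"{predict(model, T, 20.0):.4f}")
    (OUT / "ann_model.json").write_text(model.to_json())
    (OUT / "ann_metrics.json").write_text(
        json.dumps(metrics.__dict__, indent=2, sort_keys=True))
    print(f"-> {OUT / 'ann_model.json'}, {OUT / 'ann_metrics.json'}")


if __name__ == "__main__":
    main()
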