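#!/usr/bin/env python
"""Generate the study's synthetic multi-heating-rate thermograms.

Simulates a single-step first-order decomposition (Ea = 105 kJ/mol,
A = 1e9 min⁻¹) at 10/20/30/40 K/min — a scenario patterned on the
thermal decomposition of metformin powder (~10 mg, main stage within
490–780 K) — both noiseless and with 0.2% multiplicative mass noise,
and writes one CSV per run under results/thermograms/.
"""

from pathlib import Path

from thermokin import (HeatingProgram, KineticTriplet, NoiseSpec, add_noise,
                       conversion_to_thermogram, predict_peak_temperature,
                       simulate_conversion)
from thermokin.io import write_thermogram_csv

BETAS = (10.0, 20.0, 30.0, 40.0)
OUT = Path(__file__).resolve().parents[1] / "results" / "thermograms"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    triplet = KineticTriplet(Ea=105e3, A=1e9)
    print(f"kinetic truth: Ea = {triplet.Ea/1e3:g} kJ/mol, A = {triplet.A:g} 1/min, "
          f"model = {triplet.model.model_id}")
    for k, beta in enumerate(BETAS):
        curve = simulate_conversion(triplet, HeatingProgram(beta=beta))
        tg = conversion_to_thermogram(curve, w0=10.0, wf=1.5)
        noisy = add_noise(tg, NoiseSpec(mass_noise_sd=0.002, seed=100 + k))
        p_clean = write_thermogram_csv(tg, OUT / f"clean_beta{beta:g}.csv")
        p_noisy = write_thermogram_csv(noisy, OUT / f"noisy_beta{beta:g}.csv")
        tp = predict_peak_temperature(triplet, beta)
        print(f"beta {beta:>4g} K/min: analytic DTG peak {tp:7.2f} K "
              f"({tp-273.15:6.2f} C)  ->  {p_clean.name}, {p_noisy.name}")
    print(f"\nwrote {2*len(BETAS)} thermograms to {OUT}")


if __name__ == "__main__":
    main()
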