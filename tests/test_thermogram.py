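"""Conversion/rate extraction, DTG peak location, iso-conversional tables."""

import numpy as np
import pytest

from thermokin import (
    ConversionCurve,
    HeatingProgram,
    NoiseSpec,
    Thermogram,
    add_noise,
    compute_conversion,
    conversion_to_thermogram,
    find_peak,
    predict_peak_temperature,
    rates_at_conversions,
    simulate_conversion,
    temperatures_at_conversions,
)
from thermokin.exceptions import BoundaryPeakError


def make_thermogram(T, mass, beta=10.0):
    return Thermogram(time=(T - T[0]) / beta, temperature=T, mass=mass, beta=beta)


class TestComputeConversion:
    def test_endpoint_and_midpoint_arithmetic(self):
        T = np.linspace(500, 700, 101)
        mass = np.linspace(10, 2, 101)  # linear loss: w0=10, wf=2
        curve = compute_conversion(make_thermogram(T, mass), w0=10, wf=2)
        assert curve.alpha[0] == pytest.approx(0.0, abs=1e-12)
        assert curve.alpha[-1] == pytest.approx(1.0, abs=1e-12)
        # wt = 6 -> alpha = 0.5
        i = np.argmin(np.abs(mass - 6))
        assert curve.alpha[i] == pytest.approx(0.5, abs=1e-12)

    def test_recovers_generating_alpha(self, study_sim_curves, study_curves):
        for sim, rec in zip(study_sim_curves, study_curves):
            np.testing.assert_allclose(rec.alpha, sim.alpha, atol=1e-10)

    def test_w0_wf_validation(self):
        T = np.linspace(500, 700, 60)
        tg = make_thermogram(T, np.linspace(10, 2, 60))
        with pytest.raises(ValueError):
            compute_conversion(tg, w0=2, wf=10)

    def test_window_outside_data_rejected(self):
        T = np.linspace(500, 700, 60)
        tg = make_thermogram(T, np.linspace(10, 2, 60))
        with pytest.raises(ValueError):
            compute_conversion(tg, window=(900, 1000))

    def test_alpha_bounds_after_noise(self, study_thermograms):
        noisy = add_noise(study_thermograms[0], NoiseSpec(mass_noise_sd=0.01, seed=0))
        curve = compute_conversion(noisy)
        assert np.all(curve.alpha >= 0) and np.all(curve.alpha <= 1)
        assert np.all(np.diff(curve.alpha) >= 0)

    def test_mass_scale_invariance(self, study_thermograms, alpha_grid):
        """Multiplying all masses by a constant leaves α unchanged."""
        tg = study_thermograms[0]
        scaled = Thermogram(time=tg.time, temperature=tg.temperature,
                            mass=tg.mass * 7.3, beta=tg.beta)
        a = compute_conversion(tg)
        b = compute_conversion(scaled)
        np.testing.assert_allclose(a.alpha, b.alpha, atol=1e-12)


class TestFindPeak:
    def test_matches_stationarity_oracle(self, ref_triplet):
        curve = simulate_conversion(ref_triplet, HeatingProgram(beta=10,
                                                                T_start=300,
                                                                T_end=900, step=0.25))
        tg = conversion_to_thermogram(curve)
        peak = find_peak(compute_conversion(tg))
        assert abs(peak.Tp - predict_peak_temperature(ref_triplet, 10)) < 0.5

    def test_triangular_apex(self):
        T = np.linspace(500, 700, 201)
        rate = 1 - np.abs(T - 600) / 100
        curve = ConversionCurve(temperature=T, alpha=np.linspace(0, 1, 201),
                                rate=rate, beta=10)
        assert find_peak(curve).Tp == pytest.approx(600, abs=1e-9)

    def test_peak_increases_with_beta(self, study_curves):
        tps = [find_peak(c).Tp for c in study_curves]
        assert all(b > a for a, b in zip(tps, tps[1:]))

    def test_boundary_peak_rejected(self):
        T = np.linspace(500, 700, 101)
        curve = ConversionCurve(temperature=T, alpha=np.linspace(0, 1, 101),
                                rate=np.linspace(0, 1, 101), beta=10)
        with pytest.raises(BoundaryPeakError):
            find_peak(curve)

    def test_smoothing_peak_shift_below_one_step(self, study_thermograms):
        """The Savitzky–Golay window must not displace a noiseless peak."""
        tg = study_thermograms[0]
        step = tg.temperature[1] - tg.temperature[0]
        tp_narrow = find_peak(compute_conversion(tg, smooth_window=5)).Tp
        tp_default = find_peak(compute_conversion(tg, smooth_window=11)).Tp
        assert abs(tp_default - tp_narrow) <= step


class TestIsoTables:
    def test_exact_grid_point_identity(self, study_curves):
        """A conversion present in the data returns its own temperature."""
        curve = study_curves[0]
        i = np.searchsorted(curve.alpha, 0.4)
        table = temperatures_at_conversions(study_curves, [curve.alpha[i]])
        assert table.T[0, 0] == pytest.approx(curve.temperature[i], abs=1e-9)

    def test_matches_dense_inversion(self, study_triplet, study_curves, alpha_grid):
        """T(α) agrees with inversion of a 10× finer simulation grid."""
        table = temperatures_at_conversions(study_curves, alpha_grid)
        fine = simulate_conversion(study_triplet,
                                   HeatingProgram(beta=10, step=0.025))
        t_fine = fine.temperature_at(alpha_grid)
        np.testing.assert_allclose(table.T[:, 0], t_fine, atol=0.05)

    def test_columns_increase_with_alpha_and_order_kept(self, study_curves, alpha_grid):
        table = temperatures_at_conversions(study_curves, alpha_grid)
        assert np.all(np.diff(table.T, axis=0) > 0)
        np.testing.assert_array_equal(table.betas, [c.beta for c in study_curves])

    def test_fixed_alpha_temperature_increases_with_beta(self, study_curves,
                                                         alpha_grid):
        table = temperatures_at_conversions(study_curves, alpha_grid)
        assert np.all(np.diff(table.T, axis=1) > 0)

    def test_missing_cell_warns(self, study_curves):
        truncated = []
        for c in study_curves:
            mask = c.alpha <= 0.4
            truncated.append(ConversionCurve(temperature=c.temperature[mask],
                                             alpha=c.alpha[mask],
                                             rate=c.rate[mask], beta=c.beta))
        with pytest.warns(UserWarning, match="outside the span"):
            table = temperatures_at_conversions(truncated, [0.5])
        assert np.all(np.isnan(table.T))

    def test_fewer_than_three_rates_rejected(self, study_curves):
        with pytest.raises(ValueError):
            temperatures_at_conversions(study_curves[:2], [0.5])

    def test_rates_match_arrhenius_rhs(self, study_triplet, study_curves,
                                       alpha_grid):
        """Interpolated dα/dT equals the analytic rate law within 0.1%."""
        from thermokin.constants import R

        rates = rates_at_conversions(study_curves, alpha_grid)
        table = temperatures_at_conversions(study_curves, alpha_grid)
        for j, curve in enumerate(study_curves):
            analytic = (study_triplet.A / curve.beta) * (1 - alpha_grid) * np.exp(
                -study_triplet.Ea / (R * table.T[:, j])
            )
            np.testing.assert_allclose(rates[:, j], analytic, rtol=1e-3)

    def test_noisy_rates_within_five_percent_midrange(self, study_triplet,
                                                      study_thermograms):
        """0.2% mass noise with a 15-point window: <5% rate error mid-curve."""
        from thermokin.constants import R

        curves = [
            compute_conversion(
                add_noise(tg, NoiseSpec(mass_noise_sd=0.002, seed=7 + k)),
                smooth_window=15,
            )
            for k, tg in enumerate(study_thermograms)
        ]
        mid = np.arange(0.3, 0.71, 0.05)
        rates = rates_at_conversions(curves, mid)
        table = temperatures_at_conversions(curves, mid)
        for j, curve in enumerate(curves):
            analytic = (study_triplet.A / curve.beta) * (1 - mid) * np.exp(
                -study_triplet.Ea / (R * table.T[:, j])
            )
            rel = np.abs(rates[:, j] - analytic) / analytic
            assert np.median(rel) < 0.05
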