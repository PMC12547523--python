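"""Model-free Ea(α) estimation: exact-line recovery, closed-form regression
oracle, parameter recovery on simulated data, and reported-table summaries."""

import numpy as np
import pytest

from thermokin import (
    EaProfile,
    IsoTemperatureTable,
    fit_isoconversional,
    get_method,
    rates_at_conversions,
    summarize_profile,
    temperatures_at_conversions,
)
from thermokin.constants import R
from thermokin.datasets import metformin_ea_kJ_mol, metformin_kas_thermo
from thermokin.exceptions import SingularDesignError


def closed_form_ols(x, y):
    """Independent simple-linear-regression oracle."""
    x, y = np.asarray(x), np.asarray(y)
    sxx = np.sum((x - x.mean()) ** 2)
    sxy = np.sum((x - x.mean()) * (y - y.mean()))
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    ss_res = np.sum((y - slope * x - intercept) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    return slope, intercept, 1 - ss_res / ss_tot


def exact_kas_table(ea, n_beta=4):
    """Temperatures placed exactly on the KAS line for a chosen Ea (J/mol)."""
    betas = np.array([10.0, 20.0, 30.0, 40.0][:n_beta])
    alpha_grid = np.array([0.2, 0.5, 0.8])
    T = np.empty((len(alpha_grid), n_beta))
    for i in range(len(alpha_grid)):
        ci = -5.0 + 0.1 * i  # per-level intercept
        for j, b in enumerate(betas):
            # solve ln(b/T^2) = ci - (Ea/R)/T by fixed-point iteration
            t = 600.0
            for _ in range(200):
                t = (ea / R) / (ci - np.log(b / t**2))
            T[i, j] = t
    return IsoTemperatureTable(alpha_grid=alpha_grid, T=T, betas=betas)


class TestExactLines:
    def test_kas_recovers_exact_ea(self):
        """Points generated on the KAS line return Ea and r²=1 exactly."""
        table = exact_kas_table(100e3)
        profile = fit_isoconversional("KAS", table)
        for fit in profile.fits:
            assert fit.Ea == pytest.approx(100e3, rel=1e-10)
            assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["KAS", "FWO", "STARINK", "FRIEDMAN"])
    def test_fit_equals_closed_form_regression(self, method, study_curves,
                                               alpha_grid):
        """Each per-α fit must equal the closed-form OLS oracle to 1e-10."""
        table = temperatures_at_conversions(study_curves, alpha_grid)
        rates = rates_at_conversions(study_curves, alpha_grid)
        m = get_method(method)
        profile = fit_isoconversional(m, table,
                                      rates if m.needs_rate else None)
        for i, fit in enumerate(profile.fits):
            x = 1.0 / table.T[i]
            y = m.ordinate(table.betas, table.T[i],
                           rates[i] if m.needs_rate else None)
            slope, intercept, r2 = closed_form_ols(x, y)
            assert fit.slope == pytest.approx(slope, rel=1e-10)
            assert fit.intercept == pytest.approx(intercept, rel=1e-10)
            assert fit.r2 == pytest.approx(r2, abs=1e-10)

    def test_identical_betas_singular(self):
        table = exact_kas_table(100e3)
        table.betas[:] = 10.0
        with pytest.raises(SingularDesignError):
            fit_isoconversional("KAS", table)

    def test_two_heating_rates_rejected(self, study_curves):
        with pytest.raises(ValueError):
            temperatures_at_conversions(study_curves[:2], [0.3, 0.5])


class TestParameterRecovery:
    """Simulated F1 truth: Ea = 105 kJ/mol, A = 1e9 min⁻¹, β ∈ {10,20,30,40}.

    Friedman uses no temperature-integral approximation and is essentially
    exact; KAS and Starink carry a small residual bias; FWO inherits the
    Doyle-approximation slope bias (1 + 2/x)/1.052 − 1 ≈ 3.5% at
    x = Ea/RT ≈ 21 for these conditions.
    """

    TRUE_EA = 105e3
    NOISELESS_TOL = {"FRIEDMAN": 0.01, "KAS": 0.02, "STARINK": 0.02, "FWO": 0.045}

    @pytest.mark.parametrize("method", ["FRIEDMAN", "KAS", "STARINK", "FWO"])
    def test_noiseless_recovery(self, method, study_curves, alpha_grid):
        table = temperatures_at_conversions(study_curves, alpha_grid)
        rates = rates_at_conversions(study_curves, alpha_grid)
        m = get_method(method)
        profile = fit_isoconversional(m, table, rates if m.needs_rate else None)
        rel_err = abs(profile.mean_Ea - self.TRUE_EA) / self.TRUE_EA
        assert rel_err < self.NOISELESS_TOL[method]

    @pytest.mark.parametrize("method", ["FRIEDMAN", "KAS", "STARINK", "FWO"])
    def test_noisy_recovery_within_five_percent(self, method, noisy_curves,
                                                alpha_grid):
        table = temperatures_at_conversions(noisy_curves, alpha_grid)
        rates = rates_at_conversions(noisy_curves, alpha_grid)
        m = get_method(method)
        profile = fit_isoconversional(m, table, rates if m.needs_rate else None)
        assert abs(profile.mean_Ea - self.TRUE_EA) / self.TRUE_EA < 0.05

    def test_method_agreement(self, study_curves, alpha_grid):
        """On noiseless single-step data the four means lie within 4%."""
        table = temperatures_at_conversions(study_curves, alpha_grid)
        rates = rates_at_conversions(study_curves, alpha_grid)
        means = [
            fit_isoconversional(get_method(m), table,
                                rates if get_method(m).needs_rate else None).mean_Ea
            for m in ("KAS", "FWO", "STARINK", "FRIEDMAN")
        ]
        assert (max(means) - min(means)) / min(means) < 0.04

    def test_kas_starink_near_identical(self, study_curves, alpha_grid):
        """Exponent 2 vs 1.92 changes Ea by well under 0.5%."""
        table = temperatures_at_conversions(study_curves, alpha_grid)
        kas = fit_isoconversional("KAS", table)
        sta = fit_isoconversional("STARINK", table)
        np.testing.assert_allclose(kas.Ea, sta.Ea, rtol=5e-3)

    def test_friedman_requires_rates(self, study_curves, alpha_grid):
        table = temperatures_at_conversions(study_curves, alpha_grid)
        with pytest.raises(ValueError, match="rate"):
            fit_isoconversional("FRIEDMAN", table)

    def test_high_r2_on_clean_data(self, study_curves, alpha_grid):
        table = temperatures_at_conversions(study_curves, alpha_grid)
        profile = fit_isoconversional("KAS", table)
        assert all(fit.r2 > 0.97 for fit in profile.fits)


class TestSummaries:
    """Means of the reported per-conversion metformin columns."""

    @pytest.mark.parametrize(
        "method,expected_mean",
        [("KAS", 101.468), ("FWO", 105.809), ("FRIEDMAN", 111.147),
         ("STARINK", 101.486)],
    )
    def test_reported_table_means(self, method, expected_mean):
        alphas, ea = metformin_ea_kJ_mol(method)
        profile = EaProfile.from_ea_values(method, alphas, ea * 1e3)
        summary = summarize_profile(profile)
        assert summary.mean / 1e3 == pytest.approx(expected_mean, abs=6e-4)

    def test_reported_thermo_column_means(self):
        thermo = metformin_kas_thermo()
        assert summarize_profile(thermo["dH_kJ_mol"]).mean == pytest.approx(
            96.388, abs=6e-4
        )
        assert summarize_profile(thermo["dS_J_molK"]).mean == pytest.approx(
            -90.49, abs=5e-3
        )

    def test_single_fit_mean_is_value(self):
        profile = EaProfile.from_ea_values("KAS", [0.5], [99e3])
        assert summarize_profile(profile).mean == pytest.approx(99e3)

    def test_empty_profile_rejected(self):
        with pytest.raises(ValueError):
            summarize_profile(EaProfile(method="KAS", fits=[]))
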