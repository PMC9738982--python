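"""Free Gaussian fits, structure discovery, family selection, surface fit."""

import numpy as np
import pytest

import speccult as sc
from speccult.calibration import (
    _gauss_sum,
    fit_free_gaussians,
    fit_subfunction_families,
    iterate_constant_fixing,
    minimize_global_surface,
)
from tests.conftest import GRID


def noiseless_set(model, n_conc=8, seed=0):
    return sc.generate_calibration_set(
        model,
        sc.default_cem_concentrations(n_conc),
        grid=GRID,
        noise=sc.NoiseConfig(seed=seed).zero_noise(),
    )


class TestFreeGaussianFit:
    def test_recovers_exact_two_gaussian_curve(self, lam):
        true = np.array([[60.0, 530.0, 500.0], [12.0, 930.0, 180.0]])
        y = _gauss_sum(lam, true)
        coeffs, r2, flags = fit_free_gaussians((lam, y))
        assert r2 > 0.9999
        assert coeffs == pytest.approx(true, rel=1e-3)
        assert not flags

    def test_noiseless_cem_spectrum_fit_quality(self, cem_model, lam):
        y = cem_model.evaluate(lam, 5.5e5)
        _, r2, _ = fit_free_gaussians((lam, y))
        assert r2 > 0.98  # each fixed-C spectrum is itself two-Gaussian

    def test_ca_spectrum_with_offaxis_center_recovered(self, ca_model, lam):
        y = ca_model.evaluate(lam, 2e6)
        coeffs, r2, _ = fit_free_gaussians((lam, y))
        assert r2 > 0.9999  # the broad sloping background is still a Gaussian

    def test_single_gaussian_input_flags_degeneracy(self, lam):
        """A one-Gaussian curve fitted with two components is unidentifiable
        (vanishing or coincident second component) and must be flagged."""
        y = 40.0 * np.exp(-(((lam - 550.0) / 120.0) ** 2))
        coeffs, r2, flags = fit_free_gaussians((lam, y))
        amps = np.sort(np.abs(coeffs[:, 0]))
        assert r2 > 0.9999
        assert (
            flags.get("degenerate_amplitude")
            or flags.get("degenerate_overlap")
            or amps[0] < 1e-3 * amps[1]
        )

    def test_fixed_coefficients_are_pinned(self, cem_model, lam):
        y = cem_model.evaluate(lam, 3e5)
        coeffs, r2, _ = fit_free_gaussians((lam, y), fixed={"b1": 533.7, "a2": 12.21})
        assert coeffs[0, 1] == 533.7 and coeffs[1, 0] == 12.21
        assert r2 > 0.999

    def test_unknown_fixed_label_rejected(self, lam):
        with pytest.raises(ValueError, match="label"):
            fit_free_gaussians((lam, np.zeros(lam.size)), fixed={"z9": 1.0})


class TestStructureDiscovery:
    def test_noiseless_cem_set_yields_printed_structure(self, cem_model):
        structure, tables = iterate_constant_fixing(noiseless_set(cem_model))
        constants = {k for k, v in structure.items() if v != "free"}
        assert constants == {"b1", "a2", "b2", "c2"}
        assert structure["a1"] == "free" and structure["c1"] == "free"
        # fixed values equal the generating constants
        assert structure["b1"][1] == pytest.approx(533.7, abs=0.01)
        assert structure["c2"][1] == pytest.approx(177.2, abs=0.01)
        # audit trail: one coefficient fixed per iteration
        for prev, cur in zip(tables, tables[1:]):
            assert len(cur.fixed_map) == len(prev.fixed_map) + 1

    def test_identical_spectra_fix_everything(self, cem_model, lam):
        y = cem_model.evaluate(lam, 5e5)
        spectra = [
            sc.Spectrum(lam, y.copy(), sc.ABSORPTION,
                        counter_concentration=c)
            for c in np.geomspace(1e5, 1e6, 8)
        ]
        with pytest.warns(UserWarning, match="all coefficients fixed"):
            structure, _ = iterate_constant_fixing(sc.SpectrumSet(spectra))
        assert all(v != "free" for v in structure.values())

    def test_first_fixed_coefficient_is_gaussian1_center(self, cem_approx_model):
        """On noisy CEM-like data the Gaussian-1 center is the least
        dispersed coefficient and is fixed first."""
        sset = sc.generate_calibration_set(
            cem_approx_model,
            sc.default_cem_concentrations(8),
            grid=GRID,
            noise=sc.NoiseConfig(seed=0, cuvette_sd=0.0, counter_cv=0.0,
                                 detector_sd=0.2),
        )
        _, tables = iterate_constant_fixing(sset)
        assert list(tables[1].fixed_map) == ["b1"]

    def test_too_few_spectra_rejected(self, cem_model):
        sset = noiseless_set(cem_model)[:4]
        with pytest.raises(ValueError):
            iterate_constant_fixing(sset)

    def test_forced_constant_reproduces_manual_choice(self, cem_model):
        structure, tables = iterate_constant_fixing(
            noiseless_set(cem_model), forced_constant={"b2": 976.9}
        )
        assert structure["b2"] == ("constant", 976.9)
        assert all("b2" in t.fixed_map for t in tables)


class TestSubfunctionFamilySelection:
    conc = np.geomspace(1e5, 1e6, 8)

    def test_beer_lambert_data_recovers_generating_parameter(self):
        v = 100.0 * (1.0 - 10.0 ** (-7.45e-7 * self.conc))
        best, per_family = fit_subfunction_families(self.conc, v)
        assert best.family == "beer_lambert_amplitude"
        assert best.params[0] == pytest.approx(7.45e-7, rel=5e-3)
        assert per_family["beer_lambert_amplitude"]["r2"] == pytest.approx(1.0)

    def test_power_data_recovers_generating_parameters(self):
        v = 2.14 * self.conc ** 0.41
        best, _ = fit_subfunction_families(self.conc, v)
        assert best.family == "power"
        assert best.params == pytest.approx((2.14, 0.41), rel=1e-6)

    def test_log_linear_data_selected(self):
        v = -218.6 + 41.1 * np.log10(self.conc)
        best, _ = fit_subfunction_families(self.conc, v)
        assert best.family == "log_linear"
        assert best.params == pytest.approx((-218.6, 41.1), rel=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_constant_plus_noise_prefers_parsimony(self, seed):
        rng = np.random.default_rng(seed)
        v = 23.0 * (1.0 + 0.01 * rng.standard_normal(self.conc.size))
        best, per_family = fit_subfunction_families(self.conc, v)
        assert best.family == "constant"
        # the richer families nominally fit better yet are not selected
        assert per_family["power"]["r2"] >= per_family["constant"]["r2"]

    def test_log_linear_skipped_for_nonpositive_concentration(self):
        c = np.array([0.0, 1e5, 2e5, 4e5])
        v = np.array([1.0, 2.0, 3.0, 4.0])
        _, per_family = fit_subfunction_families(c, v)
        assert "skipped" in per_family["log_linear"]["note"]


class TestGlobalSurfaceMinimization:
    def test_recovery_from_perturbed_start(self, cem_model):
        sset = noiseless_set(cem_model)
        true = cem_model.parameter_vector()
        start = true * (1.0 + 0.2 * np.array([1, -1, 1, -1, 1, -1, 1]))
        res = minimize_global_surface(sset, cem_model, start=start, n_restarts=2)
        assert np.abs(res.final_params / true - 1.0).max() < 5e-3
        _, y = sset.to_matrix()
        assert res.final_error < 1e-6 * float(np.sum(y**2))

    def test_start_at_optimum_is_fixed_point(self, cem_model):
        sset = noiseless_set(cem_model)
        res = minimize_global_surface(sset, cem_model)
        assert res.final_error <= res.start_error
        assert np.abs(res.final_params / cem_model.parameter_vector() - 1.0).max() < 1e-6

    def test_objective_never_worsens(self, cem_model):
        sset = sc.generate_calibration_set(
            cem_model, sc.default_cem_concentrations(8), grid=GRID,
            noise=sc.NoiseConfig(seed=5),
        )
        res = minimize_global_surface(sset, cem_model, max_evals=500)
        assert res.final_error <= res.start_error

    @pytest.mark.parametrize("seed", range(20))
    def test_beer_lambert_parameter_recovery_under_detector_noise(
        self, cem_model, seed
    ):
        sset = sc.generate_calibration_set(
            cem_model, sc.default_cem_concentrations(8), grid=GRID,
            noise=sc.NoiseConfig(seed=seed, cuvette_sd=0.0, counter_cv=0.0,
                                 detector_sd=0.2),
        )
        res = minimize_global_surface(sset, cem_model, max_evals=4000,
                                      xtol_rel=1e-5, ftol_rel=1e-8)
        assert res.final_params[0] == pytest.approx(7.67e-7, rel=0.02)

    def test_nonfinite_start_rejected(self, cem_model):
        sset = noiseless_set(cem_model)
        start = cem_model.parameter_vector()
        start[0] = np.nan
        with pytest.raises(ValueError):
            minimize_global_surface(sset, cem_model, start=start)


class TestDeterminism:
    def test_calibration_is_deterministic(self, cem_model):
        sset = sc.generate_calibration_set(
            cem_model, sc.default_cem_concentrations(8), grid=GRID,
            noise=sc.NoiseConfig(seed=11),
        )
        lam, x = sset.to_matrix()
        y = sset.counter_concentrations()
        a = sc.SpectralShapeRegressor(name="CEM").fit(x, y, wavelengths=lam)
        b = sc.SpectralShapeRegressor(name="CEM").fit(x, y, wavelengths=lam)
        assert np.array_equal(
            a.calibration_.final_params, b.calibration_.final_params
        )
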