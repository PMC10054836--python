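"""CNLS fitting tests: parameter recovery, identifiability, condition comparison."""

import numpy as np
import pytest

from wellsense.circuit import (
    CircuitParams,
    FrequencyGrid,
    ImpedanceSpectrum,
    InvalidInputError,
    barrier_metrics,
    simulate_impedance,
)
from wellsense.eis import (
    EpithelialImpedanceModel,
    FitConvergenceError,
    FitOptions,
    compare_conditions,
    fit_circuit,
    initial_guess,
)
from wellsense.synth import NoiseModel, gen_spectrum

from conftest import random_circuit


class TestInitialGuess:
    def test_pure_resistor_yields_medium_resistance(self, band_grid):
        p = CircuitParams(r_media=150.0, r1=1e-3, c1=1.0, r2=1e-3, c2=1.0)
        guess = initial_guess(simulate_impedance(p, band_grid))
        assert guess.r_media == pytest.approx(150.0, rel=0.01)

    def test_guessed_teer_within_10_pct_of_truth(self, band_grid, pre_params):
        guess = initial_guess(simulate_impedance(pre_params, band_grid))
        true_teer = barrier_metrics(pre_params).teer
        guessed = guess.r1 + guess.r2
        assert guessed == pytest.approx(true_teer, rel=0.10)

    def test_empty_spectrum_is_an_error(self):
        with pytest.raises(InvalidInputError):
            FrequencyGrid(np.array([]))

    def test_short_spectrum_falls_back_with_warning(self, pre_params):
        grid = FrequencyGrid(np.array([10.0, 100.0, 1000.0, 1e4, 1e5]))
        spec = simulate_impedance(pre_params, grid)
        with pytest.warns(UserWarning, match="too short"):
            guess = initial_guess(spec)
        assert all(v > 0 for v in guess.as_array())


class TestFitCircuit:
    def test_noiseless_recovery_to_0p1_pct(self, band_grid):
        truth = CircuitParams(r_media=20, r1=300, c1=2.4, r2=446, c2=7.2)
        result = fit_circuit(simulate_impedance(truth, band_grid))
        for got, want in zip(result.params.as_array(), truth.as_array()):
            assert got == pytest.approx(want, rel=1e-3)

    def test_swapped_generator_labels_give_identical_metrics(self, band_grid):
        a = CircuitParams(20, 300, 2.4, 446, 7.2)
        b = CircuitParams(20, 446, 7.2, 300, 2.4)  # constructor canonicalizes
        fit_a = fit_circuit(simulate_impedance(a, band_grid))
        fit_b = fit_circuit(simulate_impedance(b, band_grid))
        assert fit_a.metrics.teer == pytest.approx(fit_b.metrics.teer, rel=1e-9)
        assert fit_a.metrics.c_cell == pytest.approx(fit_b.metrics.c_cell, rel=1e-9)

    def test_pre_egta_preset_recovers_barrier_teer(self, band_grid, pre_params):
        result = fit_circuit(simulate_impedance(pre_params, band_grid))
        assert result.metrics.teer == pytest.approx(746.0, rel=0.01)

    def test_random_circuit_recovery_on_200_draws(self, band_grid):
        rng = np.random.default_rng(123)
        for _ in range(200):
            truth = random_circuit(rng)
            want = barrier_metrics(truth)
            result = fit_circuit(simulate_impedance(truth, band_grid))
            assert result.metrics.teer == pytest.approx(want.teer, rel=1e-3)
            assert result.metrics.c_cell == pytest.approx(want.c_cell, rel=1e-3)

    def test_median_teer_error_under_1_pct_noise(self, band_grid, pre_params):
        true_teer = barrier_metrics(pre_params).teer
        errors = []
        for seed in range(100):
            spec = gen_spectrum(
                pre_params, band_grid, NoiseModel("proportional_gaussian", 0.01, seed)
            )
            result = fit_circuit(spec)
            errors.append(abs(result.metrics.teer - true_teer) / true_teer)
        assert np.median(errors) < 0.02

    def test_fit_is_local_optimum_against_20_pct_perturbations(self, band_grid):
        rng = np.random.default_rng(5)
        for _ in range(20):
            truth = random_circuit(rng)
            spec = simulate_impedance(truth, band_grid)
            result = fit_circuit(spec)

            def chi2(params):
                zm = simulate_impedance(params, band_grid).z
                w = 1.0 / np.abs(spec.z)
                return np.sum(((zm.real - spec.z.real) * w) ** 2 + ((zm.imag - spec.z.imag) * w) ** 2)

            base = chi2(result.params)
            for i in range(5):
                for factor in (0.8, 1.2):
                    arr = result.params.as_array()
                    arr[i] *= factor
                    assert chi2(CircuitParams.from_array(arr)) > base

    def test_equal_time_constants_flagged_but_teer_recovered(self, band_grid):
        truth = CircuitParams(r_media=20, r1=300, c1=4.8, r2=300, c2=4.8)
        result = fit_circuit(simulate_impedance(truth, band_grid))
        assert not result.identifiable_split
        assert result.metrics.teer == pytest.approx(600.0, rel=0.005)

    def test_nonconvergence_raises_with_best_params(self, band_grid, pre_params):
        spec = simulate_impedance(pre_params, band_grid)
        with pytest.raises(FitConvergenceError) as exc_info:
            fit_circuit(spec, FitOptions(max_iterations=2))
        assert isinstance(exc_info.value.best_params, CircuitParams)

    def test_degenerate_spectrum_rejected(self, band_grid):
        flat = ImpedanceSpectrum(band_grid, np.full(len(band_grid), 50.0 + 0j))
        with pytest.raises(InvalidInputError):
            EpithelialImpedanceModel(flat)

    def test_agrees_with_independent_lmfit_optimizer(self, band_grid, pre_params):
        lmfit = pytest.importorskip("lmfit")
        spec = gen_spectrum(
            pre_params, band_grid, NoiseModel("proportional_gaussian", 0.01, 99)
        )
        ours = fit_circuit(spec)

        pars = lmfit.Parameters()
        for name, value in zip(("r_media", "r1", "c1", "r2", "c2"), (20, 300, 2.4, 446, 7.2)):
            pars.add(name, value=value, min=1e-6)

        def resid(p):
            w = 2 * np.pi * spec.grid.frequencies
            zm = (
                p["r_media"]
                + p["r1"] / (1 + 1j * w * p["r1"] * p["c1"] * 1e-6)
                + p["r2"] / (1 + 1j * w * p["r2"] * p["c2"] * 1e-6)
            )
            wgt = 1.0 / np.abs(spec.z)
            return np.concatenate([(zm.real - spec.z.real) * wgt, (zm.imag - spec.z.imag) * wgt])

        out = lmfit.minimize(resid, pars)
        teer_lmfit = out.params["r1"].value + out.params["r2"].value
        assert ours.metrics.teer == pytest.approx(teer_lmfit, rel=1e-4)


class TestCompareConditions:
    def test_printed_teer_pair_gives_61_pct_drop(self, band_grid, pre_params, post_params):
        fit_pre = fit_circuit(simulate_impedance(pre_params, band_grid))
        fit_post = fit_circuit(simulate_impedance(post_params, band_grid))
        cmp = compare_conditions(fit_pre, fit_post)
        assert cmp.delta_teer == pytest.approx(458.0, rel=0.005)
        assert cmp.delta_teer_pct == pytest.approx(61.4, abs=0.1)

    def test_identical_fits_give_zero_change(self, band_grid, pre_params):
        fit = fit_circuit(simulate_impedance(pre_params, band_grid))
        cmp = compare_conditions(fit, fit)
        assert cmp.delta_teer_pct == 0.0

    def test_recovery_direction_reported_negative(self, band_grid, pre_params, post_params):
        fit_pre = fit_circuit(simulate_impedance(pre_params, band_grid))
        fit_post = fit_circuit(simulate_impedance(post_params, band_grid))
        cmp = compare_conditions(fit_post, fit_pre)
        assert cmp.delta_teer_pct == pytest.approx(-159.0, abs=1.0)
        assert cmp.delta_teer_pct < 0


def test_summary_reports_key_quantities(band_grid, pre_params):
    result = fit_circuit(simulate_impedance(pre_params, band_grid))
    text = result.summary()
    assert "TEER" in text and "C_cell" in text and "chi^2" in text
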