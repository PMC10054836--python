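"""SWASV trace tests: protocol grids, baseline correction, peak extraction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wellsense.circuit import InvalidInputError
from wellsense.voltammetry import (
    CU_PROTOCOL,
    ZN_PROTOCOL,
    SWVProtocol,
    Voltammogram,
    baseline_correct,
    find_peak,
    potential_grid,
)


def gaussian_trace(protocol, center, height, width=0.030, baseline=(0.0, 0.0)):
    """Construction oracle: the peak height is known exactly by construction."""
    e = potential_grid(protocol)
    intercept, slope = baseline
    i = intercept + slope * e + height * np.exp(-0.5 * ((e - center) / width) ** 2)
    return Voltammogram(protocol=protocol, potentials=e, currents=i)


class TestProtocols:
    def test_copper_preset_parameters(self):
        p = CU_PROTOCOL
        assert (p.precondition_potential, p.precondition_time) == (-1.0, 30.0)
        assert (p.e_start, p.e_end) == (-0.2, 0.5)
        assert (p.step, p.amplitude, p.frequency) == (0.004, 0.020, 25.0)
        assert (p.cleaning_potential, p.cleaning_time) == (0.3, 90.0)

    def test_zinc_preset_parameters(self):
        p = ZN_PROTOCOL
        assert (p.precondition_potential, p.precondition_time) == (-1.2, 30.0)
        assert (p.e_start, p.e_end) == (-1.0, -0.2)
        assert (p.step, p.amplitude, p.frequency) == (0.008, 0.050, 50.0)

    def test_invalid_protocols_rejected(self):
        with pytest.raises(InvalidInputError):
            SWVProtocol("Cu", -1.0, 30, e_start=0.1, e_end=0.1, step=0.004,
                        amplitude=0.02, frequency=25)
        with pytest.raises(InvalidInputError):
            SWVProtocol("Pb", -1.0, 30, e_start=-0.2, e_end=0.5, step=0.004,
                        amplitude=0.02, frequency=25)


class TestPotentialGrid:
    def test_copper_grid_has_176_points(self):
        e = potential_grid(CU_PROTOCOL)
        assert len(e) == 176
        assert e[0] == pytest.approx(-0.2)
        assert e[-1] == pytest.approx(0.5)
        assert np.allclose(np.diff(e), 0.004)

    def test_zinc_grid_has_101_points(self):
        e = potential_grid(ZN_PROTOCOL)
        assert len(e) == 101
        assert e[0] == pytest.approx(-1.0)
        assert e[-1] == pytest.approx(-0.2)

    def test_step_exceeding_range_is_error(self):
        bad = SWVProtocol("Cu", -1.0, 30, e_start=-0.2, e_end=0.5, step=1.0,
                          amplitude=0.02, frequency=25)
        with pytest.raises(InvalidInputError):
            potential_grid(bad)


class TestBaselineCorrect:
    def test_straight_line_maps_to_zero(self):
        e = potential_grid(CU_PROTOCOL)
        v = Voltammogram(CU_PROTOCOL, e, 2e-7 + 5e-7 * e)
        out = baseline_correct(v)
        assert np.allclose(out.currents, 0.0, atol=1e-18)

    def test_gaussian_on_line_recovers_pure_gaussian(self):
        height = 1e-6
        v = gaussian_trace(CU_PROTOCOL, 0.1, height, baseline=(2e-7, 5e-7))
        out = baseline_correct(v)
        pure = gaussian_trace(CU_PROTOCOL, 0.1, height).currents
        window = np.abs(out.potentials - 0.1) < 0.1
        assert np.max(np.abs(out.currents[window] - pure[window])) < 0.01 * height

    def test_flat_zero_stays_flat_zero(self):
        e = potential_grid(CU_PROTOCOL)
        out = baseline_correct(Voltammogram(CU_PROTOCOL, e, np.zeros_like(e)))
        assert np.all(out.currents == 0)

    def test_too_few_flank_points_is_error(self):
        e = potential_grid(CU_PROTOCOL)
        v = Voltammogram(CU_PROTOCOL, e, np.zeros_like(e))
        with pytest.raises(InvalidInputError):
            baseline_correct(v, flank_fraction=0.005)
        with pytest.raises(InvalidInputError):
            baseline_correct(v, flank_fraction=0.5)


class TestFindPeak:
    def test_noiseless_gaussian_height_and_position(self):
        v = gaussian_trace(CU_PROTOCOL, 0.1, 1e-6)
        peak = find_peak(v)
        assert peak.found
        assert peak.i_peak == pytest.approx(1e-6, rel=0.005)
        assert abs(peak.e_peak - 0.1) <= CU_PROTOCOL.step

    def test_flat_zero_trace_reports_no_peak(self):
        e = potential_grid(CU_PROTOCOL)
        peak = find_peak(Voltammogram(CU_PROTOCOL, e, np.zeros_like(e)))
        assert not peak.found

    def test_blank_with_sloped_baseline_reports_no_peak(self):
        e = potential_grid(CU_PROTOCOL)
        peak = find_peak(Voltammogram(CU_PROTOCOL, e, 2e-7 + 5e-7 * e))
        assert not peak.found

    def test_only_in_window_peak_is_returned(self):
        e = potential_grid(CU_PROTOCOL)
        two = (
            1e-6 * np.exp(-0.5 * ((e - 0.1) / 0.03) ** 2)
            + 5e-6 * np.exp(-0.5 * ((e - 0.3) / 0.03) ** 2)
        )
        peak = find_peak(Voltammogram(CU_PROTOCOL, e, two), window=(0.0, 0.2))
        assert peak.found
        assert abs(peak.e_peak - 0.1) <= CU_PROTOCOL.step
        assert peak.i_peak == pytest.approx(1e-6, rel=0.01)

    def test_window_outside_grid_is_error(self):
        v = gaussian_trace(CU_PROTOCOL, 0.1, 1e-6)
        with pytest.raises(InvalidInputError):
            find_peak(v, window=(2.0, 3.0))

    @given(slope=st.floats(-1e-6, 1e-6), intercept=st.floats(-1e-6, 1e-6))
    @settings(max_examples=50, deadline=None)
    def test_height_invariant_under_added_straight_line(self, slope, intercept):
        clean = find_peak(gaussian_trace(CU_PROTOCOL, 0.1, 1e-6)).i_peak
        tilted = find_peak(
            gaussian_trace(CU_PROTOCOL, 0.1, 1e-6, baseline=(intercept, slope))
        ).i_peak
        assert tilted == pytest.approx(clean, rel=0.01)

    def test_peak_position_within_one_step_across_window(self):
        for center in np.linspace(0.02, 0.18, 9):
            peak = find_peak(gaussian_trace(CU_PROTOCOL, center, 1e-6))
            assert abs(peak.e_peak - center) <= CU_PROTOCOL.step

    def test_height_estimate_linear_in_amplitude(self):
        base = find_peak(gaussian_trace(CU_PROTOCOL, 0.1, 1e-6)).i_peak
        for k in (0.1, 0.5, 2.0, 10.0):
            scaled = find_peak(gaussian_trace(CU_PROTOCOL, 0.1, k * 1e-6)).i_peak
            assert scaled == pytest.approx(k * base, rel=0.005)
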