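"""Forward-model unit and property tests.

Numeric oracles are independent of the implementation: widths are measured
by locating half-maximum crossings of the response evaluated on a dense
grid, never by calling the closed-form width routine being tested.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flavodpv import model
from flavodpv.exceptions import InvalidInputError, InvalidParameterError
from flavodpv.model import (
    PulseParams,
    RedoxCouple,
    apparent_n_from_width,
    convert_reference,
    dpv_response,
    nernst_reduced_fraction,
    theoretical_half_width,
)


def numeric_fwhm_mV(E, y):
    """Oracle: FWHM from half-maximum crossings by linear interpolation."""
    j = int(np.argmax(y))
    half = y[j] / 2.0
    left = np.nonzero(y[: j + 1] < half)[0]
    right = np.nonzero(y[j:] < half)[0]
    assert left.size and right.size, "peak not fully contained in grid"
    i = left[-1]
    x_lo = np.interp(half, [y[i], y[i + 1]], [E[i], E[i + 1]])
    k = right[0] + j
    x_hi = np.interp(half, [y[k], y[k - 1]], [E[k], E[k - 1]])
    return (x_hi - x_lo) * 1000.0


class TestNernstFraction:
    def test_symmetry_point(self):
        c = RedoxCouple(E0_V=-0.145)
        assert nernst_reduced_fraction(-0.145, c) == pytest.approx(0.5)

    def test_reduced_limit(self):
        c = RedoxCouple(E0_V=0.0)
        assert nernst_reduced_fraction(-5.0, c) == pytest.approx(1.0)
        assert nernst_reduced_fraction(5.0, c) == pytest.approx(0.0, abs=1e-12)

    def test_one_thermal_voltage_above(self):
        # E - E0 = RT/F at 303.15 K -> 1/(1+e)
        c = RedoxCouple(E0_V=0.0, n=1)
        E = model.GAS_CONSTANT * 303.15 / model.FARADAY
        assert nernst_reduced_fraction(E, c, T=303.15) == pytest.approx(
            1.0 / (1.0 + math.e), rel=1e-12
        )

    def test_strictly_decreasing(self):
        c = RedoxCouple(E0_V=-0.1, n=2)
        E = np.linspace(-0.5, 0.3, 100)
        f = nernst_reduced_fraction(E, c)
        assert np.all(np.diff(f) < 0)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            nernst_reduced_fraction(0.0, RedoxCouple(E0_V=0.0), T=-1.0)
        with pytest.raises(InvalidParameterError):
            RedoxCouple(E0_V=0.0, n=0.0)


class TestDpvResponse:
    @pytest.mark.parametrize("direction,sign", [("anodic", 1), ("cathodic", -1)])
    def test_peak_position(self, fine_grid, direction, sign):
        pulse = PulseParams(scan_direction=direction)
        c = RedoxCouple(E0_V=-0.145, n=1, magnitude=3.0)
        E = fine_grid if sign > 0 else fine_grid[::-1]
        y = dpv_response(E, c, pulse)
        Ep = E[np.argmax(y)]
        expected = c.E0_V - sign * pulse.amplitude_V / 2.0
        assert abs(Ep - expected) <= abs(E[1] - E[0]) + 1e-12

    def test_symmetry_about_peak(self):
        pulse = PulseParams()
        c = RedoxCouple(E0_V=-0.1, n=1, magnitude=2.0)
        Ep = c.E0_V - pulse.amplitude_V / 2.0
        x = np.linspace(0.0, 0.3, 500)
        left = dpv_response(Ep - x, c, pulse)
        right = dpv_response(Ep + x, c, pulse)
        assert np.max(np.abs(left - right)) < 1e-9 * np.max(left)

    def test_linear_in_magnitude(self, fine_grid):
        pulse = PulseParams()
        y1 = dpv_response(fine_grid, RedoxCouple(E0_V=0.0, magnitude=1.5), pulse)
        y2 = dpv_response(fine_grid, RedoxCouple(E0_V=0.0, magnitude=3.0), pulse)
        np.testing.assert_allclose(y2, 2.0 * y1, rtol=1e-12)

    def test_peak_height_equals_magnitude(self, fine_grid):
        pulse = PulseParams()
        y = dpv_response(fine_grid, RedoxCouple(E0_V=-0.1, magnitude=4.2), pulse)
        assert np.max(y) == pytest.approx(4.2, rel=1e-6)

    def test_empty_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            dpv_response([], RedoxCouple(E0_V=0.0), PulseParams())


class TestHalfWidth:
    def test_small_amplitude_limit(self):
        # 2*(RT/nF)*ln(3+2*sqrt(2)) = 90.6 mV for n=1 at 298.15 K
        limit = (
            2e3 * model.GAS_CONSTANT * 298.15 / model.FARADAY
            * math.log(3 + 2 * math.sqrt(2))
        )
        got = theoretical_half_width(1, 1e-6, 298.15)
        assert got == pytest.approx(limit, rel=1e-6)
        assert got == pytest.approx(90.6, abs=0.1)
        assert theoretical_half_width(2, 1e-6, 298.15) == pytest.approx(
            limit / 2, rel=1e-6
        )

    @pytest.mark.parametrize("n", [1, 2])
    @pytest.mark.parametrize("amplitude", [0.1, 25.0, 50.0])
    def test_matches_numeric_fwhm_of_response(self, fine_grid, n, amplitude):
        pulse = PulseParams(amplitude_mV=amplitude)
        c = RedoxCouple(E0_V=-0.1, n=n, magnitude=1.0)
        y = dpv_response(fine_grid, c, pulse, T=303.15)
        oracle = numeric_fwhm_mV(fine_grid, y)
        assert theoretical_half_width(n, amplitude, 303.15) == pytest.approx(
            oracle, abs=0.5
        )

    def test_reference_values_50mV_pulse(self):
        # frozen oracle values (numeric FWHM at RT/F = 26.12 mV)
        assert theoretical_half_width(1, 50, 303.15) == pytest.approx(100.5, abs=0.5)
        assert theoretical_half_width(2, 50, 303.15) == pytest.approx(62.2, abs=0.5)

    def test_monotone_in_n_and_amplitude(self):
        ns = [0.5, 1.0, 1.5, 2.0, 3.0]
        widths = [theoretical_half_width(n, 50, 303.15) for n in ns]
        assert all(a > b for a, b in zip(widths, widths[1:]))
        amps = [0.1, 10.0, 25.0, 50.0, 80.0]
        widths = [theoretical_half_width(1, a, 303.15) for a in amps]
        assert all(a < b for a, b in zip(widths, widths[1:]))

    @given(
        n=st.floats(0.5, 3.0),
        amplitude=st.floats(1.0, 80.0),
    )
    def test_apparent_n_round_trip(self, n, amplitude):
        W = theoretical_half_width(n, amplitude, 303.15)
        assert apparent_n_from_width(W, amplitude, 303.15) == pytest.approx(
            n, rel=1e-6
        )


class TestReferenceConversion:
    def test_ag_agcl_to_she(self):
        assert convert_reference(0.2, "Ag/AgCl", "SHE") == pytest.approx(0.399)

    def test_identity(self):
        assert convert_reference(0.123, "SHE", "SHE") == 0.123

    @given(E=st.floats(-1.0, 1.0))
    def test_round_trip(self, E):
        back = convert_reference(
            convert_reference(E, "Ag/AgCl_satKCl", "SHE"), "SHE", "Ag/AgCl_satKCl"
        )
        assert back == pytest.approx(E, abs=1e-12)

    def test_configurable_offset(self):
        assert convert_reference(0.2, "Ag/AgCl", "SHE", offset_V=0.2) == pytest.approx(
            0.4
        )

    def test_unknown_scale(self):
        with pytest.raises(InvalidParameterError):
            convert_reference(0.0, "SCE", "SHE")


class TestPulseParams:
    def test_invariants(self):
        with pytest.raises(InvalidParameterError):
            PulseParams(increment_mV=0)
        with pytest.raises(InvalidParameterError):
            PulseParams(pulse_width_ms=6000.0)
        with pytest.raises(InvalidParameterError):
            PulseParams(sampling_delay_ms=400.0)

    def test_scan_rate(self):
        # 5 mV per 5 s cycle -> 1 mV/s
        assert PulseParams().scan_rate_V_s == pytest.approx(1e-3)
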