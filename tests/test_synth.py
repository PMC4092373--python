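"""Synthetic-data generator tests: determinism, fixture truth, trace shapes."""

import numpy as np
import pytest

from flavodpv import synth
from flavodpv.core import AdditionEvent
from flavodpv.exceptions import InvalidInputError, InvalidParameterError
from flavodpv.model import theoretical_half_width
from tests.test_model import numeric_fwhm_mV


class TestDpvFixtures:
    def test_unknown_fixture_rejected(self):
        with pytest.raises(InvalidInputError):
            synth.make_dpv_fixture("no_such_fixture")

    def test_noise_free_is_deterministic(self):
        a = synth.make_dpv_fixture("bound_FMN_WT", 0.0, seed=1)
        b = synth.make_dpv_fixture("bound_FMN_WT", 0.0, seed=2)
        np.testing.assert_array_equal(a.currents, b.currents)

    def test_same_seed_reproducible_noisy(self):
        a = synth.make_dpv_fixture("free_FMN", 0.05, seed=7)
        b = synth.make_dpv_fixture("free_FMN", 0.05, seed=7)
        np.testing.assert_array_equal(a.currents, b.currents)

    def test_different_seeds_differ(self):
        a = synth.make_dpv_fixture("free_FMN", 0.05, seed=1)
        b = synth.make_dpv_fixture("free_FMN", 0.05, seed=2)
        assert not np.array_equal(a.currents, b.currents)

    def test_bound_fmn_peak_at_minus_145(self):
        v = synth.make_dpv_fixture("bound_FMN_WT", 0.0)
        resid = v.currents - synth.fixture_baseline(v.potentials_V)
        Ep = v.potentials_V[np.argmax(resid)]
        assert Ep * 1000 == pytest.approx(-145.0, abs=v.pulse.increment_mV)

    def test_grid_span_and_step(self):
        v = synth.make_dpv_fixture("free_RF", 0.0)
        assert v.potentials_V[0] == pytest.approx(-0.45)
        assert v.potentials_V[-1] == pytest.approx(0.25)
        assert np.allclose(np.diff(v.potentials_V), 0.005)

    def test_free_flavin_width_matches_two_electron_theory(self):
        """The ~60 mV free-flavin width is the n=2 theoretical width."""
        v = synth.make_dpv_fixture("free_FMN", 0.0)
        resid = v.currents - synth.fixture_baseline(v.potentials_V)
        W = numeric_fwhm_mV(v.potentials_V, resid)
        assert W == pytest.approx(theoretical_half_width(2, 50, 303.15), abs=3.0)

    def test_invented_components_flagged(self):
        v = synth.make_dpv_fixture("bound_FMN_WT", 0.0)
        heme = [c for c in v.metadata["components"] if c["kind"] == "gaussian"]
        assert heme and heme[0]["figure_derived_invented"] is True


class TestTitration:
    @staticmethod
    def _bound_component(voltammogram):
        return next(
            c for c in voltammogram.metadata["components"]
            if "bound" in c.get("label", "")
        )

    def test_half_saturation_magnitude(self):
        tit = synth.make_titration(concentrations_uM=[10.0], Kd_uM=10.0, i_max=7.0)
        assert self._bound_component(tit[0][1])["height"] == pytest.approx(3.5)

    def test_langmuir_scaling_at_52uM(self):
        tit = synth.make_titration(concentrations_uM=[52.0], Kd_uM=10.0, i_max=7.0)
        assert self._bound_component(tit[0][1])["height"] == pytest.approx(
            52.0 / 62.0 * 7.0, rel=1e-12
        )

    def test_magnitudes_non_decreasing(self):
        series = synth.make_titration_series(noise_frac=0.0)
        assert np.all(np.diff(series["peak_current_uA_cm2"]) >= 0)

    def test_default_52uM_point_reproduces_measured_peak(self):
        """Defaults place the 52 uM bound-peak current at 7 uA/cm2."""
        series = synth.make_titration_series(noise_frac=0.0)
        assert series["peak_current_uA_cm2"].iloc[-1] == pytest.approx(7.0, rel=1e-9)

    def test_empty_concentrations_rejected(self):
        with pytest.raises(InvalidInputError):
            synth.make_titration(concentrations_uM=[])

    def test_series_seeded(self):
        a = synth.make_titration_series(noise_frac=0.05, seed=3)
        b = synth.make_titration_series(noise_frac=0.05, seed=3)
        assert a.equals(b)


class TestCurrentTraces:
    def test_wt_flavin_plateau(self):
        tr = synth.make_current_trace("WT", "FMN", 4.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        assert tr.currents[-1] == pytest.approx(15.0, rel=0.05)

    def test_domcA_rf_equals_no_flavin(self):
        rf = synth.make_current_trace("dOmcA", "RF", 2.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        none = synth.make_current_trace("dOmcA", "none", 0.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        np.testing.assert_allclose(rf.currents, none.currents, rtol=1e-12)

    def test_domcA_fmn_tenfold_at_35h(self):
        fmn = synth.make_current_trace("dOmcA", "FMN", 2.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        none = synth.make_current_trace("dOmcA", "none", 0.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        t = 35 * 3600.0
        assert fmn.interp(t) / none.interp(t) == pytest.approx(10.0, rel=0.1)

    def test_mutant_lag_below_hundred_nA(self):
        tr = synth.make_current_trace("dMtrC", "none", 0.0, 0.4, 7.8, seed=0, noise_sd=0.0)
        early = tr.currents[tr.times_s < 2 * 3600.0]
        assert np.all(early < 0.1)

    def test_background_trace_is_flat_and_small(self):
        bg = synth.make_current_trace("WT", "FMN", 2.0, 0.4, 7.8, seed=0,
                                      noise_sd=0.0, lactate=False)
        assert np.all(bg.currents == bg.currents[0])
        assert bg.currents[0] < 0.1

    def test_noise_free_same_seed_identical(self):
        a = synth.make_current_trace("WT", "RF", 2.0, 0.4, 7.8, seed=5, noise_sd=0.0)
        b = synth.make_current_trace("WT", "RF", 2.0, 0.4, 7.8, seed=5, noise_sd=0.0)
        np.testing.assert_array_equal(a.currents, b.currents)

    def test_noisy_seeded(self):
        a = synth.make_current_trace("WT", "RF", seed=5)
        b = synth.make_current_trace("WT", "RF", seed=5)
        c = synth.make_current_trace("WT", "RF", seed=6)
        np.testing.assert_array_equal(a.currents, b.currents)
        assert not np.array_equal(a.currents, c.currents)

    def test_unknown_strain_or_flavin(self):
        with pytest.raises(InvalidParameterError):
            synth.make_current_trace("dFoo", "RF")
        with pytest.raises(InvalidParameterError):
            synth.make_current_trace("WT", "FAD")

    def test_addition_event_reaches_target_EF(self):
        t0 = 30 * 3600.0
        tr = synth.make_current_trace(
            "WT", "FMN", 2.0, -0.2, 7.8,
            events=[AdditionEvent(t0)], seed=0, noise_sd=0.0,
        )
        bg = tr.metadata["background_uA_cm2"]
        pre = tr.interp(t0 - 30.0) - bg
        post = tr.interp(t0 + 20 * synth._EF_RISE_TAU_S) - bg
        assert post / pre == pytest.approx(tr.metadata["EF_target"], rel=1e-4)

    def test_ef_table_flags_invented_entries(self):
        assert not synth.enhancement_factor_table("FMN", -0.2, 7.8)[
            "figure_derived_invented"
        ]
        assert synth.enhancement_factor_table("FMN", 0.4, 7.8)[
            "figure_derived_invented"
        ]
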