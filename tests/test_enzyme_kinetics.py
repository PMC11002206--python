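"""Beer-Lambert enzyme kinetics and citrate-synthase normalization."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitoflux.enzyme_kinetics import (
    DEFAULT_ASSAY_CONFIGS,
    AssayConfig,
    Carrier,
    CsActivity,
    Enzyme,
    beer_lambert_rate,
    citrate_synthase_activity,
    complex_iv_activity,
    normalize_to_cs,
    spectrophotometric_activity,
    subtract_background,
    to_electron_flux,
)
from mitoflux.errors import AssayConfigError, NormalizationError, TraceValidationError
from mitoflux.synthetic_data import TraceSpec, make_trace

CI = DEFAULT_ASSAY_CONFIGS[Enzyme.COMPLEX_I]
CS = DEFAULT_ASSAY_CONFIGS[Enzyme.CITRATE_SYNTHASE]


def absorbance_trace(activity, background=0.0, epsilon=6.22, volume=2.0,
                     direction=-1, **kw):
    return make_trace(TraceSpec(kind="absorbance", activity=activity,
                                background_rate=background, epsilon=epsilon,
                                volume_ml=volume, direction=direction,
                                absorbance_start=2.0, **kw))


class TestBeerLambertRate:
    def test_complex_i_worked_example(self):
        # 0.622 AU/min / (6.22 * 1 cm) = 0.1 mM/min * 2 mL -> 200 nmol/min
        rate, flags = beer_lambert_rate(-0.622, CI)
        assert rate == pytest.approx(200.0)
        assert flags == ()

    def test_zero_slope(self):
        assert beer_lambert_rate(0.0, CI)[0] == 0.0

    def test_complex_ii_micro_cuvette(self):
        cfg = DEFAULT_ASSAY_CONFIGS[Enzyme.COMPLEX_II]
        rate, _ = beer_lambert_rate(-0.191, cfg)
        assert rate == pytest.approx(2.0)

    def test_wrong_direction_flags_inverted_trace(self):
        _, flags = beer_lambert_rate(+0.5, CI)  # NADH assay should fall
        assert "direction_mismatch" in flags

    @given(slope=st.floats(-1, -1e-4), k=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_slope_and_volume_inverse_in_epsilon(self, slope, k):
        base, _ = beer_lambert_rate(slope, CI)
        doubled_slope, _ = beer_lambert_rate(k * slope, CI)
        assert doubled_slope == pytest.approx(k * base, rel=1e-9)
        cfg_vol = AssayConfig(enzyme=CI.enzyme, epsilon_mm_cm=CI.epsilon_mm_cm,
                              wavelength_nm=CI.wavelength_nm,
                              pathlength_cm=CI.pathlength_cm,
                              assay_volume_ml=CI.assay_volume_ml * k,
                              carrier=CI.carrier, direction=CI.direction)
        assert beer_lambert_rate(slope, cfg_vol)[0] \
            == pytest.approx(k * base, rel=1e-9)
        cfg_eps = AssayConfig(enzyme=CI.enzyme,
                              epsilon_mm_cm=CI.epsilon_mm_cm / 2,
                              wavelength_nm=CI.wavelength_nm,
                              pathlength_cm=CI.pathlength_cm,
                              assay_volume_ml=CI.assay_volume_ml,
                              carrier=CI.carrier, direction=CI.direction)
        assert beer_lambert_rate(slope, cfg_eps)[0] \
            == pytest.approx(2 * base, rel=1e-9)


class TestSubtractBackground:
    def test_simple_subtraction(self):
        assert subtract_background(200.0, 20.0) == (180.0, ())

    def test_pure_background(self):
        assert subtract_background(50.0, 50.0)[0] == 0.0

    def test_oversubtraction_flagged_not_clipped(self):
        net, flags = subtract_background(10.0, 15.0)
        assert net == -5.0
        assert "negative_net_rate" in flags

    def test_mismatched_enzymes_rejected(self):
        with pytest.raises(AssayConfigError):
            subtract_background(10.0, 5.0, Enzyme.COMPLEX_I, Enzyme.COMPLEX_II)


class TestCitrateSynthase:
    def test_worked_example(self):
        # +0.136 AU/min / 13.6 = 0.01 mM/min * 0.25 mL = 2.5 nmol/min / 5 mg
        tr = absorbance_trace(2.5, epsilon=13.6, volume=0.25, direction=+1)
        cs = citrate_synthase_activity(tr, CS, tissue_grams_in_aliquot=0.005)
        assert cs.rate == pytest.approx(500.0, rel=1e-9)

    def test_linearity_in_slope(self):
        tr = absorbance_trace(5.0, epsilon=13.6, volume=0.25, direction=+1)
        cs = citrate_synthase_activity(tr, CS, tissue_grams_in_aliquot=0.005)
        assert cs.rate == pytest.approx(1000.0, rel=1e-9)

    def test_zero_tissue_mass_rejected(self):
        tr = absorbance_trace(2.5, epsilon=13.6, volume=0.25, direction=+1)
        with pytest.raises(TraceValidationError):
            citrate_synthase_activity(tr, CS, tissue_grams_in_aliquot=0.0)


class TestComplexIV:
    def test_flux_and_electron_flux(self):
        tr = make_trace(TraceSpec(kind="respirometry", state2_flux=12.5,
                                  state3_flux=12.5, volume_ml=2.0))
        act = complex_iv_activity(tr, chamber_volume_ml=2.0)
        assert act.rate_substrate == pytest.approx(12.5, rel=1e-9)
        assert act.electron_flux == pytest.approx(50.0, rel=1e-9)


class TestElectronFlux:
    @pytest.mark.parametrize("rate, carrier, expected", [
        (100.0, Carrier.NADH, 200.0),
        (50.0, Carrier.CYTOCHROME_C, 50.0),
        (21.0, Carrier.O2, 84.0),
        (10.0, Carrier.DCPIP, 20.0),
    ])
    def test_equivalences(self, rate, carrier, expected):
        assert to_electron_flux(rate, carrier) == expected

    def test_unknown_carrier_rejected(self):
        with pytest.raises(AssayConfigError):
            to_electron_flux(10.0, Carrier.DTNB_THIOLATE)


class TestNormalizeToCs:
    @pytest.mark.parametrize("eflux, cs, expected", [
        (500.0, 500.0, 1.0), (200.0, 50.0, 4.0),
    ])
    def test_division(self, eflux, cs, expected):
        assert normalize_to_cs(eflux, CsActivity(rate=cs)).value \
            == pytest.approx(expected)

    def test_zero_cs_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_to_cs(500.0, CsActivity(rate=0.0))

    @given(x=st.floats(1, 1000), y=st.floats(1, 1000), c=st.floats(0.01, 100))
    @settings(max_examples=50, deadline=None)
    def test_content_normalization_invariance(self, x, y, c):
        a = normalize_to_cs(x, CsActivity(rate=y)).value
        b = normalize_to_cs(c * x, CsActivity(rate=c * y)).value
        assert b == pytest.approx(a, rel=1e-9)


class TestAbsorbanceRoundtrip:
    @given(activity=st.floats(5, 500), background=st.floats(0, 50))
    @settings(max_examples=30, deadline=None)
    def test_generator_analyzer_roundtrip(self, activity, background):
        """A trace generated from (activity + background) minus a
        background-only trace recovers the generating activity."""
        total_tr = absorbance_trace(activity, background=background)
        bg_tr = absorbance_trace(0.0, background=background)
        act = spectrophotometric_activity(total_tr, CI, background_trace=bg_tr)
        assert act.rate_substrate == pytest.approx(activity, rel=1e-7,
                                                   abs=1e-7)
        assert act.background_subtracted
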