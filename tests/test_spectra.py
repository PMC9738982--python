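"""Spectrum container, conversions, preprocessing and file round trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import speccult as sc
from speccult.spectra import Spectrum, SpectrumSet, clip_small_negatives


def make_spectrum(values, kind=sc.ABSORPTION, **meta):
    lam = np.linspace(330, 860, len(values))
    return Spectrum(lam, np.asarray(values, dtype=float), kind, **meta)


class TestSpectrumInvariants:
    def test_non_monotone_wavelengths_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([400.0, 399.0, 401.0]), np.zeros(3), sc.ABSORPTION)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length mismatch"):
            Spectrum(np.array([1.0, 2.0]), np.zeros(3), sc.ABSORPTION)

    def test_unknown_value_kind_rejected(self):
        with pytest.raises(ValueError, match="value_kind"):
            Spectrum(np.array([1.0, 2.0]), np.zeros(2), "absorbance")

    def test_value_range_validation(self):
        make_spectrum([0.0, 50.0, 100.0]).validate_values()
        with pytest.raises(ValueError):
            make_spectrum([0.0, 101.0, 5.0]).validate_values()
        with pytest.raises(ValueError):
            make_spectrum([-2.0, 1.0, 5.0]).validate_values(tolerance=1.0)


class TestConvertValueKind:
    @pytest.mark.parametrize(
        "t, abs_pct",
        [(1.0, 0.0), (0.25, 75.0), (0.378, 62.2), (0.0, 100.0)],
    )
    def test_transmittance_to_absorption(self, t, abs_pct):
        s = make_spectrum([t, t], kind=sc.TRANSMITTANCE)
        out = sc.convert_value_kind(s, sc.ABSORPTION)
        assert out.values == pytest.approx([abs_pct, abs_pct], abs=1e-12)

    def test_noop_conversion_warns(self):
        s = make_spectrum([10.0, 20.0])
        with pytest.warns(UserWarning, match="already"):
            out = sc.convert_value_kind(s, sc.ABSORPTION)
        assert out is s

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_exact(self, values):
        s = make_spectrum(values, kind=sc.TRANSMITTANCE)
        back = sc.convert_value_kind(
            sc.convert_value_kind(s, sc.ABSORPTION), sc.TRANSMITTANCE
        )
        # exact to machine precision on the [0, 1] scale (the subtraction
        # 1 - T cannot preserve bits of denormal-tiny transmittances)
        assert np.max(np.abs(back.values - np.asarray(values))) <= 1e-13

    def test_metadata_preserved(self):
        s = make_spectrum([0.5, 0.6], kind=sc.TRANSMITTANCE, species="CEM",
                          counter_concentration=5e5)
        out = sc.convert_value_kind(s, sc.ABSORPTION)
        assert out.species == "CEM" and out.counter_concentration == 5e5


class TestWindow:
    def test_instrument_grid_windowed_to_band(self):
        lam = np.arange(177.0, 892.0, 0.22)
        s = Spectrum(lam, np.zeros(lam.size), sc.ABSORPTION)
        out = sc.window_spectrum(s)
        assert out.wavelengths_nm[0] >= 330.0 and out.wavelengths_nm[-1] <= 860.0
        assert len(out) > 0

    def test_inclusive_endpoints_and_idempotent(self):
        lam = np.array([329.0, 330.0, 500.0, 860.0, 861.0])
        s = Spectrum(lam, np.arange(5.0), sc.ABSORPTION)
        once = sc.window_spectrum(s)
        assert np.array_equal(once.wavelengths_nm, [330.0, 500.0, 860.0])
        twice = sc.window_spectrum(once)
        assert np.array_equal(twice.values, once.values)

    def test_empty_window_raises(self):
        s = make_spectrum(np.zeros(10))
        with pytest.raises(ValueError, match="no samples"):
            sc.window_spectrum(s, 500.05, 500.06)


class TestArtifactRemoval:
    def test_empty_mask_is_identity(self):
        s = make_spectrum(np.linspace(0, 50, 20))
        assert sc.remove_lamp_artifacts(s, []) is s

    def test_spike_interpolated_close_to_smooth_curve(self, cem_model, lam):
        smooth = cem_model.evaluate(lam, 5e5)
        spiked = smooth.copy()
        idx = int(np.argmin(np.abs(lam - 656.0)))
        spiked[idx] += 30.0
        s = Spectrum(lam, spiked, sc.ABSORPTION)
        out = sc.remove_lamp_artifacts(s, [(654.0, 658.0)])
        assert np.max(np.abs(out.values - smooth)) < 0.1

    def test_disjoint_masks_commute(self):
        rng = np.random.default_rng(7)
        s = make_spectrum(rng.uniform(0, 80, 100))
        both = sc.remove_lamp_artifacts(s, [(400, 420), (700, 720)])
        sequential = sc.remove_lamp_artifacts(
            sc.remove_lamp_artifacts(s, [(400, 420)]), [(700, 720)]
        )
        assert np.array_equal(both.values, sequential.values)

    def test_mask_covering_grid_end_raises(self):
        s = make_spectrum(np.zeros(10))
        with pytest.raises(ValueError, match="grid end"):
            sc.remove_lamp_artifacts(s, [(320.0, 340.0)])

    def test_window_and_masking_commute_when_masks_inside_window(self):
        lam = np.arange(177.0, 892.0, 1.0)
        rng = np.random.default_rng(1)
        s = Spectrum(lam, rng.uniform(0, 90, lam.size), sc.ABSORPTION)
        masks = [(484, 488), (654, 658)]
        a = sc.remove_lamp_artifacts(sc.window_spectrum(s), masks)
        b = sc.window_spectrum(sc.remove_lamp_artifacts(s, masks))
        assert np.allclose(a.values, b.values, atol=0, rtol=0)


class TestNegativeClipping:
    def test_small_negatives_clipped_large_rejected(self):
        s = make_spectrum([-0.5, 0.2, 3.0])
        out = clip_small_negatives(s)
        assert out.values[0] == 0.0 and out.values[2] == 3.0
        with pytest.raises(ValueError):
            clip_small_negatives(make_spectrum([-2.0, 0.0, 1.0]))


class TestQualityFilter:
    def test_model_spectrum_kept_noise_rejected(self, cem_model, lam):
        good = Spectrum(lam, cem_model.evaluate(lam, 5e5), sc.ABSORPTION)
        rng = np.random.default_rng(0)
        bad = Spectrum(lam, rng.uniform(0, 60, lam.size), sc.ABSORPTION)
        kept, rejected = sc.quality_filter(SpectrumSet([good, bad]))
        assert len(kept) == 1 and len(rejected) == 1
        assert "R2" in rejected[0].extra["rejection_reason"]

    def test_zero_threshold_keeps_all_valid(self, cem_model, lam):
        rng = np.random.default_rng(0)
        spectra = [
            Spectrum(lam, rng.uniform(0, 60, lam.size), sc.ABSORPTION)
            for _ in range(3)
        ]
        kept, rejected = sc.quality_filter(SpectrumSet(spectra), r2_threshold=0.0)
        assert len(kept) == 3 and len(rejected) == 0


# ---- file round trips -----------------------------------------------------

meta_strategy = st.fixed_dictionaries(
    {},
    optional={
        "species": st.sampled_from(["CEM", "CA"]),
        "counter_concentration": st.floats(1e4, 1e7),
        "time_h": st.floats(0, 48),
        "set_id": st.sampled_from(["W11", "W23"]),
    },
)


@st.composite
def spectrum_sets(draw):
    n_points = draw(st.integers(3, 20))
    n_spectra = draw(st.integers(1, 4))
    lam = np.cumsum(draw(st.lists(st.floats(0.1, 10.0), min_size=n_points,
                                  max_size=n_points))) + 330.0
    kind = draw(st.sampled_from([sc.ABSORPTION, sc.TRANSMITTANCE]))
    hi = 100.0 if kind == sc.ABSORPTION else 1.0
    spectra = []
    for i in range(n_spectra):
        vals = np.asarray(
            draw(st.lists(st.floats(0, hi, allow_nan=False), min_size=n_points,
                          max_size=n_points))
        )
        meta = draw(meta_strategy)
        spectra.append(Spectrum(lam.copy(), vals, kind, cuvette_id=f"cuv{i}", **meta))
    return SpectrumSet(spectra)


class TestFileRoundTrips:
    @given(spectrum_sets())
    @settings(max_examples=25, deadline=None)
    def test_wide_csv_round_trip_bit_exact(self, tmp_path_factory, sset):
        path = tmp_path_factory.mktemp("io") / "set.csv"
        sc.write_spectra(sset, path, "wide_csv")
        back = sc.read_spectra(path, "wide_csv")
        assert len(back) == len(sset)
        for a, b in zip(sset, back):
            assert np.array_equal(a.wavelengths_nm, b.wavelengths_nm)
            assert np.array_equal(a.values, b.values)
            assert a.value_kind == b.value_kind
            assert a.species == b.species
            assert a.counter_concentration == b.counter_concentration
            assert a.time_h == b.time_h
            assert a.set_id == b.set_id

    @given(spectrum_sets())
    @settings(max_examples=25, deadline=None)
    def test_two_column_round_trip_bit_exact(self, tmp_path_factory, sset):
        path = tmp_path_factory.mktemp("io") / "one.txt"
        single = SpectrumSet([sset[0]])
        sc.write_spectra(single, path, "two_column_text")
        back = sc.read_spectra(path, "two_column_text")
        assert np.array_equal(back[0].values, single[0].values)
        assert np.array_equal(back[0].wavelengths_nm, single[0].wavelengths_nm)
        assert back[0].value_kind == single[0].value_kind

    def test_wide_csv_parses_metadata_and_grid(self, tmp_path):
        path = tmp_path / "set.csv"
        path.write_text(
            "wavelength;value_kind=absorption_percent,"
            "cuv1;species=CEM;concentration=5.5e5,cuv2\n"
            "400,10,11\n401,12,13\n402,14,15\n403,16,17\n404,18,19\n"
        )
        sset = sc.read_spectra(path, "wide_csv")
        assert len(sset) == 2 and sset.common_grid
        assert sset[0].species == "CEM"
        assert sset[0].counter_concentration == 5.5e5

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# value_kind=absorption_percent\n400 1.0\n401 oops\n")
        with pytest.raises(sc.ParseError, match=":3"):
            sc.read_spectra(path, "two_column_text")

    def test_non_monotone_grid_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("# value_kind=absorption_percent\n400 1\n399 2\n401 3\n")
        with pytest.raises(ValueError, match="strictly increasing"):
            sc.read_spectra(path, "two_column_text")

    def test_missing_value_kind_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("400 1\n401 2\n")
        with pytest.raises(ValueError, match="value_kind"):
            sc.read_spectra(path, "two_column_text")


class TestResampling:
    def test_resample_onto_first_grid(self):
        a = Spectrum(np.arange(330.0, 860.5, 1.0), np.full(531, 10.0), sc.ABSORPTION)
        b = Spectrum(np.arange(330.5, 860.0, 1.0), np.full(530, 20.0), sc.ABSORPTION)
        out = sc.resample_to_common_grid(SpectrumSet([a, b]))
        assert out.common_grid
        assert out[1].values == pytest.approx(20.0)

    def test_coverage_gap_rejected(self):
        a = Spectrum(np.arange(330.0, 860.5, 1.0), np.zeros(531), sc.ABSORPTION)
        b = Spectrum(np.arange(340.0, 860.5, 1.0), np.zeros(521), sc.ABSORPTION)
        with pytest.raises(ValueError, match="more than 1 nm"):
            sc.resample_to_common_grid(SpectrumSet([a, b]))
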