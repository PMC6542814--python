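"""Spectrum container, unit conversion, band statistics and CSV round-trip."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from photoloc import (
    CANONICAL_GRID,
    Spectrum,
    SpectrumUnit,
    band_mean,
    read_spectrum_csv,
    resample,
    to_photon_units,
    write_spectrum_csv,
)


class TestSpectrumInvariants:
    def test_rejects_unsorted_wavelengths(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([500.0, 400.0]), np.array([1.0, 1.0]))

    def test_rejects_duplicate_wavelengths(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            Spectrum(np.array([400.0, 400.0, 500.0]), np.ones(3))

    def test_rejects_negative_values(self):
        with pytest.raises(ValueError, match="non-negative"):
            Spectrum(np.array([400.0, 500.0]), np.array([1.0, -0.1]))

    def test_fraction_unit_enforces_upper_bound(self):
        with pytest.raises(ValueError, match="exceed 1"):
            Spectrum(np.array([400.0, 500.0]), np.array([0.5, 1.5]), SpectrumUnit.FRACTION)

    def test_relative_unit_may_exceed_one(self):
        # spark relative radiance peaks above a white standard
        s = Spectrum(np.array([400.0, 500.0]), np.array([1.0, 2.15]))
        assert s.values.max() == 2.15

    def test_arithmetic_requires_identical_grids(self):
        a = Spectrum(np.array([400.0, 500.0]), np.ones(2))
        b = Spectrum(np.array([400.0, 600.0]), np.ones(2))
        with pytest.raises(ValueError, match="different wavelength grids"):
            a * b


class TestResample:
    def test_constant_spectrum_preserved(self):
        s = Spectrum(np.array([400.0, 700.0]), np.array([1.0, 1.0]))
        out = resample(s, CANONICAL_GRID)
        assert np.allclose(out.values, 1.0)

    def test_linear_midpoint(self):
        s = Spectrum(np.array([400.0, 700.0]), np.array([0.0, 3.0]))
        out = resample(s, np.array([450.0, 500.0]))
        assert out.values[1] == pytest.approx(1.0)

    def test_identity_on_own_grid(self):
        s = Spectrum(CANONICAL_GRID, np.linspace(0, 2, CANONICAL_GRID.size))
        assert resample(s, s.grid) is s

    def test_extrapolation_names_offending_wavelength(self):
        s = Spectrum(np.array([450.0, 650.0]), np.ones(2))
        with pytest.raises(ValueError, match="400"):
            resample(s, np.array([400.0, 500.0]))

    def test_unit_preserved(self):
        s = Spectrum(np.array([400.0, 700.0]), np.ones(2), SpectrumUnit.FRACTION)
        assert resample(s, np.array([500.0, 600.0])).unit is SpectrumUnit.FRACTION

    @given(st.floats(min_value=0.0, max_value=10.0))
    @settings(deadline=None, max_examples=25)
    def test_constant_preserved_property(self, level):
        s = Spectrum(np.array([400.0, 550.0, 700.0]), np.full(3, level))
        out = resample(s, np.linspace(410, 690, 17))
        assert np.allclose(out.values, level)


class TestPhotonConversion:
    def test_zero_maps_to_zero(self):
        s = Spectrum(np.array([400.0, 500.0]), np.zeros(2), SpectrumUnit.ENERGY_RADIANCE)
        assert np.all(to_photon_units(s).values == 0)

    def test_linear_in_wavelength(self):
        s = Spectrum(np.array([350.0, 700.0]), np.ones(2), SpectrumUnit.ENERGY_RADIANCE)
        out = to_photon_units(s)
        assert out.values[1] / out.values[0] == pytest.approx(2.0, rel=1e-12)

    def test_one_watt_at_500nm(self):
        # lambda/(h c) with SI-exact h and c: 500e-9 / 1.986445857e-25
        s = Spectrum(np.array([400.0, 500.0]), np.ones(2), SpectrumUnit.ENERGY_RADIANCE)
        out = to_photon_units(s)
        assert out.values[1] == pytest.approx(2.517057e18, rel=1e-6)
        assert out.unit is SpectrumUnit.PHOTON_RADIANCE

    def test_rejects_non_energy_input(self):
        s = Spectrum(np.array([400.0, 500.0]), np.ones(2), SpectrumUnit.RELATIVE)
        with pytest.raises(ValueError, match="energy_radiance"):
            to_photon_units(s)

    def test_scaling_linearity(self):
        vals = np.linspace(0.5, 2.0, CANONICAL_GRID.size)
        s = Spectrum(CANONICAL_GRID, vals, SpectrumUnit.ENERGY_RADIANCE)
        doubled = Spectrum(CANONICAL_GRID, 2 * vals, SpectrumUnit.ENERGY_RADIANCE)
        assert np.allclose(
            to_photon_units(doubled).values, 2 * to_photon_units(s).values
        )


class TestBandMean:
    def test_constant(self):
        s = Spectrum(CANONICAL_GRID, np.full(CANONICAL_GRID.size, 1.34))
        assert band_mean(s, 400, 700) == pytest.approx(1.34)

    def test_white_standard_is_one(self):
        s = Spectrum(CANONICAL_GRID, np.ones(CANONICAL_GRID.size))
        assert band_mean(s, 400, 700) == pytest.approx(1.0)

    def test_linear_ramp(self):
        s = Spectrum(CANONICAL_GRID, np.linspace(0, 2, CANONICAL_GRID.size))
        assert band_mean(s, 400, 700) == pytest.approx(1.0)

    def test_rejects_inverted_band(self):
        s = Spectrum(CANONICAL_GRID, np.ones(CANONICAL_GRID.size))
        with pytest.raises(ValueError, match="lo < hi"):
            band_mean(s, 600, 500)

    @given(
        st.floats(min_value=400.0, max_value=600.0),
        st.floats(min_value=10.0, max_value=100.0),
    )
    @settings(deadline=None, max_examples=25)
    def test_all_ones_band_mean_is_one_on_any_subband(self, lo, width):
        s = Spectrum(CANONICAL_GRID, np.ones(CANONICAL_GRID.size))
        hi = min(lo + width, 700.0)
        assert band_mean(s, lo, hi) == pytest.approx(1.0)


class TestCsvRoundTrip:
    def test_minimal_two_row_file(self, tmp_path):
        p = tmp_path / "min.csv"
        p.write_text("wavelength_nm,value\n400,0.5\n700,1.0\n")
        s = read_spectrum_csv(p)
        assert len(s) == 2
        assert s.values[1] == 1.0

    def test_round_trip_301_points(self, tmp_path, synth_config):
        from photoloc import generate_spark

        s = generate_spark(synth_config).rho
        p = tmp_path / "spark.csv"
        write_spectrum_csv(s, p)
        back = read_spectrum_csv(p)
        assert np.allclose(back.values, s.values, rtol=1e-12, atol=0)
        assert np.array_equal(back.wavelengths_nm, s.wavelengths_nm)

    def test_out_of_band_wavelength_rejected_by_policy(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,value\n399,0.5\n700,1.0\n")
        with pytest.raises(ValueError, match="line 2"):
            read_spectrum_csv(p, wavelength_range=(400, 700))

    def test_missing_header(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wl,v\n400,1\n700,1\n")
        with pytest.raises(ValueError, match="line 1"):
            read_spectrum_csv(p)

    def test_unsorted_rows_report_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,value\n500,1\n400,1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_spectrum_csv(p)

    def test_negative_value_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("wavelength_nm,value\n400,1\n500,-2\n700,1\n")
        with pytest.raises(ValueError, match="line 3"):
            read_spectrum_csv(p)
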