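"""Spectral preprocessing: resampling, averaging, smoothing, chlorophyll."""

import numpy as np
import pytest

import floravision as fv
from floravision.spectra import STANDARD_GRID, SpectrumError, mask_artefact


class TestSpectrumInvariants:
    def test_non_monotone_grid_rejected(self):
        with pytest.raises(SpectrumError, match="monotone"):
            fv.Spectrum(np.array([700.0, 500.0, 300.0]), np.array([0.1, 0.1, 0.1]))

    def test_negative_reflectance_rejected(self):
        with pytest.raises(SpectrumError, match="negative"):
            fv.Spectrum(np.array([300.0, 700.0]), np.array([0.1, -0.1]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(SpectrumError):
            fv.Spectrum(np.array([300.0, 400.0, 500.0]), np.array([0.1, 0.2]))


class TestIO:
    def test_two_column_roundtrip(self, tmp_path):
        path = tmp_path / "acc1.csv"
        path.write_text("\n".join(f"{wl},0.1" for wl in range(300, 701)))
        (s,) = fv.read_spectra(path, format="two_column")
        assert s.accession_id == "acc1"
        assert s.wavelengths_nm.size == 401
        assert np.allclose(s.reflectance, 0.1)

    def test_wide_table_column_count(self, tmp_path):
        path = tmp_path / "wide.csv"
        rows = ["wavelength_nm,a,b,c"] + [f"{wl},0.1,0.2,0.3" for wl in range(300, 701)]
        path.write_text("\n".join(rows))
        spectra = fv.read_spectra(path, format="wide_table")
        assert [s.accession_id for s in spectra] == ["a", "b", "c"]

    def test_descending_wavelengths_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("\n".join(f"{wl},0.1" for wl in range(700, 299, -1)))
        with pytest.raises(SpectrumError, match="monotone"):
            fv.read_spectra(path, format="two_column")

    def test_write_read_roundtrip_six_digits(self, tmp_path, flat):
        rng = np.random.default_rng(5)
        spectra = [
            fv.Spectrum(STANDARD_GRID.copy(), rng.random(401), accession_id=f"a{i}")
            for i in range(3)
        ]
        out = tmp_path / "out.csv"
        fv.write_spectra(spectra, out)
        back = fv.read_spectra(out, format="wide_table")
        for orig, rt in zip(spectra, back):
            assert np.allclose(rt.reflectance, orig.reflectance, rtol=1e-5)


class TestResample:
    def test_constant_preserved(self):
        s = fv.Spectrum(np.arange(300.0, 701.0, 5.0), np.full(81, 0.5))
        r = fv.resample(s)
        assert r.wavelengths_nm.size == 401
        assert np.allclose(r.reflectance, 0.5)

    def test_linear_ramp_exact(self):
        wl = np.arange(300.0, 701.0, 5.0)
        s = fv.Spectrum(wl, (wl - 300.0) / 400.0)
        r = fv.resample(s)
        assert np.allclose(r.reflectance, (STANDARD_GRID - 300.0) / 400.0, atol=1e-12)

    def test_coverage_gap_error(self):
        s = fv.Spectrum(np.arange(305.0, 701.0), np.full(396, 0.5))
        with pytest.raises(SpectrumError, match="305"):
            fv.resample(s)


class TestAverageReplicates:
    def test_pointwise_mean(self, flat):
        avg = fv.average_replicates([flat(0.2, "x"), flat(0.4, "x")])
        assert np.allclose(avg.reflectance, 0.3)

    def test_single_identity(self, flat):
        s = flat(0.7)
        assert np.array_equal(fv.average_replicates([s]).reflectance, s.reflectance)

    def test_mixed_accessions_need_pool_flag(self, flat):
        with pytest.raises(SpectrumError, match="pool"):
            fv.average_replicates([flat(0.2, "x"), flat(0.4, "y")])
        pooled = fv.average_replicates([flat(0.2, "x"), flat(0.4, "y")], pool=True)
        assert pooled.accession_id == "x+y"

    def test_noise_shrinks_as_sqrt_n(self, flat):
        rng = np.random.default_rng(1)
        sigma, truth = 0.01, 0.5
        reps = [
            flat(0.0, "x").with_values(np.clip(truth + rng.normal(0, sigma, 401), 0, None))
            for _ in range(3)
        ]
        avg = fv.average_replicates(reps)
        assert np.all(np.abs(avg.reflectance - truth) < 3 * sigma / np.sqrt(3))


class TestSmooth:
    def test_constant_unchanged(self, flat):
        assert np.allclose(fv.smooth(flat(0.5)).reflectance, 0.5)

    def test_impulse_single_pass_spreads_one_ninth(self, flat):
        values = np.zeros(401)
        values[200] = 1.0  # 500 nm
        s = flat(0.0).with_values(values)
        out = fv.smooth(s, passes=1).reflectance
        assert np.allclose(out[196:205], 1 / 9)
        assert out[195] == 0.0 and out[205] == 0.0

    def test_ramp_interior_unchanged(self):
        s = fv.Spectrum(STANDARD_GRID.copy(), (STANDARD_GRID - 300.0) / 400.0)
        out = fv.smooth(s, passes=3).reflectance
        assert np.allclose(out[12:-12], s.reflectance[12:-12], atol=1e-12)

    def test_linearity(self, flat):
        rng = np.random.default_rng(1)
        f, g = rng.random(401), rng.random(401)
        lhs = fv.smooth(flat(0.0).with_values(2.0 * f + 3.0 * g)).reflectance
        rhs = (
            2.0 * fv.smooth(flat(0.0).with_values(f)).reflectance
            + 3.0 * fv.smooth(flat(0.0).with_values(g)).reflectance
        )
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_window_larger_than_spectrum_error(self):
        s = fv.Spectrum(np.arange(300.0, 305.0), np.full(5, 0.5))
        with pytest.raises(SpectrumError, match="window"):
            fv.smooth(s, window_nm=9)


class TestBrightnessAndNormalization:
    def test_constant_half_area(self, flat):
        assert fv.brightness(flat(0.5)) == pytest.approx(200.0)

    def test_zero_spectrum(self, flat):
        assert fv.brightness(flat(0.0)) == 0.0

    def test_triangle_area(self):
        values = np.interp(STANDARD_GRID, [300.0, 500.0, 700.0], [0.0, 1.0, 0.0])
        s = fv.Spectrum(STANDARD_GRID.copy(), values)
        assert fv.brightness(s) == pytest.approx(200.0)

    def test_normalize_constant(self, flat):
        out = fv.normalize_integral(flat(0.5), target=100.0)
        assert np.allclose(out.reflectance, 0.25)

    def test_normalize_idempotent_and_scale_invariant(self, flat):
        rng = np.random.default_rng(2)
        s = flat(0.0).with_values(rng.random(401) + 0.1)
        once = fv.normalize_integral(s)
        assert np.allclose(fv.normalize_integral(once).reflectance, once.reflectance)
        scaled = fv.normalize_integral(s.with_values(7.3 * s.reflectance))
        assert np.allclose(scaled.reflectance, once.reflectance)

    def test_zero_spectrum_error(self, flat):
        with pytest.raises(SpectrumError, match="zero-area"):
            fv.normalize_integral(flat(0.0))


class TestChlorophyllDetection:
    def test_flat_negative(self, flat):
        assert not fv.detect_chlorophyll(flat(0.5)).present

    def test_gaussian_band_at_675_detected(self, flat):
        dip = 0.15 * np.exp(-((STANDARD_GRID - 675.0) ** 2) / (2 * 10.0**2))
        call = fv.detect_chlorophyll(fv.smooth(flat(0.5).with_values(0.5 - dip)))
        assert call.present
        assert abs(call.minimum_wavelength_nm - 675.0) <= 3.0

    def test_monotone_slope_negative(self, flat):
        s = flat(0.0).with_values(np.linspace(0.1, 0.6, 401))
        assert not fv.detect_chlorophyll(s).present

    def test_generator_labels_recovered_perfectly(self):
        """100% sensitivity/specificity on labelled synthetic spectra at
        band depth >= 2x the prominence threshold and noise sd <= 0.005."""
        from dataclasses import replace

        rng = np.random.default_rng(42)
        hits = total = 0
        for name, profile in fv.DEFAULT_CLASS_PROFILES.items():
            profile = replace(profile, noise_sd=0.005)
            for _ in range(10):
                s, truth = fv.simulate_flower_spectrum(profile, rng)
                call = fv.detect_chlorophyll(fv.smooth(s))
                hits += call.present == truth["chlorophyll"]
                total += 1
        assert hits == total


def test_artefact_masking_interpolates_interval(flat):
    values = np.full(401, 0.5)
    values[(STANDARD_GRID > 475) & (STANDARD_GRID < 500)] = 0.1
    fixed = mask_artefact(flat(0.0).with_values(values), (470.0, 505.0))
    assert np.allclose(fixed.reflectance, 0.5)
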