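"""Feature bank: every family against an analytic or brute-force oracle."""

import numpy as np
import pandas as pd
import pytest

from wakebreath import synthgen
from wakebreath.featurebank import (
    FeatureConfig,
    assemble_feature_table,
    phase_features,
)
from wakebreath.featurebank import bispectral, imagefeat, nonlinear, spectral
from wakebreath.featurebank import timedomain as td
from wakebreath.featurebank import timefreq as tf
from wakebreath.preprocess import BreathPhase
from wakebreath.spectra import BispectrumEstimate, GapSet

FS = float(synthgen.DEFAULT_FS)


class TestSpectralFeatures:
    def test_flat_psd_has_unit_entropy_and_crest(self):
        out = spectral.spectral_features(np.arange(16.0), np.ones(16))
        assert out["entropy"] == pytest.approx(1.0)
        assert out["crest"] == pytest.approx(1.0)

    def test_single_bin_psd(self):
        psd = np.zeros(8)
        psd[3] = 2.0
        out = spectral.spectral_features(np.arange(8.0) * 10, psd)
        assert out["entropy"] == pytest.approx(0.0)
        assert out["centroid"] == pytest.approx(30.0)

    def test_triangular_psd_hand_oracle(self):
        """Powers (1,2,1) at 100/200/300 Hz: centroid 200, bandwidth sqrt(5000)."""
        out = spectral.spectral_features(np.array([100.0, 200.0, 300.0]),
                                         np.array([1.0, 2.0, 1.0]))
        assert out["centroid"] == pytest.approx(200.0)
        assert out["bandwidth"] == pytest.approx(np.sqrt(5000.0))

    def test_empty_band_masked(self):
        out = spectral.spectral_features(np.arange(8.0), np.ones(8),
                                         band=(100.0, 200.0))
        assert np.isnan(out["mean_power"])


class TestBispectralFeatures:
    def _est(self, mag):
        n = mag.shape[0]
        f = np.arange(n) * 10.0
        return BispectrumEstimate(f, f, mag, np.zeros_like(mag),
                                  np.zeros_like(mag), 8)

    def test_empty_region_list_masks_stats_zeroes_geometry(self):
        out = bispectral.bispectral_features(self._est(np.ones((16, 16))),
                                             GapSet())
        assert np.isnan(out["mag_mean"])
        assert out["box_area"] == 0.0 and out["n_regions"] == 0.0

    def test_box_geometry_oracle(self):
        """5x5-bin box at 10 Hz resolution: area 2500, perimeter 200, aspect 1."""
        gaps = GapSet(bispec_regions=[(2, 7, 3, 8, "above")])
        out = bispectral.bispectral_features(self._est(np.ones((16, 16))), gaps)
        assert out["box_area"] == pytest.approx(2500.0)
        assert out["box_perimeter"] == pytest.approx(200.0)
        assert out["box_aspect_ratio"] == pytest.approx(1.0)

    def test_region_energy_equals_brute_force_sum(self, rng):
        mag = rng.exponential(size=(16, 16))
        box = (2, 7, 3, 9)
        brute = sum(mag[i, j] ** 2 for i in range(2, 7) for j in range(3, 9))
        assert bispectral.region_energy(mag, box) == pytest.approx(brute)

    def test_symmetric_map_has_zero_asymmetry(self, rng):
        m = rng.exponential(size=(12, 12))
        m = m + m.T
        out = bispectral.bispectral_features(self._est(m), None)
        assert out["asymmetry"] == pytest.approx(0.0, abs=1e-12)


class TestTimeFeatures:
    def test_sinusoid_zero_crossings_analytic(self):
        f, dur = 100.0, 1.0
        t = np.arange(int(FS * dur)) / FS
        zc = td.zero_crossing_rate(np.sin(2 * np.pi * f * t), FS) * dur
        assert abs(zc - 2 * f * dur) <= 1

    def test_unit_sinusoid_rms(self):
        t = np.arange(int(FS)) / FS
        out = td.time_features(np.sin(2 * np.pi * 128 * t), FS)
        assert out["rms"] == pytest.approx(1 / np.sqrt(2), abs=1e-3)

    def test_perfectly_periodic_signal_zero_jitter_shimmer(self):
        # integer samples per period so peaks are exactly equispaced
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 128 * t)
        jit, shim = td.jitter_shimmer(x, FS)
        assert jit == pytest.approx(0.0, abs=1e-9)
        assert shim == pytest.approx(0.0, abs=1e-9)

    def test_nhr_low_for_periodic_high_for_noise(self, rng):
        t = np.arange(int(FS)) / FS
        assert td.noise_to_harmonic_ratio(np.sin(2 * np.pi * 128 * t)) < 0.05
        assert td.noise_to_harmonic_ratio(rng.standard_normal(int(FS))) > 0.5


class TestTimeFreqFeatures:
    def test_configured_mfcc_count_contract(self, rng):
        x = rng.standard_normal(int(FS))
        out = tf.mfcc_features(x, FS, n_coeffs=13)
        assert sum(k.endswith("_mean") for k in out) == 13
        assert len(out) == 13 * 3

    def test_scaling_shifts_only_zeroth_mfcc(self, rng):
        """x -> 2x adds a constant to the log-mel spectrum, which the DCT maps
        entirely onto coefficient 0."""
        x = rng.standard_normal(int(FS))
        c1, c2 = tf.mfcc(x, FS), tf.mfcc(2 * x, FS)
        assert np.max(np.abs((c2 - c1)[:, 1:])) < 1e-6
        assert np.all((c2 - c1)[:, 0] > 1.0)

    def test_wavelet_band_energies_parseval(self, rng):
        x = rng.standard_normal(4096)
        e = tf.wavelet_band_energies(x)
        assert abs(e.sum() - np.sum(x**2)) / np.sum(x**2) < 0.01

    def test_tqwt_band_energies_parseval(self, rng):
        x = rng.standard_normal(4096)
        e = tf.tqwt_band_energies(x)
        assert abs(e.sum() - np.sum(x**2)) / np.sum(x**2) < 0.01

    def test_cqt_peak_tracks_tone(self):
        t = np.arange(int(FS)) / FS
        x = np.sin(2 * np.pi * 400 * t)
        e = tf.cqt_band_energies(x, FS, fmin=100.0)
        k = int(np.argmax(e))
        fk = 100.0 * 2 ** (k / 12)
        assert 350 < fk < 460

    def test_hpss_ratio_high_for_tone(self, rng):
        t = np.arange(int(FS)) / FS
        tone = np.sin(2 * np.pi * 500 * t)
        assert tf.hpss_energy_ratio(tone, FS) > 1.0


class TestNonlinearFeatures:
    def test_katz_fd_of_line_is_one(self):
        line = np.linspace(0.0, 3.0, 500)
        assert nonlinear.katz_fd(line) == pytest.approx(1.0, abs=1e-3)

    def test_higuchi_fd_of_white_noise_near_two(self, rng):
        x = rng.standard_normal(4096)
        assert 1.9 <= nonlinear.higuchi_fd(x) <= 2.05

    def test_rqa_determinism_of_sinusoid(self):
        t = np.arange(600) / 600.0
        out = nonlinear.rqa_features(np.sin(2 * np.pi * 5 * t))
        assert out["determinism"] > 0.95

    def test_bundle_finite_or_nan(self, rng):
        out = nonlinear.nonlinear_features(rng.standard_normal(3000), FS)
        for k, v in out.items():
            assert np.isfinite(v) or np.isnan(v), k

    def test_hurst_persistent_vs_noise(self, rng):
        white = rng.standard_normal(4096)
        brown = np.cumsum(white)
        assert nonlinear.hurst_dfa(brown) > nonlinear.hurst_dfa(white) + 0.5


class TestImageFeatures:
    def test_constant_image_glcm(self):
        out = imagefeat.glcm_features(np.ones((32, 32)))
        assert out["glcm_energy"] == pytest.approx(1.0)
        assert out["glcm_contrast"] == pytest.approx(0.0)

    def test_solid_square_morphology(self):
        img = np.zeros((32, 32))
        img[8:24, 8:24] = 1.0
        out = imagefeat.morphology_features(img, 0.5)
        assert out["n_components"] == 1
        assert out["n_holes"] == 0
        assert out["euler_number"] == 1
        assert out["bounding_box_area"] == 16 * 16

    def test_square_annulus_euler_oracle(self):
        """Euler = components - holes: an annulus has 1 component, 1 hole."""
        img = np.zeros((32, 32))
        img[8:24, 8:24] = 1.0
        img[12:20, 12:20] = 0.0
        out = imagefeat.morphology_features(img, 0.5)
        assert out["n_components"] == 1
        assert out["n_holes"] == 1
        assert out["euler_number"] == 0

    def test_pbp_probabilities_in_unit_interval(self, rng):
        out = imagefeat.pbp_features(rng.standard_normal((32, 32)))
        assert 0.0 <= out["pbp_mean"] <= 1.0
        assert 0.0 <= out["pbp_entropy"] <= 1.0


def _phase(samples, sid="S0", route="mouth", ptype="inspiration"):
    return BreathPhase(sid, route, ptype, np.asarray(samples, dtype=float),
                       FS, 20.0, True)


class TestAssembly:
    CFG = FeatureConfig(families=("spectral", "time"))

    def test_single_phase_row_equals_phase_features(self, rng):
        x = rng.standard_normal(int(1.5 * FS))
        table = assemble_feature_table({"S0": [_phase(x)]}, self.CFG)
        direct = phase_features(_phase(x), self.CFG)
        row = table.frame.loc["S0"]
        for name, val in direct.items():
            got = row["mouth_insp_" + name]
            assert got == pytest.approx(val, nan_ok=True)

    def test_duplicated_phase_mean_idempotent(self, rng):
        x = rng.standard_normal(int(1.5 * FS))
        one = assemble_feature_table({"S0": [_phase(x)]}, self.CFG)
        two = assemble_feature_table({"S0": [_phase(x), _phase(x)]}, self.CFG)
        pd.testing.assert_frame_equal(one.frame, two.frame)

    def test_mean_aggregation_arithmetic_oracle(self, rng, monkeypatch):
        import wakebreath.featurebank as fb

        vals = iter([{"f": 1.0}, {"f": 3.0}])
        monkeypatch.setattr(fb, "phase_features", lambda p, c: next(vals))
        x = rng.standard_normal(1024)
        table = fb.assemble_feature_table({"S0": [_phase(x), _phase(x)]}, self.CFG)
        assert table.frame.loc["S0", "mouth_insp_f"] == pytest.approx(2.0)

    def test_determinism_bit_identical(self, rng):
        x = rng.standard_normal(int(1.5 * FS))
        phases = {"S0": [_phase(x)], "S1": [_phase(2 * x, sid="S1")]}
        a = assemble_feature_table(phases, self.CFG)
        b = assemble_feature_table(phases, self.CFG)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_zero_kept_phases_warns_and_masks(self, rng):
        x = rng.standard_normal(int(FS))
        p = _phase(x)
        p.kept = False
        with pytest.warns(UserWarning, match="no kept phases"):
            table = assemble_feature_table({"S0": [p]}, self.CFG)
        assert table.frame.loc["S0"].isna().all()

    def test_scale_free_after_preprocess_normalization(self, rng):
        """Energy-type features are scale-free through the full chain because
        normalization fixes the SD: c*x preprocessed equals x preprocessed."""
        from wakebreath.preprocess import normalize_phase

        x = rng.standard_normal(int(1.5 * FS))
        f1 = phase_features(_phase(normalize_phase(x, FS)), self.CFG)
        f2 = phase_features(_phase(normalize_phase(5.0 * x, FS)), self.CFG)
        for k in f1:
            assert f1[k] == pytest.approx(f2[k], rel=1e-9, nan_ok=True)
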