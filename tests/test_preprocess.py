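"""Baseline removal, normalization and averaging contracts."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import serscreen as ss
from serscreen.preprocess import (
    PreprocessingConfig,
    ProcessedSpectrum,
    average_replicates,
    normalize_area,
    preprocess_cohort,
    preprocess_records,
    read_spectrum_csv,
    samples_to_frame,
    vancouver_baseline,
)
from serscreen.synthetic import SpectralGrid, evaluate_baseline, peak_signal

GRID = SpectralGrid()
X = GRID.wavenumbers()


class TestVancouverBaseline:
    def test_peak_free_polynomial_is_its_own_baseline(self):
        """Without peaks the iterative fit reduces to ordinary least squares,
        which reproduces a lower-degree polynomial exactly."""
        y = 5.0 + 0.001 * X + 1e-6 * X**2 - 1e-10 * X**3
        res = vancouver_baseline(X, y, order=5)
        dynamic_range = y.max() - y.min()
        assert np.max(np.abs(res.baseline - y)) < 1e-6 * dynamic_range
        assert np.max(np.abs(res.corrected)) < 1e-6 * dynamic_range

    def test_all_zero_spectrum(self):
        res = vancouver_baseline(X, np.zeros_like(X))
        assert np.array_equal(res.baseline, np.zeros_like(X))
        assert np.array_equal(res.corrected, np.zeros_like(X))
        assert res.iterations == 1
        assert res.converged

    def test_recovers_known_degree4_baseline_under_14_bands(self):
        """The generator's true baseline is the oracle: the estimate must sit
        within 3% RMS of its range on a noiseless spectrum."""
        cfg = ss.default_config()
        true_baseline = evaluate_baseline(cfg.grid, cfg.baseline_coefficients)
        y = true_baseline + peak_signal(cfg.grid, cfg.peaks)
        res = vancouver_baseline(X, y)
        rms = np.sqrt(np.mean((res.baseline - true_baseline) ** 2))
        assert rms < 0.03 * (true_baseline.max() - true_baseline.min())
        assert res.converged

    def test_peak_recovery_within_5_percent(self):
        """Corrected intensities at the 14 band centers track the true
        baseline-free signal."""
        cfg = ss.default_config()
        true_baseline = evaluate_baseline(cfg.grid, cfg.baseline_coefficients)
        signal = peak_signal(cfg.grid, cfg.peaks)
        res = vancouver_baseline(X, true_baseline + signal)
        for peak in cfg.peaks:
            i = int(np.argmin(np.abs(X - peak.center)))
            assert res.corrected[i] == pytest.approx(signal[i], rel=0.05)

    def test_corrected_plus_baseline_reconstructs_input(self, rng):
        y = 100 + rng.normal(size=X.size)
        res = vancouver_baseline(X, y)
        np.testing.assert_allclose(res.baseline + res.corrected, y, atol=1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(ss.PreprocessingError, match="finite"):
            vancouver_baseline(X, np.full_like(X, np.nan))
        with pytest.raises(ss.PreprocessingError, match="order"):
            vancouver_baseline(X, np.zeros_like(X), order=0)
        with pytest.raises(ss.PreprocessingError, match="points"):
            vancouver_baseline(X[:4], np.zeros(4), order=5)

    def test_non_convergence_flagged_not_raised(self):
        cfg = ss.default_config()
        y = evaluate_baseline(cfg.grid, cfg.baseline_coefficients) + peak_signal(cfg.grid, cfg.peaks)
        res = vancouver_baseline(X, y, max_iterations=2, tolerance=1e-12)
        assert not res.converged
        assert res.iterations == 2


class TestNormalizeArea:
    def test_constant_spectrum_becomes_uniform_density(self):
        out = normalize_area(np.full(GRID.n_points, 42.0), GRID)
        np.testing.assert_allclose(out.intensities, 1.0 / 1400.0, rtol=1e-12)

    def test_scale_invariance(self, rng):
        y = rng.uniform(0.5, 2.0, GRID.n_points)
        a = normalize_area(y, GRID).intensities
        b = normalize_area(17.3 * y, GRID).intensities
        np.testing.assert_allclose(a, b, rtol=1e-12)

    def test_output_integrates_to_one(self, rng):
        y = rng.uniform(0.1, 5.0, GRID.n_points)
        out = normalize_area(y, GRID)
        assert np.trapezoid(out.intensities, X) == pytest.approx(1.0, abs=1e-9)

    def test_zero_area_error_names_spectrum(self):
        with pytest.raises(ss.PreprocessingError, match="sampleX"):
            normalize_area(np.zeros(GRID.n_points), GRID, label="sampleX")

    @settings(max_examples=25, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_normalization_idempotent_on_random_positive_spectra(self, seed):
        y = np.random.default_rng(seed).uniform(0.1, 3.0, GRID.n_points)
        once = normalize_area(y, GRID).intensities
        twice = normalize_area(once, GRID).intensities
        np.testing.assert_allclose(once, twice, rtol=1e-9)


class TestAverageReplicates:
    def test_identical_replicates_idempotent(self, rng):
        spec = ProcessedSpectrum(GRID, rng.uniform(size=GRID.n_points))
        out = average_replicates([spec] * 10, "s1", "Sham")
        np.testing.assert_allclose(out.spectrum.intensities, spec.intensities,
                                   rtol=1e-12)
        assert out.n_replicates_used == 10

    def test_two_point_mean_and_permutation_invariance(self, rng):
        a = ProcessedSpectrum(GRID, rng.uniform(size=GRID.n_points))
        b = ProcessedSpectrum(GRID, rng.uniform(size=GRID.n_points))
        mean_ab = average_replicates([a, b]).spectrum.intensities
        mean_ba = average_replicates([b, a]).spectrum.intensities
        np.testing.assert_allclose(mean_ab, (a.intensities + b.intensities) / 2, rtol=1e-15)
        np.testing.assert_array_equal(mean_ab, mean_ba)

    def test_empty_and_mismatched_grids_rejected(self):
        with pytest.raises(ss.PreprocessingError, match="no replicates"):
            average_replicates([], "s", "g")
        other = SpectralGrid(400, 1800, 4)
        a = ProcessedSpectrum(GRID, np.ones(GRID.n_points))
        b = ProcessedSpectrum(other, np.ones(other.n_points))
        with pytest.raises(ss.PreprocessingError, match="grid"):
            average_replicates([a, b], "s", "g")


class TestPreprocessCohort:
    def test_in_memory_small_cohort(self, small_cohort, small_samples):
        assert len(small_samples) == 12  # 3 groups × 4 samples
        for s in small_samples:
            area = np.trapezoid(s.spectrum.intensities, X)
            assert area == pytest.approx(1.0, abs=1e-9)
            assert s.n_replicates_used == 3

    def test_single_replicate_equals_composed_path(self, small_config):
        rec = ss.generate_cohort(small_config)[0]
        [sample] = preprocess_records([rec])
        res = ss.remove_baseline(rec.spectrum)
        expected = normalize_area(res.corrected, rec.spectrum.grid).intensities
        np.testing.assert_allclose(sample.spectrum.intensities, expected, rtol=1e-12)

    def test_file_roundtrip_matches_in_memory(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_samples_per_group=2, n_replicates=2)
        records = ss.generate_cohort(cfg)
        manifest = ss.write_cohort(records, tmp_path)
        from_files = preprocess_cohort(manifest)
        in_memory = preprocess_records(records)
        assert [s.sample_id for s in from_files] == [s.sample_id for s in in_memory]
        for a, b in zip(from_files, in_memory):
            np.testing.assert_allclose(
                a.spectrum.intensities, b.spectrum.intensities, atol=1e-8
            )

    def test_missing_file_error_names_manifest_row(self, tmp_path, small_config):
        cfg = dataclasses.replace(small_config, n_samples_per_group=2, n_replicates=1)
        manifest = ss.write_cohort(ss.generate_cohort(cfg), tmp_path)
        victim = next((tmp_path / "spectra").iterdir())
        victim.unlink()
        with pytest.raises(ss.PreprocessingError, match=victim.name):
            preprocess_cohort(manifest)

    def test_sample_matrix_frame_shape(self, small_samples):
        df = samples_to_frame(small_samples)
        assert df.shape == (12, 2 + GRID.n_points)
        assert list(df.columns[:2]) == ["sample_id", "group"]

    def test_spectrum_csv_reader_skips_header(self, tmp_path):
        p = tmp_path / "one.csv"
        p.write_text("wavenumber,intensity\n400,1.5\n402,2.5\n")
        x, y = read_spectrum_csv(p)
        np.testing.assert_array_equal(x, [400.0, 402.0])
        np.testing.assert_array_equal(y, [1.5, 2.5])

    def test_normalize_after_average_switch(self, small_config):
        cfg = dataclasses.replace(small_config, n_samples_per_group=2, n_replicates=2)
        records = ss.generate_cohort(cfg)
        late = preprocess_records(records, PreprocessingConfig(normalize_before_average=False))
        for s in late:
            assert np.trapezoid(s.spectrum.intensities, X) == pytest.approx(1.0, abs=1e-9)
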