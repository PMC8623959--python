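"""Band slicing and the eight spectral explanatory variables."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from lrfa.features import (
    FEATURE_NAMES,
    MONOAXIAL_SCHEME,
    POLYAXIAL_SCHEME,
    BandScheme,
    FrequencyBand,
    band_slice,
    build_feature_table,
    extract_band_features,
    get_scheme,
    read_feature_table,
    write_feature_table,
)
from lrfa.preprocess import Spectrum


def _spectrum(freqs, intens):
    return Spectrum(frequencies=np.asarray(freqs, float), intensities=np.asarray(intens, float))


def _moment_oracle(x):
    """Independent transcription of the band shape statistics.

    dispersion: population variance (1/n); kurtosis: bias-adjusted excess;
    skewness: bias-adjusted third moment.
    """
    x = np.asarray(x, float)
    n = len(x)
    xbar = sum(x) / n
    V = sum((xi - xbar) ** 2 for xi in x) / n
    s = (sum((xi - xbar) ** 2 for xi in x) / (n - 1)) ** 0.5
    K = (
        n * (n + 1) / ((n - 1) * (n - 2) * (n - 3)) * sum(((xi - xbar) / s) ** 4 for xi in x)
        - 3 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    )
    S = n / ((n - 1) * (n - 2)) * sum(((xi - xbar) / s) ** 3 for xi in x)
    return V, K, S


class TestPresets:
    def test_monoaxial_has_8_bands_64_variables(self):
        assert len(MONOAXIAL_SCHEME.bands) == 8
        assert MONOAXIAL_SCHEME.n_variables == 64

    def test_polyaxial_has_6_bands_48_variables(self):
        assert len(POLYAXIAL_SCHEME.bands) == 6
        assert POLYAXIAL_SCHEME.n_variables == 48

    def test_polyaxial_band_edges_as_published(self):
        edges = [(b.low, b.high) for b in POLYAXIAL_SCHEME.bands]
        assert edges == [
            (0, 1500),
            (1500, 6500),
            (6500, 11_500),
            (11_500, 15_000),
            (15_000, 25_000),
            (0, 25_000),
        ]

    def test_unknown_preset_rejected(self):
        with pytest.raises(KeyError, match="unknown"):
            get_scheme("biaxial")


class TestBandSlice:
    def test_whole_range_band_returns_everything(self, flat_spectrum):
        sub = band_slice(flat_spectrum, FrequencyBand(0, 10_000))
        assert len(sub.frequencies) == len(flat_spectrum.frequencies)

    def test_half_open_interval_index_arithmetic(self, flat_spectrum):
        # 10-Hz grid: [100, 200) must contain 100, 110, ..., 190
        sub = band_slice(flat_spectrum, FrequencyBand(100, 200))
        np.testing.assert_array_equal(sub.frequencies, np.arange(100.0, 200.0, 10.0))

    def test_band_above_support_rejected(self, flat_spectrum):
        with pytest.raises(ValueError, match="no spectrum bins"):
            band_slice(flat_spectrum, FrequencyBand(5000, 6000))


class TestExtractBandFeatures:
    def test_single_bin_band(self):
        feats = extract_band_features(_spectrum([100.0], [2.0]))
        assert feats["peak_frequency"] == 100.0
        assert feats["peak_intensity"] == 2.0
        assert feats["centroid_frequency"] == 100.0
        assert feats["centroid_intensity"] == 2.0
        assert feats["average_intensity"] == 2.0
        assert feats["dispersion"] == 0.0

    def test_flat_band_has_zero_dispersion_and_degenerate_shape(self):
        spec = _spectrum(np.arange(5) * 10.0, np.ones(5))
        with pytest.warns(RuntimeWarning, match="degenerate"):
            feats = extract_band_features(spec)
        assert feats["dispersion"] == 0.0
        assert feats["kurtosis"] == 0.0
        assert feats["skewness"] == 0.0

    def test_moments_match_independent_oracle(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        feats = extract_band_features(_spectrum(np.arange(6) * 10.0, x))
        V, K, S = _moment_oracle(x)
        assert feats["dispersion"] == pytest.approx(V, abs=1e-12)
        assert feats["kurtosis"] == pytest.approx(K, abs=1e-12)
        assert feats["skewness"] == pytest.approx(S, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_moments_match_scipy_bias_corrected_forms(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.exponential(size=30)
        feats = extract_band_features(_spectrum(np.arange(30) * 5.0, x))
        assert feats["kurtosis"] == pytest.approx(sps.kurtosis(x, bias=False), abs=1e-10)
        assert feats["skewness"] == pytest.approx(sps.skew(x, bias=False), abs=1e-10)
        assert feats["dispersion"] == pytest.approx(np.var(x), abs=1e-12)

    def test_peak_tie_broken_toward_lowest_frequency(self):
        feats = extract_band_features(_spectrum([10.0, 20.0, 30.0], [5.0, 1.0, 5.0]))
        assert feats["peak_frequency"] == 10.0

    def test_symmetric_profile_has_zero_skewness(self):
        freqs = np.arange(8) * 10.0
        intens = np.array([1, 2, 3, 4, 4, 3, 2, 1], float)
        feats = extract_band_features(_spectrum(freqs, intens))
        assert abs(feats["skewness"]) < 1e-9
        assert feats["centroid_frequency"] == pytest.approx(35.0)

    def test_centroid_frequency_stays_inside_the_band(self):
        rng = np.random.default_rng(8)
        freqs = np.arange(50) * 7.0 + 100
        feats = extract_band_features(_spectrum(freqs, rng.random(50)))
        assert freqs[0] <= feats["centroid_frequency"] <= freqs[-1]

    def test_nearest_bin_centroid_intensity_mode(self):
        spec = _spectrum([0.0, 10.0], [1.0, 3.0])
        interp = extract_band_features(spec, "interpolate")
        nearest = extract_band_features(spec, "nearest")
        # centroid at 7.5 Hz: interpolation 2.5, nearest bin (10 Hz) 3.0
        assert interp["centroid_intensity"] == pytest.approx(2.5)
        assert nearest["centroid_intensity"] == pytest.approx(3.0)

    @settings(max_examples=30, derandomize=True)
    @given(
        alpha=st.floats(min_value=1e-3, max_value=1e3),
        seed=st.integers(min_value=0, max_value=2**16),
    )
    def test_scale_equivariance(self, alpha, seed):
        rng = np.random.default_rng(seed)
        freqs = np.arange(12) * 10.0
        x = rng.random(12) + 0.1
        base = extract_band_features(_spectrum(freqs, x))
        scaled = extract_band_features(_spectrum(freqs, alpha * x))
        assert scaled["peak_frequency"] == base["peak_frequency"]
        assert scaled["centroid_frequency"] == pytest.approx(base["centroid_frequency"], rel=1e-9)
        assert scaled["kurtosis"] == pytest.approx(base["kurtosis"], rel=1e-6)
        assert scaled["skewness"] == pytest.approx(base["skewness"], rel=1e-6)
        for name in ("peak_intensity", "centroid_intensity", "average_intensity"):
            assert scaled[name] == pytest.approx(alpha * base[name], rel=1e-9)
        assert scaled["dispersion"] == pytest.approx(alpha**2 * base["dispersion"], rel=1e-9)


class TestBuildFeatureTable:
    def _wide_spectrum(self, seed=0):
        rng = np.random.default_rng(seed)
        freqs = np.arange(0.0, 50_000.0, 10.0)
        return Spectrum(frequencies=freqs, intensities=rng.random(len(freqs)) + 0.01)

    def test_monoaxial_table_has_64_explanatory_columns(self):
        table = build_feature_table([self._wide_spectrum()], [1.0], MONOAXIAL_SCHEME)
        assert table.shape == (1, 65)  # 64 + objective

    def test_polyaxial_table_has_48_explanatory_columns(self):
        table = build_feature_table([self._wide_spectrum()], [1.0], POLYAXIAL_SCHEME)
        assert table.shape == (1, 49)

    def test_single_band_scheme_gives_8_columns(self):
        scheme = BandScheme(bands=(FrequencyBand(0, 1000),))
        table = build_feature_table([self._wide_spectrum()], [0.5], scheme)
        assert table.shape == (1, 9)
        assert list(table.columns[:-1]) == [f"0-1000Hz:{f}" for f in FEATURE_NAMES]

    def test_failure_names_measurement_and_band(self):
        spec = _spectrum([10.0, 20.0], [1.0, 1.0])  # support ends at 20 Hz
        with pytest.raises(ValueError, match=r"m000.*1500-6500Hz|measurement m000"):
            build_feature_table([spec], [1.0], POLYAXIAL_SCHEME)

    def test_missing_objective_rejected(self):
        with pytest.raises(ValueError, match="objective"):
            build_feature_table([self._wide_spectrum()], [float("nan")], POLYAXIAL_SCHEME)

    def test_table_roundtrip_through_text(self, tmp_path):
        table = build_feature_table(
            [self._wide_spectrum(1), self._wide_spectrum(2)], [0.5, 1.5], POLYAXIAL_SCHEME
        )
        path = tmp_path / "features.tsv"
        write_feature_table(table, path)
        back = read_feature_table(path)
        assert list(back.columns) == list(table.columns)
        np.testing.assert_allclose(back.to_numpy(), table.to_numpy(), rtol=1e-10)
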