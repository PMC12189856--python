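"""Feature operators against independent brute-force oracles.

Oracles: direct periodogram + Parseval for Welch totals, cumulative-sum
construction for median frequency, explicit filter-bank convolution for the
DWT level means, O(n^2) template counting for approximate entropy, and
closed forms / direct moment sums for entropy, ZCR, skewness and kurtosis.
"""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from oracles import apen_bruteforce, dwt_oracle

from ctesm import CohortSpec, generate_cohort, window
from ctesm.features import (
    BandDefinition,
    FeatureConfig,
    SpectralEstimate,
    UndefinedFeatureError,
    approximate_entropy,
    band_power,
    band_ratio,
    extract_features,
    kurtosis,
    median_frequency,
    read_feature_table,
    skewness,
    spectral_entropy,
    wavelet_level_means,
    welch_psd,
    write_feature_table,
    zero_crossing_rate,
)

FS = 500.0
ALPHA = BandDefinition("alpha", 8.0, 13.0)
BETA = BandDefinition("beta", 13.0, 30.0)


def tone(freq, duration_s=2.0, fs=FS, amplitude=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


# ---------------------------------------------------------------------------
# Welch PSD


def test_welch_peak_at_tone_frequency():
    est = welch_psd(tone(10.0), FS)
    assert est.frequencies[np.argmax(est.psd)] == pytest.approx(10.0, abs=1.0)


def test_welch_zero_input_zero_psd():
    est = welch_psd(np.zeros(1000), FS)
    np.testing.assert_array_equal(est.psd, 0.0)


def test_welch_parseval_against_direct_periodogram(rng):
    """Welch total power integrates to the signal variance within 10%,
    cross-checked against the raw periodogram's exact Parseval identity."""
    x = rng.standard_normal(4000)
    est = welch_psd(x, FS, segment_s=2.0)
    df = est.frequencies[1] - est.frequencies[0]
    welch_total = est.psd.sum() * df
    # periodogram oracle (rectangular, full length): exact Parseval
    pg = np.abs(np.fft.rfft(x)) ** 2 / (FS * len(x))
    pg[1:-1] *= 2
    pg_total = pg.sum() * (FS / len(x))
    assert pg_total == pytest.approx(np.mean(x**2), rel=1e-10)
    assert welch_total == pytest.approx(np.mean(x**2), rel=0.10)


def test_welch_rejects_short_input():
    with pytest.raises(ValueError, match="shorter"):
        welch_psd(np.ones(100), FS, segment_s=1.0)


# ---------------------------------------------------------------------------
# Band power and ratio


def test_band_power_is_mean_of_constant_psd():
    freqs = np.arange(0.0, 50.0, 0.5)
    est = SpectralEstimate(freqs, np.full_like(freqs, 3.7))
    assert band_power(est, BETA) == pytest.approx(3.7)


def test_tone_concentrates_power_in_its_band():
    est = welch_psd(tone(10.0), FS)
    alpha_p = band_power(est, ALPHA)
    for band in (BandDefinition("delta", 0.5, 4), BandDefinition("theta", 4, 8),
                 BETA, BandDefinition("gamma", 30, 45)):
        assert alpha_p > 50 * band_power(est, band)


def test_empty_band_rejected():
    est = welch_psd(tone(10.0), FS)
    with pytest.raises(ValueError, match="no PSD bins"):
        band_power(est, BandDefinition("subdelta", 0.05, 0.2))


@pytest.mark.parametrize(
    "p_beta, p_alpha, expected", [(2.0, 1.0, 2.0), (0.0, 1.0, 0.0), (1.3, 1.3, 1.0)]
)
def test_band_ratio_values(p_beta, p_alpha, expected):
    ratio, floored = band_ratio(p_beta, p_alpha)
    assert ratio == pytest.approx(expected)
    assert not floored


def test_band_ratio_epsilon_floor_flags():
    ratio, floored = band_ratio(1.0, 0.0, epsilon=1e-12)
    assert floored
    assert ratio == pytest.approx(1e12)


# ---------------------------------------------------------------------------
# Median frequency and spectral entropy


def test_median_frequency_of_tone():
    assert median_frequency(welch_psd(tone(10.0), FS)) == pytest.approx(10.0, abs=1.0)


def test_median_frequency_symmetric_psd_cumsum_oracle():
    freqs = np.arange(0.0, 41.0)
    psd = np.exp(-((freqs - 20.0) ** 2) / 50.0)  # symmetric about 20 Hz
    est = SpectralEstimate(freqs, psd)
    # independent cumulative-sum oracle
    cum = np.cumsum(psd)
    oracle = freqs[np.searchsorted(cum, 0.5 * cum[-1])]
    assert median_frequency(est) == oracle
    assert abs(median_frequency(est) - 20.0) <= 1.0


def test_median_frequency_flat_spectrum_is_half_nyquist():
    freqs = np.linspace(0, 250, 501)
    est = SpectralEstimate(freqs, np.ones_like(freqs))
    assert median_frequency(est) == pytest.approx(125.0, abs=1.0)


def test_median_frequency_zero_power_undefined():
    est = SpectralEstimate(np.arange(5.0), np.zeros(5))
    with pytest.raises(UndefinedFeatureError):
        median_frequency(est)


def test_spectral_entropy_closed_forms():
    freqs = np.arange(8.0)
    one_bin = np.zeros(8); one_bin[3] = 5.0
    assert spectral_entropy(SpectralEstimate(freqs, one_bin)) == pytest.approx(0.0)
    uniform = np.ones(8)
    assert spectral_entropy(SpectralEstimate(freqs, uniform)) == pytest.approx(3.0)
    two = np.zeros(8); two[2] = two[5] = 1.0
    assert spectral_entropy(SpectralEstimate(freqs, two)) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Wavelet level means: explicit filter-bank convolution oracle


@pytest.mark.parametrize("wavelet_name", ["db4", "db2", "sym4"])
def test_wavelet_level_means_match_filter_bank_oracle(rng, wavelet_name):
    x = rng.standard_normal(600)
    levels = 4
    approx = x
    oracle_details = []
    for _ in range(levels):
        approx, detail = dwt_oracle(approx, wavelet_name)
        oracle_details.append(np.abs(detail).mean())
    expected = np.array(oracle_details + [np.abs(approx).mean()])
    got = wavelet_level_means(x, wavelet_name, levels)
    np.testing.assert_allclose(got, expected, atol=1e-10)


def test_wavelet_impulse_against_oracle(rng):
    x = np.zeros(256); x[100] = 1.0
    a, d = dwt_oracle(x, "db4")
    got = wavelet_level_means(x, "db4", 1)
    np.testing.assert_allclose(got, [np.abs(d).mean(), np.abs(a).mean()], atol=1e-12)


def test_wavelet_zero_input_and_homogeneity(rng):
    assert np.all(wavelet_level_means(np.zeros(512)) == 0.0)
    x = rng.standard_normal(512)
    np.testing.assert_allclose(
        wavelet_level_means(3.5 * x), 3.5 * wavelet_level_means(x), rtol=1e-12
    )


def test_wavelet_depth_too_large_rejected():
    with pytest.raises(ValueError, match="levels"):
        wavelet_level_means(np.ones(32), "db4", 5)


# ---------------------------------------------------------------------------
# Approximate entropy: O(n^2) brute-force oracle


@pytest.mark.parametrize("n", [60, 120, 200])
def test_apen_equals_bruteforce_oracle(rng, n):
    x = rng.standard_normal(n)
    value, degenerate = approximate_entropy(x, m=2, r=0.2)
    assert not degenerate
    assert value == pytest.approx(apen_bruteforce(x, 2, 0.2), abs=1e-10)


def test_apen_constant_input_is_zero_and_flagged():
    value, degenerate = approximate_entropy(np.full(100, 2.5))
    assert value == 0.0 and degenerate


def test_apen_periodic_below_white_noise(rng):
    periodic = np.tile([0.0, 1.0, 0.5, -1.0], 25)
    noise = rng.standard_normal(100)
    ap_periodic, _ = approximate_entropy(periodic)
    ap_noise, _ = approximate_entropy(noise)
    assert ap_periodic < ap_noise
    assert ap_periodic == pytest.approx(apen_bruteforce(periodic, 2, 0.2), abs=1e-10)


def test_apen_amplitude_entropy_variant(rng):
    """The histogram-entropy alternative: closed form for a two-level signal
    occupying two bins equally is ln 2."""
    x = np.tile([0.0, 1.0], 50)
    value, _ = approximate_entropy(x, method="amplitude")
    assert value == pytest.approx(np.log(2))


def test_apen_input_validation():
    with pytest.raises(ValueError):
        approximate_entropy(np.ones(3), m=2)
    with pytest.raises(ValueError):
        approximate_entropy(np.ones(50), r=0.0)


# ---------------------------------------------------------------------------
# Moments and ZCR


def test_skewness_symmetric_is_zero():
    assert skewness(np.array([-1.0, 0.0, 1.0])) == pytest.approx(0.0)


def test_alternating_signal_has_unit_zcr():
    assert zero_crossing_rate(np.array([1.0, -1.0, 1.0, -1.0])) == 1.0


def test_population_moment_convention_against_direct_sums(rng):
    """Moments divide by N (not N-1) and kurtosis keeps the +3 offset:
    direct-sum oracle and a large-n Gaussian check."""
    x = rng.standard_normal(41)  # odd n makes N vs N-1 detectable
    mu = x.sum() / len(x)
    sd = np.sqrt(((x - mu) ** 2).sum() / len(x))
    assert skewness(x) == pytest.approx(((x - mu) ** 3).sum() / len(x) / sd**3, rel=1e-12)
    assert kurtosis(x) == pytest.approx(((x - mu) ** 4).sum() / len(x) / sd**4, rel=1e-12)
    big = rng.standard_normal(200_000)
    assert kurtosis(big) == pytest.approx(3.0, abs=0.1)
    assert skewness(big) == pytest.approx(0.0, abs=0.05)


def test_zero_variance_moments_undefined():
    with pytest.raises(UndefinedFeatureError):
        skewness(np.ones(10))
    with pytest.raises(UndefinedFeatureError):
        kurtosis(np.ones(10))


def test_zcr_of_random_walk_vs_direct_count(rng):
    x = np.cumsum(rng.standard_normal(500))
    direct = np.sum(x[1:] * x[:-1] < 0) / (len(x) - 1)
    assert zero_crossing_rate(x) == pytest.approx(direct)


# ---------------------------------------------------------------------------
# Assembly


def test_extract_features_shapes_and_determinism(tiny_cohort, tiny_features):
    spec, recs = tiny_cohort
    frameset = window(recs[0])
    instances = extract_features(frameset)
    assert len(instances) == frameset.n_frames
    n_feat = len(FeatureConfig().feature_names())
    for inst in instances:
        assert inst.matrix.shape == (spec.n_channels, n_feat)
        assert np.all(np.isfinite(inst.matrix))
        assert inst.label == recs[0].label
    again = extract_features(frameset)
    np.testing.assert_array_equal(instances[0].matrix, again[0].matrix)


def test_channel_permutation_permutes_rows(tiny_cohort):
    from dataclasses import replace

    _, recs = tiny_cohort
    rec = recs[0]
    perm = np.array([3, 0, 2, 1, 7, 5, 6, 4])
    permuted = replace(
        rec,
        signal=rec.signal[:, perm],
        channel_names=tuple(rec.channel_names[i] for i in perm),
    )
    base = extract_features(window(rec))[0].matrix
    shuffled = extract_features(window(permuted))[0].matrix
    np.testing.assert_allclose(shuffled, base[perm], rtol=1e-12)


def test_degenerate_channel_gets_sentinel_and_flags():
    from ctesm.synthetic import Recording

    sig = np.zeros((1000, 2))
    sig[:, 1] = tone(10.0, 2.0)
    rec = Recording(signal=sig, sampling_rate_hz=FS, label="HC", subject_id="s0")
    inst = extract_features(window(rec))[0]
    flagged = {name for ch, name in inst.flags if ch == 0}
    assert {"median_frequency", "spectral_entropy", "skewness", "kurtosis"} <= flagged
    names = list(inst.feature_names)
    assert inst.matrix[0, names.index("spectral_entropy")] == 0.0
    assert np.all(np.isfinite(inst.matrix))


@settings(max_examples=15, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=0.01, max_value=100.0))
def test_amplitude_scale_equivariance(scale):
    """Scaling a frame by c > 0: band powers x c^2, wavelet means x c, and
    ratio / median frequency / entropies / moments / ZCR unchanged."""
    x = np.sin(2 * np.pi * 11.0 * np.arange(1000) / FS) + 0.3 * np.sin(
        2 * np.pi * 21.0 * np.arange(1000) / FS + 1.0
    )
    est1, est2 = welch_psd(x, FS), welch_psd(scale * x, FS)
    for band in (ALPHA, BETA):
        assert band_power(est2, band) == pytest.approx(
            scale**2 * band_power(est1, band), rel=1e-9
        )
    assert band_ratio(band_power(est2, BETA), band_power(est2, ALPHA))[0] == pytest.approx(
        band_ratio(band_power(est1, BETA), band_power(est1, ALPHA))[0], rel=1e-9
    )
    assert median_frequency(est2) == median_frequency(est1)
    assert spectral_entropy(est2) == pytest.approx(spectral_entropy(est1), abs=1e-9)
    np.testing.assert_allclose(
        wavelet_level_means(scale * x), scale * wavelet_level_means(x), rtol=1e-9
    )
    assert approximate_entropy(scale * x)[0] == pytest.approx(
        approximate_entropy(x)[0], abs=1e-9
    )
    assert skewness(scale * x) == pytest.approx(skewness(x), abs=1e-9)
    assert kurtosis(scale * x) == pytest.approx(kurtosis(x), abs=1e-9)
    assert zero_crossing_rate(scale * x) == zero_crossing_rate(x)


def test_feature_ranges(tiny_features):
    names = list(tiny_features[0].feature_names)
    power_cols = [names.index(f"power_{b}") for b in ("delta", "theta", "alpha", "beta", "gamma")]
    ent = names.index("spectral_entropy")
    zcr_col = names.index("zcr")
    n_bins = len(welch_psd(np.ones(1000), FS).frequencies)
    for inst in tiny_features:
        assert np.all(inst.matrix[:, power_cols] >= 0)
        assert np.all(inst.matrix[:, ent] >= 0)
        assert np.all(inst.matrix[:, ent] <= np.log2(n_bins))
        assert np.all((inst.matrix[:, zcr_col] >= 0) & (inst.matrix[:, zcr_col] <= 1))


def test_beta_features_separate_classes(separable_features):
    """With a beta amplitude multiplier of 2 for PD, subject-mean beta power
    and beta/alpha ratio separate classes (one-sided t-test p < 0.01)."""
    names = list(separable_features[0].feature_names)
    by_subject = {}
    for inst in separable_features:
        by_subject.setdefault((inst.subject_id, inst.label), []).append(inst.matrix)
    for feature in ("power_beta", "beta_alpha_ratio"):
        col = names.index(feature)
        pd_means, hc_means = [], []
        for (sid, label), mats in by_subject.items():
            val = np.mean([m[:, col].mean() for m in mats])
            (pd_means if label == "PD" else hc_means).append(val)
        t, p = stats.ttest_ind(pd_means, hc_means, alternative="greater")
        assert p < 0.01, f"{feature}: one-sided p={p}"


def test_feature_table_round_trip(tmp_path, tiny_features):
    path = write_feature_table(tiny_features[:5], tmp_path / "features.csv")
    back = read_feature_table(path)
    assert len(back) == 5
    for a, b in zip(tiny_features[:5], back):
        assert a.subject_id == b.subject_id and a.frame_index == b.frame_index
        assert a.label == b.label and a.feature_names == b.feature_names
        np.testing.assert_allclose(b.matrix, a.matrix, rtol=1e-12)
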