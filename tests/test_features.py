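"""Feature operations: analytic identities, Parseval checks, oracle match."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import signal as sps

from cciqeeg import features as feat
from cciqeeg.config import BAND_NAMES, BIN_FREQS, N_BINS
from cciqeeg.features import BinnedSpectrum
from cciqeeg.preprocess import Epoch, bandpass
from cciqeeg.synth import generate_recording, strain_presets
from cciqeeg.preprocess import extract_epochs

import oracles
from conftest import make_regime
from cciqeeg.synth import synthesize_pair

FS = 1024.0


def _spectrum(power) -> BinnedSpectrum:
    return BinnedSpectrum(freqs=BIN_FREQS.copy(), power=np.asarray(power, float))


# --- spectral entropy -------------------------------------------------------

def test_entropy_flat_spectrum_is_log_nbins():
    assert feat.spectral_entropy(_spectrum(np.ones(64))) == pytest.approx(np.log(64), abs=1e-12)


def test_entropy_single_bin_is_zero():
    p = np.zeros(64)
    p[10] = 3.0
    assert feat.spectral_entropy(_spectrum(p)) == 0.0


def test_entropy_two_equal_bins_is_log_two():
    p = np.zeros(64)
    p[[3, 40]] = 1.5
    assert feat.spectral_entropy(_spectrum(p)) == pytest.approx(np.log(2), abs=1e-12)


def test_entropy_rejects_zero_spectrum():
    with pytest.raises(ValueError):
        feat.spectral_entropy(_spectrum(np.zeros(64)))


@given(hnp.arrays(np.float64, 64, elements=st.floats(0.0, 1e3)))
def test_entropy_bounded_for_any_spectrum(power):
    if power.sum() == 0:
        return
    h = feat.spectral_entropy(_spectrum(power))
    assert -1e-12 <= h <= np.log(64) + 1e-12


# --- normalization / power -------------------------------------------------

def test_normalization_arithmetic_and_bookkeeping():
    norm = feat.normalize_to_baseline(_spectrum(np.full(64, 0.5)), 2.0)
    assert np.allclose(norm.power, 0.25)
    assert norm.normalized and norm.norm_constant == 2.0


def test_self_normalized_spectrum_has_unit_total():
    spec = _spectrum(np.random.default_rng(0).uniform(0.1, 2.0, 64))
    norm = feat.normalize_to_baseline(spec, feat.total_power(spec))
    assert norm.power.sum() * 0.5 == pytest.approx(1.0, abs=1e-12)


def test_normalization_rejects_nonpositive_baseline():
    with pytest.raises(ValueError):
        feat.normalize_to_baseline(_spectrum(np.ones(64)), 0.0)


def test_total_power_flat_spectrum():
    assert feat.total_power(_spectrum(np.full(64, 2.0))) == pytest.approx(64.0)
    assert feat.total_power(_spectrum(np.zeros(64))) == 0.0


def test_total_power_rejects_normalized_input():
    norm = feat.normalize_to_baseline(_spectrum(np.ones(64)), 1.0)
    with pytest.raises(ValueError):
        feat.total_power(norm)


def test_total_power_matches_periodogram_parseval_oracle(rng):
    # Parseval check against a direct periodogram of the same data,
    # integrated over the same 0.5-32 Hz range (Hamming normalization)
    x = rng.standard_normal(int(60 * FS))
    tp = feat.total_power(feat.psd(x, FS))
    n = len(x)
    spec = np.abs(np.fft.rfft(x - x.mean())) ** 2 / (FS * n)
    spec[1:-1] *= 2.0  # one-sided density
    freqs = np.fft.rfftfreq(n, 1.0 / FS)
    inband = (freqs >= 0.25) & (freqs < 32.25)  # the 64 bins' support
    oracle_power = spec[inband].sum() * (freqs[1] - freqs[0])
    assert tp == pytest.approx(oracle_power, rel=0.05)


# --- percent band power -----------------------------------------------------

def test_flat_spectrum_band_percentages():
    spec = _spectrum(np.ones(64))
    assert feat.pct_band_power(spec, "delta") == pytest.approx(12.5)
    assert feat.pct_band_power(spec, "theta") == pytest.approx(12.5)
    assert feat.pct_band_power(spec, "alpha") == pytest.approx(15.625)
    assert feat.pct_band_power(spec, "beta") == pytest.approx(59.375)


def test_single_bin_spectrum_band_percentages():
    p = np.zeros(64)
    p[BIN_FREQS == 20.0] = 1.0
    spec = _spectrum(p)
    assert feat.pct_band_power(spec, "beta") == 100.0
    assert feat.pct_band_power(spec, "delta") == 0.0


@given(hnp.arrays(np.float64, 64, elements=st.floats(1e-6, 1e3)))
def test_band_percentages_partition_to_100(power):
    spec = _spectrum(power)
    total = sum(feat.pct_band_power(spec, b) for b in BAND_NAMES)
    assert total == pytest.approx(100.0, abs=1e-6)


# --- psd --------------------------------------------------------------------

def test_psd_peak_at_sinusoid_frequency():
    t = np.arange(int(60 * FS)) / FS
    spec = feat.psd(np.sin(2 * np.pi * 10.0 * t), FS)
    assert spec.freqs[np.argmax(spec.power)] == 10.0


def test_psd_zero_signal_gives_zero_bins():
    spec = feat.psd(np.zeros(2048), FS)
    assert np.all(spec.power == 0.0)


def test_psd_requires_one_window():
    with pytest.raises(ValueError):
        feat.psd(np.zeros(511), FS)


def test_psd_has_exactly_64_bins(ppks_epochs):
    spec = feat.psd(ppks_epochs["baseline"].left, FS)
    assert len(spec.power) == N_BINS
    assert spec.freqs[0] == 0.5 and spec.freqs[-1] == 32.0


def test_psd_matches_direct_dft_oracle(rng):
    # two-window toy signal, 1e-8 relative agreement
    n = 512 + 384
    x = rng.standard_normal(n)
    window = sps.get_window("hamming", 512)
    ours = feat.psd(x, FS).power
    ref = oracles.psd_oracle(x, FS, window)
    assert np.allclose(ours, ref, rtol=1e-8, atol=1e-12)


# --- coherence --------------------------------------------------------------

def test_coherence_of_signal_with_itself_is_one(rng):
    x = rng.standard_normal(4096)
    cs = feat.coherence(x, x, FS)
    assert np.all(np.abs(cs.cxy - 1.0) < 1e-10)


def test_coherence_scale_invariance(rng):
    x = rng.standard_normal(4096)
    cs = feat.coherence(x, 3.0 * x, FS)
    assert np.all(np.abs(cs.cxy - 1.0) < 1e-10)


def test_coherence_requires_two_windows(rng):
    with pytest.raises(ValueError):
        feat.coherence(rng.standard_normal(895), rng.standard_normal(895), FS)


def test_coherence_bounded_everywhere(ppks_epochs):
    ep = ppks_epochs["post_0.5"]
    cs = feat.coherence(ep.left, ep.right, FS)
    assert np.all(cs.cxy >= 0.0) and np.all(cs.cxy <= 1.0)


def test_independent_noise_coherence_below_null_threshold():
    # Monte-Carlo null: 60 s independent white channels; the observed mean
    # must sit below the null's 95th percentile estimated from replicates
    null_means = []
    for seed in range(200):
        r = np.random.default_rng(40_000 + seed)
        cs = feat.coherence(r.standard_normal(61440), r.standard_normal(61440), FS)
        null_means.append(cs.cxy.mean())
    threshold = np.quantile(null_means, 0.95)
    r = np.random.default_rng(99)
    observed = feat.coherence(
        r.standard_normal(61440), r.standard_normal(61440), FS
    ).cxy.mean()
    assert observed < threshold
    assert threshold < 0.05  # the null level itself is small at this length


def test_coherence_matches_direct_dft_oracle(rng):
    n = 512 + 384
    x = rng.standard_normal(n)
    y = 0.6 * x + 0.8 * rng.standard_normal(n)
    window = sps.get_window("hamming", 512)
    ours = feat.coherence(x, y, FS).cxy
    ref = oracles.coherence_oracle(x, y, FS, window)
    assert np.allclose(ours, ref, rtol=1e-8, atol=1e-12)


# --- kurtosis / line length -------------------------------------------------

def test_kurtosis_alternating_sequence_is_one():
    x = np.tile([1.0, -1.0], 500)
    assert feat.kurtosis(x) == pytest.approx(1.0, abs=1e-12)


def test_kurtosis_gaussian_large_sample(rng):
    x = rng.standard_normal(1_000_000)
    assert feat.kurtosis(x) == pytest.approx(3.0, abs=0.1)


def test_kurtosis_single_outlier_exceeds_gaussian(rng):
    x = rng.standard_normal(61440)
    x[100] = 20.0 * x.std()
    assert feat.kurtosis(x) > 3.0


def test_kurtosis_rejects_constant_signal():
    with pytest.raises(ValueError):
        feat.kurtosis(np.full(100, 2.5))


def test_line_length_constant_signal():
    assert feat.line_length(np.full(100, 7.0)) == pytest.approx(99.0)


def test_line_length_unit_ramp():
    assert feat.line_length(np.arange(100.0)) == pytest.approx(99.0 * np.sqrt(2.0))


def test_line_length_alternating():
    a = 2.0
    x = np.tile([a, -a], 50)
    assert feat.line_length(x) == pytest.approx(99.0 * np.sqrt(1.0 + 4.0 * a * a))


def test_line_length_amplitude_variant():
    assert feat.line_length_amplitude(np.arange(100.0)) == pytest.approx(99.0)
    with pytest.raises(ValueError):
        feat.line_length(np.array([1.0]))


# --- feature assembly -------------------------------------------------------

def test_feature_vector_has_the_19_canonical_features(ppks_epochs):
    fv = feat.build_features(ppks_epochs["baseline"], "right")
    for name in feat.FEATURE_NAMES:
        assert name in fv
    assert len(feat.FEATURE_NAMES) == 19


def test_delta_only_signal_gives_full_delta_share(rng):
    gains = {b: 0.0 for b in BAND_NAMES}
    gains["delta"] = 1.0
    p = make_regime(band_gains=gains)
    left, right = synthesize_pair(p, p, 61440, FS, rng)
    ep = Epoch(label="baseline", left=left, right=right, fs=FS)
    fv = feat.build_features(ep, "right")
    # the 512-sample window's ~2 Hz mainlobe smears a little delta power
    # into adjacent theta bins, so the share saturates near (not at) 100%
    assert fv["delta_pct_ipsi"] > 90.0
    assert fv["delta_pct_contra"] > 90.0
    assert fv["delta_pct_ipsi"] + fv["theta_pct_ipsi"] > 99.0
    assert fv["beta_pct_ipsi"] < 1.0


def test_swapping_ipsilateral_flag_relabels_without_changing_values(ppks_epochs):
    ep = ppks_epochs["post_0.5"]
    right_ipsi = feat.build_features(ep, "right")
    left_ipsi = feat.build_features(ep, "left")
    for name in ("entropy", "kurtosis", "line_length"):
        assert right_ipsi[f"{name}_ipsi"] == left_ipsi[f"{name}_contra"]
        assert right_ipsi[f"{name}_contra"] == left_ipsi[f"{name}_ipsi"]
    for b in BAND_NAMES:
        assert right_ipsi[f"coh_{b}"] == left_ipsi[f"coh_{b}"]
    assert right_ipsi["total_power"] == left_ipsi["total_power"]


def test_resistant_strain_ipsilateral_kurtosis_rises_after_impact():
    # simulation oracle: the injected transients raise the fourth moment in
    # nearly every draw
    preset = strain_presets()["PPKR"]
    hits = 0
    n_seeds = 10
    for seed in range(n_seeds):
        spec = dataclasses.replace(preset, seed=31_000 + seed)
        eps = extract_epochs(generate_recording(spec))
        base = feat.build_features(eps["baseline"], "right")["kurtosis_ipsi"]
        post = feat.build_features(eps["post_0.5"], "right")["kurtosis_ipsi"]
        hits += post > base
    assert hits >= 9
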