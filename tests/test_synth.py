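"""Generator contracts: determinism, parameter recovery, preset structure."""

import dataclasses

import numpy as np
import pytest

from cciqeeg import features as feat
from cciqeeg.config import BAND_NAMES
from cciqeeg.synth import (
    RegimeParams,
    SubjectSpec,
    cohort_manifest,
    cohort_specs,
    generate_cohort,
    generate_recording,
    strain_presets,
    synthesize_pair,
)

from conftest import make_regime


def test_identical_seed_gives_bit_identical_recordings():
    spec = dataclasses.replace(strain_presets()["SD"], seed=77)
    a = generate_recording(spec)
    b = generate_recording(spec)
    assert np.array_equal(a.left, b.left)
    assert np.array_equal(a.right, b.right)
    assert a.cci_sample == b.cci_sample


def test_impact_artifact_written_at_cci_sample(ppks_recording):
    rec = ppks_recording
    n_art = int(round(0.5 * rec.fs))
    assert np.all(rec.left[rec.cci_sample : rec.cci_sample + n_art] == 1000.0)
    assert np.all(rec.right[rec.cci_sample : rec.cci_sample + n_art] == 1000.0)


@pytest.mark.parametrize("bad", [
    dict(fs=60.0),                      # below 2 x 32 Hz
    dict(cci_time=50.0),                # < 90 s of baseline
    dict(duration=500.0),               # < 16 min post
])
def test_invalid_specs_rejected(bad):
    preset = strain_presets()["PPKS"]
    with pytest.raises(ValueError):
        dataclasses.replace(preset, **bad)


def test_regime_params_validation():
    with pytest.raises(ValueError):
        make_regime(am_depth=1.5)
    with pytest.raises(ValueError):
        make_regime(spike_rate=-1.0)
    with pytest.raises(ValueError):
        make_regime(rms=0.0)
    with pytest.raises(ValueError):
        make_regime(shared_fraction={b: 2.0 for b in BAND_NAMES})


def test_fully_shared_sources_give_unit_coherence(rng):
    p = make_regime(shared_fraction={b: 1.0 for b in BAND_NAMES})
    left, right = synthesize_pair(p, p, 61440, 1024.0, rng)
    cs = feat.coherence(left, right, 1024.0)
    assert cs.cxy.min() > 0.99


def test_independent_sources_give_small_coherence():
    # Monte-Carlo across seeds: with no shared source the estimated band
    # coherence stays near the estimator's null bias level.
    p = make_regime(shared_fraction={b: 0.0 for b in BAND_NAMES})
    means = []
    for seed in range(8):
        left, right = synthesize_pair(p, p, 2 * 61440, 1024.0, np.random.default_rng(seed))
        cs = feat.coherence(left, right, 1024.0)
        means.append(cs.cxy.mean())
    assert np.mean(means) < 0.05


def test_coherence_monotone_in_shared_fraction():
    grid = [0.0, 0.25, 0.5, 0.75, 1.0]
    est = []
    for s in grid:
        p = make_regime(shared_fraction={b: s for b in BAND_NAMES})
        vals = []
        for seed in range(4):
            left, right = synthesize_pair(p, p, 61440, 1024.0, np.random.default_rng(seed))
            cs = feat.coherence(left, right, 1024.0)
            vals.append(cs.cxy.mean())
        est.append(np.mean(vals))
    assert all(b >= a for a, b in zip(est, est[1:]))


def test_band_gain_increases_band_power_share(rng):
    shares = []
    for gain in (0.5, 1.0, 2.0, 4.0):
        gains = {b: 1.0 for b in BAND_NAMES}
        gains["theta"] = gain
        p = make_regime(band_gains=gains)
        left, _ = synthesize_pair(p, p, 61440, 1024.0, np.random.default_rng(5))
        shares.append(feat.pct_band_power(feat.psd(left), "theta"))
    assert all(b > a for a, b in zip(shares, shares[1:]))


def test_amplitude_modulation_lowers_spectral_entropy():
    diffs = []
    for seed in range(20):
        flat = make_regime(am_depth=0.0)
        mod = make_regime(am_depth=0.9)
        l0, _ = synthesize_pair(flat, flat, 61440, 1024.0, np.random.default_rng(seed))
        l1, _ = synthesize_pair(mod, mod, 61440, 1024.0, np.random.default_rng(seed))
        diffs.append(
            feat.spectral_entropy(feat.psd(l1)) - feat.spectral_entropy(feat.psd(l0))
        )
    assert np.mean(diffs) < 0


def test_sparse_transients_raise_kurtosis():
    hits = 0
    for seed in range(20):
        p = make_regime(spike_rate=0.5, spike_amp=8.0)
        left, _ = synthesize_pair(p, p, 61440, 1024.0, np.random.default_rng(seed))
        hits += feat.kurtosis(left) > 3.0
    assert hits >= 19  # >= 95% of seeds


def test_strain_presets_encode_required_structure():
    pres = strain_presets()
    ppks, sd, ppkr = pres["PPKS"], pres["SD"], pres["PPKR"]
    # kindling-resistant baseline: slow-wave excess, faster-band deficit
    assert ppkr.baseline["left"].band_gains["delta"] > ppks.baseline["left"].band_gains["delta"]
    for band in ("theta", "alpha", "beta"):
        assert ppkr.baseline["left"].band_gains[band] < ppks.baseline["left"].band_gains[band]
        assert ppkr.baseline["left"].band_gains[band] < sd.baseline["left"].band_gains[band]
    # susceptible strain keeps its spectral shape after injury
    assert ppks.post["left"].band_gains == ppks.baseline["left"].band_gains
    # non-susceptible strains lose broadband power
    for strain in (sd, ppkr):
        for band in BAND_NAMES:
            assert strain.post["left"].band_gains[band] < strain.baseline["left"].band_gains[band]
    # post-injury delta coherence ordering PPKS < SD < PPKR
    assert (
        ppks.post["left"].shared_fraction["delta"]
        < sd.post["left"].shared_fraction["delta"]
        < ppkr.post["left"].shared_fraction["delta"]
    )
    # ipsilateral-only entropy mechanism in PPKS/SD, transients in PPKR only
    for strain in (ppks, sd):
        assert strain.post["right"].am_depth > strain.post["left"].am_depth
        assert strain.post["right"].spike_rate == 0.0
    assert ppkr.post["right"].spike_rate > 0.0
    assert ppkr.post["right"].am_depth == 0.0


def test_cohort_counts_and_manifest_determinism():
    recs, manifest = generate_cohort(2, seed=7)
    assert len(recs) == 6
    assert len(manifest) == 6
    assert set(manifest["strain"]) == {"PPKS", "SD", "PPKR"}
    manifest2 = cohort_manifest(cohort_specs(2, seed=7))
    assert manifest.equals(manifest2)
    with pytest.raises(ValueError):
        cohort_specs(0, seed=7)


def test_subject_seeds_independent_of_cohort_size():
    small = {s.subject_id: s.seed for s in cohort_specs(2, seed=3)}
    large = {s.subject_id: s.seed for s in cohort_specs(4, seed=3)}
    for sid, seed in small.items():
        assert large[sid] == seed
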