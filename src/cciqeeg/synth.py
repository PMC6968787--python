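"""Synthetic two-channel epidural EEG with a controlled injury-time regime change.

The generator produces surrogate recordings whose *measured* summaries —
binned power spectrum, interhemispheric magnitude-squared coherence,
spectral entropy, kurtosis — can be dialed independently, so the whole
downstream analysis chain is testable without animal data.

Signal model
------------
Each hemisphere channel is a sum of four band-limited Gaussian noise
components (delta/theta/alpha/beta) with a 1/f^a spectral envelope.  Per
band, the two channels mix a *common* source and *private* sources,

    ch_i = sqrt(s) * common + sqrt(1 - s) * private_i,

so the shared variance fraction ``s`` controls interhemispheric coherence
in that band (zero lag; the expected magnitude-squared coherence is s^2).
A burst-like envelope with depth ``am_depth`` gates the supra-delta
components (emulating post-impact suppression of faster activity), which
concentrates spectral mass at low frequencies and lowers spectral entropy.
Sparse high-amplitude transients injected at a Poisson rate raise kurtosis.
Parameters switch from a baseline regime to a post-injury regime at the
impact sample, where a saturating square artifact is also written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .config import BAND_NAMES, FS_DEFAULT

STRAINS = ("PPKS", "SD", "PPKR")

#: Contiguous band edges used for signal synthesis, Hz.
SYNTH_BAND_EDGES = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 32.0),
}

#: Impact artifact: saturating square pulse written on both channels.
ARTIFACT_DURATION_S = 0.5
ARTIFACT_AMPLITUDE_UV = 1000.0

#: Width of one injected transient, seconds.
SPIKE_WIDTH_S = 0.04

# Epoch-scheme span requirements (seconds before/after the impact) that a
# recording must satisfy so that all five 60 s epochs exist.
MIN_PRE_S = 90.0
MIN_POST_S = 960.0


@dataclass(frozen=True)
class RegimeParams:
    """Generator parameters for one channel within one regime.

    psd_exponent : 1/f slope ``a`` of the spectral envelope (dimensionless).
    band_gains : per-band multiplicative power gain (dimensionless).
    shared_fraction : per-band fraction of variance drawn from the source
        common to both channels, in [0, 1]; must match the paired channel.
    am_depth : burst-envelope depth in [0, 1] applied to supra-delta
        components (0 = no gating; larger values lower spectral entropy).
    spike_rate : Poisson rate of additive sparse transients, events/s.
    spike_amp : transient amplitude in units of the channel SD.
    rms : target channel RMS in microvolts for unit band gains.
    """

    psd_exponent: float = 1.0
    band_gains: dict[str, float] = field(
        default_factory=lambda: {b: 1.0 for b in BAND_NAMES}
    )
    shared_fraction: dict[str, float] = field(
        default_factory=lambda: {b: 0.5 for b in BAND_NAMES}
    )
    am_depth: float = 0.0
    spike_rate: float = 0.0
    spike_amp: float = 8.0
    rms: float = 50.0

    def __post_init__(self) -> None:
        for b in BAND_NAMES:
            if self.band_gains.get(b, 0.0) < 0:
                raise ValueError(f"band_gains[{b}] must be >= 0")
            s = self.shared_fraction.get(b)
            if s is None or not 0.0 <= s <= 1.0:
                raise ValueError(f"shared_fraction[{b}] must lie in [0, 1]")
        if not 0.0 <= self.am_depth <= 1.0:
            raise ValueError("am_depth must lie in [0, 1]")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        if self.rms <= 0:
            raise ValueError("rms must be > 0")


@dataclass(frozen=True)
class SubjectSpec:
    """Full ground-truth description of one synthetic subject."""

    strain: str
    sex: str
    baseline: dict[str, RegimeParams]  # keys "left", "right"
    post: dict[str, RegimeParams]
    cci_time: float
    duration: float
    fs: float = FS_DEFAULT
    seed: int = 0
    subject_id: str = ""

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"unknown strain {self.strain!r}")
        for regime in (self.baseline, self.post):
            if set(regime) != {"left", "right"}:
                raise ValueError("regime params must map 'left' and 'right'")
            lf, rt = regime["left"], regime["right"]
            if any(
                abs(lf.shared_fraction[b] - rt.shared_fraction[b]) > 1e-12
                for b in BAND_NAMES
            ):
                raise ValueError("shared_fraction must match across the pair")
        if self.fs <= 64.0:
            raise ValueError("fs must exceed 64 Hz (2 x 32 Hz band limit)")
        if self.cci_time < MIN_PRE_S:
            raise ValueError(f"cci_time must allow >= {MIN_PRE_S:.0f} s of baseline")
        if self.duration - self.cci_time < MIN_POST_S:
            raise ValueError(
                f"duration must allow >= {MIN_POST_S:.0f} s after the impact"
            )

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SubjectSpec":
        d = dict(d)
        for key in ("baseline", "post"):
            d[key] = {ch: RegimeParams(**p) for ch, p in d[key].items()}
        return cls(**d)


@dataclass
class Recording:
    """Two synchronized channels (microvolts) with the impact sample marked."""

    left: np.ndarray
    right: np.ndarray
    fs: float
    cci_sample: int
    meta: SubjectSpec | None = None
    ipsilateral_channel: str = "right"

    def __post_init__(self) -> None:
        if len(self.left) != len(self.right):
            raise ValueError("channels must have equal length")
        if not 0 < self.cci_sample < len(self.left):
            raise ValueError("cci_sample must fall inside the recording")
        if self.ipsilateral_channel not in ("left", "right"):
            raise ValueError("ipsilateral_channel must be 'left' or 'right'")

    @property
    def n_samples(self) -> int:
        return len(self.left)

    def channel(self, name: str) -> np.ndarray:
        return self.left if name == "left" else self.right


def _band_weights(exponent: float) -> dict[str, float]:
    """Fraction of total power per band under a 1/f^exponent envelope."""

    def integral(lo: float, hi: float) -> float:
        if abs(exponent - 1.0) < 1e-9:
            return float(np.log(hi / lo))
        p = 1.0 - exponent
        return float((hi**p - lo**p) / p)

    raw = {b: integral(*SYNTH_BAND_EDGES[b]) for b in BAND_NAMES}
    total = sum(raw.values())
    return {b: v / total for b, v in raw.items()}


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
                exponent: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi] with 1/f^a shaping."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(f)
    mask = (f >= lo) & (f < hi)
    amp[mask] = f[mask] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * amp, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _burst_envelope(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """Smooth waxing-and-waning gain in [0, 1] from squashed slow noise.

    The probit squashing gives a uniform marginal, so the envelope spends
    equal time at every suppression level rather than switching between
    two states; this keeps the kurtosis footprint of the modulation small.
    """
    from scipy.special import ndtr

    slow = _band_noise(rng, n, fs, 0.05, 0.4, 0.0)
    return ndtr(slow)


def _spike_train(rng: np.random.Generator, n: int, fs: float, rate: float,
                 amp_uv: float) -> np.ndarray:
    """Sparse biphasic transients at a Poisson rate; raises kurtosis."""
    out = np.zeros(n)
    count = rng.poisson(rate * n / fs)
    width = max(4, int(round(SPIKE_WIDTH_S * fs)))
    shape = np.hanning(width) * np.sin(2 * np.pi * np.arange(width) / width)
    peak = np.abs(shape).max()
    if peak > 0:
        shape = shape / peak
    starts = rng.integers(0, max(1, n - width), size=count)
    signs = rng.choice([-1.0, 1.0], size=count)
    for s0, sg in zip(starts, signs):
        out[s0 : s0 + width] += sg * amp_uv * shape[: n - s0]
    return out


def synthesize_pair(left: RegimeParams, right: RegimeParams, n_samples: int,
                    fs: float, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize one regime segment for a channel pair.

    The draw order of random sources is fixed so that changing e.g. only
    ``am_depth`` leaves the underlying noise realization unchanged.
    """
    for b in BAND_NAMES:
        if abs(left.shared_fraction[b] - right.shared_fraction[b]) > 1e-12:
            raise ValueError("shared_fraction must match across the pair")
    chans = {"left": left, "right": right}
    weights = {ch: _band_weights(p.psd_exponent) for ch, p in chans.items()}
    slow_parts = {"left": np.zeros(n_samples), "right": np.zeros(n_samples)}
    fast_parts = {"left": np.zeros(n_samples), "right": np.zeros(n_samples)}
    for b in BAND_NAMES:
        lo, hi = SYNTH_BAND_EDGES[b]
        # common source uses the left channel's exponent; private sources
        # use their own channel's exponent (identical in all presets)
        common = _band_noise(rng, n_samples, fs, lo, hi, left.psd_exponent)
        priv = {
            ch: _band_noise(rng, n_samples, fs, lo, hi, chans[ch].psd_exponent)
            for ch in ("left", "right")
        }
        s = left.shared_fraction[b]
        for ch, p in chans.items():
            mix = np.sqrt(s) * common + np.sqrt(1.0 - s) * priv[ch]
            comp = np.sqrt(p.band_gains[b] * weights[ch][b]) * mix
            (slow_parts if b == "delta" else fast_parts)[ch] += comp
    env_gate = _burst_envelope(rng, n_samples, fs)
    out = {}
    for ch, p in chans.items():
        env = 1.0 - p.am_depth * (1.0 - env_gate)
        y = (slow_parts[ch] + env * fast_parts[ch]) * p.rms
        y = y + _spike_train(rng, n_samples, fs, p.spike_rate, p.spike_amp * p.rms)
        out[ch] = y
    return out["left"], out["right"]


def generate_recording(spec: SubjectSpec) -> Recording:
    """Render one subject: baseline regime, impact artifact, post regime.

    Deterministic given ``spec.seed``; two calls with the same spec return
    bit-identical sample arrays.
    """
    rng = np.random.default_rng(spec.seed)
    n_pre = int(round(spec.cci_time * spec.fs))
    n_total = int(round(spec.duration * spec.fs))
    n_post = n_total - n_pre
    pre_l, pre_r = synthesize_pair(
        spec.baseline["left"], spec.baseline["right"], n_pre, spec.fs, rng
    )
    post_l, post_r = synthesize_pair(
        spec.post["left"], spec.post["right"], n_post, spec.fs, rng
    )
    left = np.concatenate([pre_l, post_l])
    right = np.concatenate([pre_r, post_r])
    n_art = int(round(ARTIFACT_DURATION_S * spec.fs))
    left[n_pre : n_pre + n_art] = ARTIFACT_AMPLITUDE_UV
    right[n_pre : n_pre + n_art] = ARTIFACT_AMPLITUDE_UV
    return Recording(
        left=left, right=right, fs=spec.fs, cci_sample=n_pre,
        meta=spec, ipsilateral_channel="right",
    )


def _regime(gains, shared, am_depth=0.0, spike_rate=0.0, spike_amp=8.0) -> RegimeParams:
    return RegimeParams(
        psd_exponent=1.0,
        band_gains=dict(gains),
        shared_fraction=dict(shared),
        am_depth=am_depth,
        spike_rate=spike_rate,
        spike_amp=spike_amp,
        rms=50.0,
    )


def strain_presets() -> dict[str, SubjectSpec]:
    """Per-strain generator defaults encoding the qualitative injury pattern.

    PPKS (plasticity-susceptible), SD (outbred parent), PPKR (resistant):

    * PPKR baseline has excess delta power and a deficit above 4 Hz.
    * After the impact SD and PPKR lose broadband power; PPKS does not.
    * All strains lose mid-frequency (3-7 Hz) interhemispheric coherence
      after the impact; post-injury delta coherence orders PPKS < SD < PPKR.
    * PPKS and SD show an ipsilateral (right) spectral-entropy drop
      (burst gating of supra-delta activity); PPKR does not.
    * PPKR alone shows an ipsilateral kurtosis rise (sparse transients).
    """
    unit = {b: 1.0 for b in BAND_NAMES}
    ppkr_base_gain = {"delta": 1.6, "theta": 0.5, "alpha": 0.5, "beta": 0.5}
    base_sf = {"delta": 0.7, "theta": 0.7, "alpha": 0.6, "beta": 0.5}
    sd_base_sf = {"delta": 0.7, "theta": 0.5, "alpha": 0.45, "beta": 0.5}

    def post_sf(base, delta):
        out = dict(base)
        out["delta"] = delta
        out["theta"] = 0.3
        return out

    def scale(gains, k):
        return {b: g * k for b, g in gains.items()}

    specs = {}
    layouts = {
        "PPKS": dict(
            base_gain=unit, base_sf=base_sf,
            post_gain=unit, post_delta_sf=0.25,
            ipsi_am=0.2, ipsi_spikes=None,
        ),
        "SD": dict(
            base_gain=unit, base_sf=sd_base_sf,
            post_gain=scale(unit, 0.55), post_delta_sf=0.45,
            ipsi_am=0.2, ipsi_spikes=None,
        ),
        "PPKR": dict(
            base_gain=ppkr_base_gain, base_sf=base_sf,
            post_gain=scale(ppkr_base_gain, 0.7), post_delta_sf=0.65,
            ipsi_am=0.0, ipsi_spikes=(0.05, 8.0),
        ),
    }
    for strain, lay in layouts.items():
        baseline = {
            "left": _regime(lay["base_gain"], lay["base_sf"]),
            "right": _regime(lay["base_gain"], lay["base_sf"]),
        }
        psf = post_sf(lay["base_sf"], lay["post_delta_sf"])
        spike_rate, spike_amp = lay["ipsi_spikes"] or (0.0, 8.0)
        post = {
            "left": _regime(lay["post_gain"], psf),
            "right": _regime(
                lay["post_gain"], psf, am_depth=lay["ipsi_am"],
                spike_rate=spike_rate, spike_amp=spike_amp,
            ),
        }
        specs[strain] = SubjectSpec(
            strain=strain, sex="F", baseline=baseline, post=post,
            cci_time=100.0, duration=1072.0, fs=FS_DEFAULT, seed=0,
            subject_id=strain,
        )
    return specs


def _subject_seed(master_seed: int, strain_idx: int, subject_idx: int) -> int:
    """Counter-based per-subject seed; independent of cohort ordering."""
    ss = np.random.SeedSequence([int(master_seed), strain_idx, subject_idx])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def _jitter_gains(regime: RegimeParams, factors: dict[str, float]) -> RegimeParams:
    from dataclasses import replace

    return replace(
        regime,
        band_gains={b: g * factors[b] for b, g in regime.band_gains.items()},
    )


def cohort_specs(
    n_per_strain: int, seed: int, gain_jitter_sd: float = 0.2
) -> list[SubjectSpec]:
    """Subject specs for a balanced three-strain cohort (sexes alternating).

    Each subject carries log-normal per-band gain multipliers
    (``gain_jitter_sd`` on the log scale, the same draw in both regimes
    and channels), emulating stable between-animal differences in
    spectral shape.  The jittered gains are part of the recorded ground
    truth.
    """
    if n_per_strain < 1:
        raise ValueError("n_per_strain must be >= 1")
    presets = strain_presets()
    specs = []
    for si, strain in enumerate(STRAINS):
        base = presets[strain]
        for i in range(n_per_strain):
            jit_rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), si, i, 1])
            )
            factors = {
                b: float(np.exp(gain_jitter_sd * jit_rng.standard_normal()))
                for b in BAND_NAMES
            }
            specs.append(
                SubjectSpec(
                    strain=strain,
                    sex="MF"[i % 2],
                    baseline={
                        ch: _jitter_gains(p, factors)
                        for ch, p in base.baseline.items()
                    },
                    post={
                        ch: _jitter_gains(p, factors) for ch, p in base.post.items()
                    },
                    cci_time=base.cci_time,
                    duration=base.duration,
                    fs=base.fs,
                    seed=_subject_seed(seed, si, i),
                    subject_id=f"{strain}_{i:02d}",
                )
            )
    return specs


def cohort_manifest(specs: list[SubjectSpec]) -> pd.DataFrame:
    """Ground-truth manifest: one row per subject, full spec as JSON."""
    rows = []
    for spec in specs:
        rows.append(
            {
                "subject_id": spec.subject_id,
                "strain": spec.strain,
                "sex": spec.sex,
                "seed": spec.seed,
                "fs": spec.fs,
                "cci_time_s": spec.cci_time,
                "duration_s": spec.duration,
                "cci_sample": int(round(spec.cci_time * spec.fs)),
                "ipsilateral_channel": "right",
                "params_json": json.dumps(spec.to_dict(), sort_keys=True),
            }
        )
    return pd.DataFrame(rows)


def generate_cohort(n_per_strain: int, seed: int) -> tuple[list[Recording], pd.DataFrame]:
    """Materialize a cohort of recordings plus its ground-truth manifest."""
    specs = cohort_specs(n_per_strain, seed)
    recordings = [generate_recording(s) for s in specs]
    return recordings, cohort_manifest(specs)
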