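"""Spectral and time-domain features on the 64-bin 0.5-32 Hz grid.

Power spectra are Welch averages of Hamming-windowed 512-sample segments
with 128-sample overlap, zero-padded to 2048 FFT points so the native
frequency spacing equals the 0.5 Hz analysis bins.  Interhemispheric
magnitude-squared coherence uses the same scheme with cross/auto spectra
averaged across segments before the ratio is formed.  Scalar features:
total power (PSD integral), percent band power, band-mean coherence,
spectral entropy of the normalized 64-bin spectrum (nats), kurtosis as the
fourth standardized moment, and line length.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps
from scipy import stats as sst

from .config import (
    BAND_NAMES,
    BIN_FREQS,
    BIN_STEP,
    FS_DEFAULT,
    N_BINS,
    NFFT,
    NOVERLAP,
    NPERSEG,
    band_mask,
)
from .preprocess import Epoch

#: The 19 scalar features consumed by the risk-score learner, in canonical order.
FEATURE_NAMES = (
    "total_power",
    "delta_pct_ipsi", "theta_pct_ipsi", "alpha_pct_ipsi", "beta_pct_ipsi",
    "delta_pct_contra", "theta_pct_contra", "alpha_pct_contra", "beta_pct_contra",
    "coh_delta", "coh_theta", "coh_alpha", "coh_beta",
    "entropy_ipsi", "entropy_contra",
    "kurtosis_ipsi", "kurtosis_contra",
    "line_length_ipsi", "line_length_contra",
)


def _welch_window() -> np.ndarray:
    return sps.get_window("hamming", NPERSEG)


@dataclass
class BinnedSpectrum:
    """Power per 0.5 Hz bin over 0.5-32 Hz (64 bins).

    ``power`` is a one-sided density (uV^2/Hz), or dimensionless after
    baseline normalization (``normalized`` set, ``norm_constant`` recorded).
    """

    freqs: np.ndarray
    power: np.ndarray
    normalized: bool = False
    norm_constant: float | None = None

    def __post_init__(self) -> None:
        if len(self.freqs) != N_BINS or len(self.power) != N_BINS:
            raise ValueError(f"expected exactly {N_BINS} bins")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative in every bin")


@dataclass
class CoherenceSpectrum:
    """Magnitude-squared coherence per 0.5 Hz bin, each value in [0, 1]."""

    freqs: np.ndarray
    cxy: np.ndarray

    def __post_init__(self) -> None:
        if len(self.cxy) != N_BINS:
            raise ValueError(f"expected exactly {N_BINS} bins")
        if np.any(self.cxy < -1e-12) or np.any(self.cxy > 1 + 1e-12):
            raise ValueError("coherence must lie in [0, 1]")
        self.cxy = np.clip(self.cxy, 0.0, 1.0)


def _bin_slice(freqs: np.ndarray) -> np.ndarray:
    """Indices of the 64 analysis bins on the zero-padded Welch grid."""
    idx = np.searchsorted(freqs, BIN_FREQS)
    if not np.allclose(freqs[idx], BIN_FREQS, atol=1e-9):
        raise ValueError("Welch grid does not contain the 0.5 Hz analysis bins")
    return idx


def psd(x: np.ndarray, fs: float = FS_DEFAULT) -> BinnedSpectrum:
    """Welch power spectral density binned to the 64-bin analysis grid."""
    x = np.asarray(x, dtype=float)
    if len(x) < NPERSEG:
        raise ValueError(f"signal must hold at least one {NPERSEG}-sample window")
    f, p = sps.welch(
        x, fs=fs, window=_welch_window(), noverlap=NOVERLAP, nfft=NFFT,
        detrend="constant", scaling="density",
    )
    idx = _bin_slice(f)
    return BinnedSpectrum(freqs=BIN_FREQS.copy(), power=p[idx])


def coherence(x: np.ndarray, y: np.ndarray, fs: float = FS_DEFAULT) -> CoherenceSpectrum:
    """Magnitude-squared coherence |Pxy|^2 / (Pxx Pyy) on the 64-bin grid.

    Requires at least two Welch segments; the coherence of a single
    segment is identically 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("channels must have equal length")
    hop = NPERSEG - NOVERLAP
    if len(x) < NPERSEG + hop:
        raise ValueError("need at least two Welch segments for coherence")
    f, c = sps.coherence(
        x, y, fs=fs, window=_welch_window(), noverlap=NOVERLAP, nfft=NFFT,
        detrend="constant",
    )
    idx = _bin_slice(f)
    return CoherenceSpectrum(freqs=BIN_FREQS.copy(), cxy=c[idx])


def normalize_to_baseline(spec: BinnedSpectrum, baseline_total: float) -> BinnedSpectrum:
    """Divide every bin by the subject's baseline total power."""
    if baseline_total <= 0:
        raise ValueError("baseline_total must be > 0")
    return replace(
        spec,
        power=spec.power / baseline_total,
        normalized=True,
        norm_constant=float(baseline_total),
    )


def total_power(spec: BinnedSpectrum) -> float:
    """PSD integral over the 64 bins: sum(power) * 0.5 Hz, in uV^2."""
    if spec.normalized:
        raise ValueError("total power is defined on the non-normalized spectrum")
    return float(spec.power.sum() * BIN_STEP)


def pct_band_power(spec: BinnedSpectrum, band: str) -> float:
    """Percent of 0.5-32 Hz power in *band*; the four bands sum to 100."""
    total = spec.power.sum()
    if total <= 0:
        raise ValueError("cannot compute band percentages of a zero spectrum")
    return float(100.0 * spec.power[band_mask(band)].sum() / total)


def band_coherence(cs: CoherenceSpectrum, band: str) -> float:
    """Unweighted mean magnitude-squared coherence over the band's bins."""
    return float(cs.cxy[band_mask(band)].mean())


def spectral_entropy(spec: BinnedSpectrum) -> float:
    """Shannon entropy (nats) of the spectrum renormalized to sum to 1.

    Zero bins contribute nothing; the value lies in [0, ln 64], attained
    at a single-bin and a flat spectrum respectively.
    """
    total = spec.power.sum()
    if total <= 0:
        raise ValueError("spectral entropy of an all-zero spectrum is undefined")
    p = spec.power / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def kurtosis(x: np.ndarray) -> float:
    """Fourth standardized moment E(x-mu)^4 / sigma^4 (population form).

    Not excess kurtosis: a Gaussian gives 3, the +/-1 alternating
    sequence gives 1.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("kurtosis of a constant signal is undefined")
    return float(sst.kurtosis(x, fisher=False, bias=True))


def line_length(x: np.ndarray) -> float:
    """Path length of the trace with unit index step: sum sqrt(1 + dy^2).

    Treats the signal as a planar curve (sample index, amplitude in uV);
    a constant N-sample signal therefore has length N - 1.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("line length needs at least two samples")
    dy = np.diff(x)
    return float(np.sqrt(1.0 + dy * dy).sum())


def line_length_amplitude(x: np.ndarray) -> float:
    """Conventional amplitude-only variant: sum |dy| (kept for sensitivity)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise ValueError("line length needs at least two samples")
    return float(np.abs(np.diff(x)).sum())


def build_features(epoch: Epoch, ipsilateral: str = "right") -> dict[str, float]:
    """Assemble the 19 scalar features for one labeled epoch.

    ``ipsilateral`` names the injured-side channel; swapping it relabels
    the side-specific features without changing any value.  Percent band
    powers come from each side's own non-normalized spectrum; total power
    is the mean of the two sides' PSD integrals.
    """
    if ipsilateral not in ("left", "right"):
        raise ValueError("ipsilateral must be 'left' or 'right'")
    contralateral = "left" if ipsilateral == "right" else "right"
    sides = {"ipsi": epoch.channel(ipsilateral), "contra": epoch.channel(contralateral)}
    specs = {k: psd(v, epoch.fs) for k, v in sides.items()}
    cs = coherence(epoch.left, epoch.right, epoch.fs)
    fv: dict[str, float] = {
        "total_power": 0.5 * (total_power(specs["ipsi"]) + total_power(specs["contra"]))
    }
    for side in ("ipsi", "contra"):
        for b in BAND_NAMES:
            fv[f"{b}_pct_{side}"] = pct_band_power(specs[side], b)
    for b in BAND_NAMES:
        fv[f"coh_{b}"] = band_coherence(cs, b)
    for side in ("ipsi", "contra"):
        fv[f"entropy_{side}"] = spectral_entropy(specs[side])
        fv[f"kurtosis_{side}"] = kurtosis(sides[side])
        fv[f"line_length_{side}"] = line_length(sides[side])
    # sensitivity companions, not part of the 19-feature canonical set
    for side in ("ipsi", "contra"):
        fv[f"line_length_amp_{side}"] = line_length_amplitude(sides[side])
    return fv


def epoch_spectra(epoch: Epoch, ipsilateral: str = "right") -> dict[str, BinnedSpectrum]:
    """Per-side binned spectra of one epoch, keyed 'ipsi'/'contra'."""
    contralateral = "left" if ipsilateral == "right" else "right"
    return {
        "ipsi": psd(epoch.channel(ipsilateral), epoch.fs),
        "contra": psd(epoch.channel(contralateral), epoch.fs),
    }
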