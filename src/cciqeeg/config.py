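"""Shared analysis constants: frequency grid, band definitions, window scheme.

Every spectral quantity in the package lives on a fixed 64-bin grid with
0.5 Hz spacing covering 0.5–32 Hz.  The four classical EEG bands partition
that grid exactly (8 + 8 + 10 + 38 bins).
"""

from __future__ import annotations

import numpy as np

#: Default sampling rate of the epidural recordings, Hz.
FS_DEFAULT = 1024.0

#: Frequency-bin spacing, Hz.
BIN_STEP = 0.5

#: Analysis band limits, Hz (bin centers included on both ends).
F_LO = 0.5
F_HI = 32.0

#: Centers of the 64 analysis bins: 0.5, 1.0, ..., 32.0 Hz.
BIN_FREQS = np.round(np.arange(1, 65) * BIN_STEP, 6)

N_BINS = 64

#: Band definitions as (low, high) bin-center frequencies, inclusive.
BANDS = {
    "delta": (0.5, 4.0),
    "theta": (4.5, 8.0),
    "alpha": (8.5, 13.0),
    "beta": (13.5, 32.0),
}

BAND_NAMES = tuple(BANDS)

# Welch / STFT scheme: Hamming window of 512 samples, 128-sample overlap
# (hop 384), zero-padded to 2048 FFT points so the native resolution at
# fs=1024 Hz is exactly the 0.5 Hz bin spacing.
NPERSEG = 512
NOVERLAP = 128
NFFT = 2048

#: Base of the spectral-entropy logarithm (natural log -> nats).
ENTROPY_LOG_BASE = "e"

# Bandpass template: passband 0.5-32 Hz (ripple <= 1 dB), stopbands
# <= 0.1 Hz and >= 40 Hz (attenuation >= 40 dB), zero net phase.
FILTER_SPEC = {
    "pass_lo_hz": 0.5,
    "pass_hi_hz": 32.0,
    "stop_lo_hz": 0.1,
    "stop_hi_hz": 40.0,
    "stop_atten_db": 40.0,
    "pass_ripple_db": 1.0,
}


def band_mask(band: str) -> np.ndarray:
    """Boolean mask over :data:`BIN_FREQS` selecting the bins of *band*."""
    lo, hi = BANDS[band]
    return (BIN_FREQS >= lo - 1e-9) & (BIN_FREQS <= hi + 1e-9)


def band_indices(band: str) -> np.ndarray:
    return np.flatnonzero(band_mask(band))
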