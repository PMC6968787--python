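"""Independent reference implementations used only for cross-checking.

These deliberately avoid the library spectral routines and the package's
own vectorized search: plain-loop DFTs and exhaustive model scans, slow
but transparently correct at toy sizes.
"""

import itertools
import math

import numpy as np
from scipy import stats as sst

from cciqeeg.config import BIN_FREQS, NFFT, NOVERLAP, NPERSEG


def _segments(x: np.ndarray) -> list[np.ndarray]:
    hop = NPERSEG - NOVERLAP
    out = []
    start = 0
    while start + NPERSEG <= len(x):
        out.append(x[start : start + NPERSEG])
        start += hop
    return out


def _dft(seg: np.ndarray) -> np.ndarray:
    """Direct O(n^2) DFT of a zero-padded, windowed, demeaned segment."""
    n = NFFT
    k = np.arange(n // 2 + 1)
    t = np.arange(n)
    padded = np.zeros(n)
    padded[: len(seg)] = seg
    basis = np.exp(-2j * np.pi * np.outer(k, t) / n)
    return basis @ padded


def welch_cross_oracle(x: np.ndarray, y: np.ndarray, fs: float, window: np.ndarray):
    """Welch auto/cross spectral densities on the 64-bin grid, by direct DFT.

    One-sided density scaling: 2 / (fs * sum(w^2)) with no doubling at DC
    and Nyquist; per-segment constant detrend; segments averaged before
    any ratio is formed.
    """
    scale = 1.0 / (fs * (window**2).sum())
    sxx = syy = sxy = 0.0
    segs_x, segs_y = _segments(x), _segments(y)
    for sx, sy in zip(segs_x, segs_y):
        fx = _dft((sx - sx.mean()) * window)
        fy = _dft((sy - sy.mean()) * window)
        sxx = sxx + (fx * np.conj(fx)).real
        syy = syy + (fy * np.conj(fy)).real
        sxy = sxy + fy * np.conj(fx)
    m = len(segs_x)
    freqs = np.arange(NFFT // 2 + 1) * fs / NFFT
    one_sided = np.ones(NFFT // 2 + 1) * 2.0
    one_sided[0] = 1.0
    one_sided[-1] = 1.0
    sxx = sxx / m * scale * one_sided
    syy = syy / m * scale * one_sided
    sxy = sxy / m * scale * one_sided
    idx = np.searchsorted(freqs, BIN_FREQS)
    return sxx[idx], syy[idx], sxy[idx]


def psd_oracle(x: np.ndarray, fs: float, window: np.ndarray) -> np.ndarray:
    sxx, _, _ = welch_cross_oracle(x, x, fs, window)
    return sxx


def coherence_oracle(x: np.ndarray, y: np.ndarray, fs: float, window: np.ndarray) -> np.ndarray:
    sxx, syy, sxy = welch_cross_oracle(x, y, fs, window)
    return np.abs(sxy) ** 2 / (sxx * syy)


def split_scan_oracle(values, labels):
    """Naive threshold scan; returns (logworth, threshold, direction)."""
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    distinct = np.sort(np.unique(values))
    best = None
    for lo, hi in zip(distinct[:-1], distinct[1:]):
        thr = (lo + hi) / 2.0
        below = values < thr
        a = int((below & labels).sum())
        b = int((below & ~labels).sum())
        c = int((~below & labels).sum())
        d = int((~below & ~labels).sum())
        obs = np.array([[a, b], [c, d]], float)
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        if exp.min() < 1.0:
            p = sst.fisher_exact([[a, b], [c, d]])[1]
        else:
            with np.errstate(divide="ignore", invalid="ignore"):
                terms = np.where(obs > 0, obs * np.log(obs / exp), 0.0)
            p = sst.chi2.sf(2.0 * terms.sum(), 1)
        lw = -math.log10(max(p, 1e-300))
        direction = "lt" if a / (a + b) >= c / (c + d) else "gt"
        if best is None or lw > best[0] + 1e-12:
            best = (lw, thr, direction)
    return best


def riskslim_oracle(z: np.ndarray, y: np.ndarray, max_terms: int, l0: float,
                    intercepts=range(-10, 11)):
    """Exhaustive plain-loop search over subsets/signs/intercepts.

    Returns (objective, subset, signs, intercept) with the same
    tie-breaking priority as the package: fewer terms, lexicographic
    subset, +1-first sign patterns, smaller intercept.
    """
    n, m = z.shape
    y = y.astype(float)
    best = None
    for k in range(0, max_terms + 1):
        for subset in itertools.combinations(range(m), k):
            for signs in itertools.product([1, -1], repeat=k):
                scores = np.zeros(n)
                for j, c in zip(subset, signs):
                    scores += c * z[:, j]
                for b in intercepts:
                    eta = b + scores
                    ll = float(np.sum(y * -np.log1p(np.exp(-eta))
                                      + (1 - y) * -np.log1p(np.exp(eta))))
                    obj = ll - l0 * k
                    if best is None or obj > best[0]:
                        best = (obj, subset, signs, b)
    return best
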