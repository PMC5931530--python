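"""Dyadic band decomposition: coarse-graining, Haar, and DB4 details.

Each sensor signal is split into six power-of-two frequency bands, the
detail series of a 6-level Daubechies-4 wavelet decomposition.  Each
detail is reconstructed back to full signal length so that nonlinear
measures see equal-length series in every band.  Block-average
coarse-graining (the classic multiscale-entropy scaling step) and its
Haar-approximation equivalent are provided alongside: with averaging
normalization the two are identical at every power-of-two scale.

Band naming follows common EEG usage: level 1 (the highest octave,
fs/4..fs/2) is "high gamma", down to level 6 "delta" (fs/128..fs/64,
with everything below folded in).  The labels are names for dyadic
octaves, not literal clinical band edges.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

N_LEVELS = 6

#: Band labels for wavelet detail levels 1..6, highest frequencies first.
BAND_NAMES: tuple[str, ...] = (
    "high_gamma", "gamma", "beta", "alpha", "theta", "delta",
)


def _check_power_of_two(scale: int) -> None:
    if scale < 2 or scale & (scale - 1):
        raise ValueError(f"scale must be a power of two >= 2, got {scale}")


def coarse_grain(x: np.ndarray, scale: int) -> np.ndarray:
    """Non-overlapping block means of ``x`` at a power-of-two ``scale``.

    Output element ``j`` is the mean of input samples
    ``x[j*scale:(j+1)*scale]``; any tail shorter than ``scale`` is
    dropped, so the output has ``floor(len(x)/scale)`` elements.
    """
    _check_power_of_two(int(scale))
    x = np.asarray(x, dtype=np.float64)
    n = x.size // scale
    if n < 1:
        raise ValueError("series shorter than one block")
    return x[: n * scale].reshape(n, scale).mean(axis=1)


def haar_approximation(
    x: np.ndarray, level: int, normalization: str = "average"
) -> np.ndarray:
    """Iterated pairwise reduction of ``x`` to depth ``level``.

    With ``normalization="average"`` each step replaces sample pairs by
    their mean, and the result equals ``coarse_grain(x, 2**level)``
    exactly.  ``normalization="orthonormal"`` uses the (a+b)/sqrt(2)
    convention of the orthonormal Haar transform instead, which differs
    from coarse-graining by a factor of 2**(level/2).
    """
    if level < 1:
        raise ValueError("level must be >= 1")
    if normalization not in ("average", "orthonormal"):
        raise ValueError(f"unknown normalization {normalization!r}")
    div = 2.0 if normalization == "average" else np.sqrt(2.0)
    out = np.asarray(x, dtype=np.float64)
    for _ in range(level):
        if out.size < 2:
            raise ValueError("series too short for requested level")
        m = out.size // 2
        out = (out[: 2 * m : 2] + out[1 : 2 * m : 2]) / div
    return out


def band_frequency_range(level: int, fs: float) -> tuple[float, float]:
    """Nominal (low, high) Hz edges of detail level ``level`` at rate ``fs``.

    Level ``k`` covers the octave ``(fs/2**(k+1), fs/2**k]``; level 1
    tops out at the Nyquist frequency.
    """
    if not 1 <= level <= N_LEVELS:
        raise ValueError(f"level must be in 1..{N_LEVELS}")
    return fs / 2 ** (level + 1), fs / 2 ** level


@dataclass
class BandSet:
    """Six full-length detail series for one channel.

    ``bands[k-1]`` is the time-domain reconstruction of detail level
    ``k`` (``band_names[k-1]``), same length as the input signal.
    ``approximation`` is the residual level-6 approximation, so the sum
    of all six bands plus the approximation reproduces the input.
    """

    channel_label: str
    bands: np.ndarray            # (6, n_samples)
    band_names: tuple[str, ...]
    freq_ranges: tuple[tuple[float, float], ...]
    approximation: np.ndarray
    fs: float
    wavelet_name: str = "db4"

    def __post_init__(self) -> None:
        if self.bands.shape[0] != N_LEVELS:
            raise ValueError("a BandSet holds exactly 6 bands")

    def band(self, name: str) -> np.ndarray:
        return self.bands[self.band_names.index(name)]


def wavelet_bands(
    x: np.ndarray, fs: float, wavelet: str = "db4", channel_label: str = ""
) -> BandSet:
    """Decompose one channel into six dyadic detail bands.

    Uses a 6-level discrete wavelet transform (default DB4) in
    periodization mode, which keeps the transform orthogonal and exactly
    invertible; inputs whose length is not a multiple of 2**6 are
    edge-padded internally and trimmed after reconstruction.  Each
    detail level is reconstructed alone to full signal length.
    """
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    if n < 2 ** N_LEVELS:
        raise ValueError(f"need at least {2**N_LEVELS} samples for {N_LEVELS} levels")
    block = 2 ** N_LEVELS
    pad = (-n) % block
    xp = np.pad(x, (0, pad), mode="edge") if pad else x

    coeffs = pywt.wavedec(xp, wavelet, mode="periodization", level=N_LEVELS)
    # coeffs = [cA6, cD6, cD5, cD4, cD3, cD2, cD1]
    bands = np.empty((N_LEVELS, n))
    for level in range(1, N_LEVELS + 1):
        sel = [np.zeros_like(c) for c in coeffs]
        idx = N_LEVELS + 1 - level   # position of cD<level> in coeffs
        sel[idx] = coeffs[idx]
        bands[level - 1] = pywt.waverec(sel, wavelet, mode="periodization")[:n]
    sel = [np.zeros_like(c) for c in coeffs]
    sel[0] = coeffs[0]
    approx = pywt.waverec(sel, wavelet, mode="periodization")[:n]

    return BandSet(
        channel_label=channel_label,
        bands=bands,
        band_names=BAND_NAMES,
        freq_ranges=tuple(band_frequency_range(k, fs) for k in range(1, N_LEVELS + 1)),
        approximation=approx,
        fs=fs,
        wavelet_name=wavelet,
    )
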