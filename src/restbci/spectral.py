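"""Spectral features of 2-s resting epochs.

Each epoch is summarised per channel by 12 features: the median
frequency and Shannon entropy of the Hamming-windowed periodogram
restricted to 4-50 Hz, plus the 10 pairwise ratios of the five band
powers (theta 4-8, alpha 8-13, low beta 13-20, high beta 20-30, gamma
30-50 Hz).  The fifth (gamma) band completes the 4-band list to the
advertised "10 ratios from all possible pairs" (C(5,2) = 10) and fills
the 30-50 Hz remainder of the analysed range; the band scheme is
configurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
from scipy import signal

__all__ = [
    "BandScheme",
    "Psd",
    "compute_psd",
    "band_powers",
    "band_ratios",
    "median_frequency",
    "spectral_shannon_entropy",
    "spectral_feature_set",
]

DEFAULT_BANDS = (
    ("theta", 4.0, 8.0),
    ("alpha", 8.0, 13.0),
    ("lbeta", 13.0, 20.0),
    ("hbeta", 20.0, 30.0),
    ("gamma", 30.0, 50.0),
)

PSD_FMIN = 4.0
PSD_FMAX = 50.0


@dataclass(frozen=True)
class BandScheme:
    """Ordered, non-overlapping frequency bands within [4, 50] Hz."""

    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS

    def __post_init__(self) -> None:
        prev_high = None
        for name, low, high in self.bands:
            if not PSD_FMIN <= low < high <= PSD_FMAX:
                raise ValueError(f"band {name} outside [{PSD_FMIN}, {PSD_FMAX}]")
            if prev_high is not None and low < prev_high:
                raise ValueError(f"band {name} overlaps its predecessor")
            prev_high = high

    @property
    def names(self) -> list[str]:
        return [b[0] for b in self.bands]

    @property
    def ratio_names(self) -> list[str]:
        # lower-frequency band in the numerator, matching "theta/hbeta" style
        return [f"{a}/{b}" for a, b in combinations(self.names, 2)]


@dataclass
class Psd:
    """Per-channel power spectral density on a common frequency grid,
    restricted to [4, 50] Hz."""

    freqs: np.ndarray  # [n_freqs]
    power: np.ndarray  # [channels x n_freqs]

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.atleast_2d(np.asarray(self.power, dtype=float))
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")


def compute_psd(epoch: np.ndarray, fs: float) -> Psd:
    """Single-segment Hamming-windowed periodogram, 4-50 Hz.

    ``epoch`` is [channels x samples] (a single channel may be passed as
    a 1-D array).  Frequency resolution is fs/N, i.e. 0.5 Hz for a 2-s
    epoch at 160 Hz.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    if epoch.shape[-1] < 2:
        raise ValueError("epoch must have at least 2 samples")
    if fs / 2 < PSD_FMAX:
        raise ValueError(f"fs/2 must reach {PSD_FMAX} Hz")
    freqs, power = signal.periodogram(epoch, fs=fs, window="hamming",
                                      axis=-1, detrend=False)
    keep = (freqs >= PSD_FMIN) & (freqs <= PSD_FMAX)
    return Psd(freqs=freqs[keep], power=power[:, keep])


def band_powers(psd: Psd, scheme: BandScheme | None = None) -> np.ndarray:
    """Per-channel band powers: mean PSD over bins with low <= f < high.

    The half-open convention assigns shared band edges (8, 13, 20, 30 Hz)
    to exactly one band.  Returns [channels x n_bands].
    """
    scheme = scheme or BandScheme()
    out = np.empty((psd.power.shape[0], len(scheme.bands)))
    for k, (name, low, high) in enumerate(scheme.bands):
        mask = (psd.freqs >= low) & (psd.freqs < high)
        if not mask.any():
            raise ValueError(f"band {name} contains no frequency bins")
        out[:, k] = psd.power[:, mask].mean(axis=1)
    return out


def band_ratios(bp: np.ndarray, scheme: BandScheme | None = None) -> np.ndarray:
    """All pairwise band-power ratios, lower band in the numerator.

    Zero denominators yield NaN (flagged missing, not an exception).
    Returns [channels x C(n_bands, 2)].
    """
    scheme = scheme or BandScheme()
    bp = np.atleast_2d(bp)
    pairs = list(combinations(range(bp.shape[1]), 2))
    out = np.empty((bp.shape[0], len(pairs)))
    with np.errstate(divide="ignore", invalid="ignore"):
        for k, (i, j) in enumerate(pairs):
            out[:, k] = np.where(bp[:, j] > 0, bp[:, i] / bp[:, j], np.nan)
    return out


def median_frequency(psd: Psd) -> np.ndarray:
    """Smallest grid frequency at which cumulative power reaches half of
    the total over [4, 50] Hz; NaN where total power is zero."""
    total = psd.power.sum(axis=1)
    cum = np.cumsum(psd.power, axis=1)
    out = np.full(psd.power.shape[0], np.nan)
    ok = total > 0
    if ok.any():
        idx = np.argmax(cum[ok] >= total[ok, None] / 2.0, axis=1)
        out[ok] = psd.freqs[idx]
    return out


def spectral_shannon_entropy(psd: Psd) -> np.ndarray:
    """Shannon entropy (nats) of the power distribution over the [4, 50]
    Hz bins, per channel; NaN where total power is zero."""
    total = psd.power.sum(axis=1)
    out = np.full(psd.power.shape[0], np.nan)
    ok = total > 0
    if ok.any():
        q = psd.power[ok] / total[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(q > 0, q * np.log(q), 0.0)
        out[ok] = -terms.sum(axis=1)
    return out


def spectral_feature_set(
    epoch: np.ndarray,
    fs: float,
    scheme: BandScheme | None = None,
) -> dict[str, np.ndarray]:
    """The 12 spectral features per channel of one epoch.

    Returns an ordered mapping {feature name -> per-channel values}:
    ``medfreq``, ``shanen`` and the 10 band-power ratios.  Degenerate
    (all-zero) channels yield NaN throughout.
    """
    scheme = scheme or BandScheme()
    psd = compute_psd(epoch, fs)
    features: dict[str, np.ndarray] = {
        "medfreq": median_frequency(psd),
        "shanen": spectral_shannon_entropy(psd),
    }
    bp = band_powers(psd, scheme)
    ratios = band_ratios(bp, scheme)
    for k, name in enumerate(scheme.ratio_names):
        features[name] = ratios[:, k]
    return features
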