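"""Weighted phase-lag-index (wPLI) connectivity matrices and regional averages.

The wPLI of a channel pair is ``|mean(imag S_xy)| / mean(|imag S_xy|)`` with
cross-spectral terms pooled over epochs and over the FFT bins inside the
frequency band.  Zero-lag (volume-conducted) coupling contributes no imaginary
cross-spectrum and therefore no wPLI.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import windows

from .montage import REGIONS
from .preprocess import EpochSet
from .spectral import BandSpec

__all__ = [
    "ConnectivityMatrix",
    "band_cross_spectra",
    "wpli",
    "connectivity_matrix",
    "region_mean",
    "whole_brain_mean",
]


@dataclass
class ConnectivityMatrix:
    """Symmetric per-band wPLI matrix with zero diagonal, entries in [0, 1]."""

    band: BandSpec
    values: np.ndarray
    channels: tuple[str, ...]
    n_epochs: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.channels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} channels")
        if not np.allclose(v, v.T):
            raise ValueError("connectivity matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("diagonal must be exactly zero")
        if v.min() < 0 or v.max() > 1:
            raise ValueError("wPLI entries must lie in [0, 1]")
        self.values = v

    def pair(self, chan_i: str, chan_j: str) -> float:
        i = self.channels.index(chan_i)
        j = self.channels.index(chan_j)
        return float(self.values[i, j])


def band_cross_spectra(es: EpochSet, band: BandSpec) -> tuple[np.ndarray, np.ndarray]:
    """Per-epoch cross-spectral terms at in-band frequencies.

    Each epoch is Hann-tapered and Fourier transformed; the cross-spectrum of
    channels (i, j) is ``X_i * conj(X_j)``.  Returns ``(cross, freqs)`` where
    ``cross`` has shape (n_epochs, n_channels, n_channels, n_bins).
    """
    if es.n_epochs < 2:
        raise ValueError("need at least 2 epochs for cross-spectral estimation")
    n = es.epochs.shape[2]
    freqs = np.fft.rfftfreq(n, d=1.0 / es.fs)
    sel = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    if not sel.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    taper = windows.hann(n, sym=False)
    spec = np.fft.rfft(es.epochs * taper, axis=2)[:, :, sel]
    cross = spec[:, :, None, :] * np.conj(spec[:, None, :, :])
    return cross, freqs[sel]


def wpli(cross_terms: np.ndarray, signed: bool = False) -> float:
    """wPLI of a pooled collection of complex cross-spectral terms.

    ``|mean(imag)| / mean(|imag|)``, in [0, 1]; a degenerate pooled set (all
    imaginary parts zero) gives 0 by convention.  With ``signed=True`` the
    outer absolute value is dropped and the result lies in [-1, 1].
    """
    im = np.imag(np.ravel(np.asarray(cross_terms)))
    denom = np.abs(im).mean() if im.size else 0.0
    if denom == 0:
        return 0.0
    num = im.mean()
    return float(num / denom) if signed else float(abs(num) / denom)


def connectivity_matrix(
    es: EpochSet, band: BandSpec, per_epoch: bool = False
) -> ConnectivityMatrix:
    """wPLI for all channel pairs of an epoch set in one band.

    By default cross-spectral terms are pooled across epochs and in-band bins
    before the ratio; ``per_epoch=True`` instead computes a wPLI per epoch
    (pooling bins only) and averages the per-epoch values.
    """
    cross, _ = band_cross_spectra(es, band)
    im = cross.imag
    if per_epoch:
        num = np.abs(im.mean(axis=3))
        den = np.abs(im).mean(axis=3)
        with np.errstate(invalid="ignore"):
            w = np.where(den > 0, num / den, 0.0).mean(axis=0)
    else:
        num = np.abs(im.mean(axis=(0, 3)))
        den = np.abs(im).mean(axis=(0, 3))
        with np.errstate(invalid="ignore"):
            w = np.where(den > 0, num / den, 0.0)
    np.fill_diagonal(w, 0.0)
    w = np.clip((w + w.T) / 2.0, 0.0, 1.0)  # symmetrize against float noise
    return ConnectivityMatrix(band, w, es.channels, es.n_epochs)


def _region_channels(region, channels: tuple[str, ...]) -> list[int]:
    if isinstance(region, str):
        region = REGIONS[region]
    idx = [i for i, c in enumerate(channels) if c in region]
    if not idx:
        raise ValueError("region contains no channels of this matrix")
    return idx


def region_mean(cm: ConnectivityMatrix, region_a, region_b) -> float:
    """Mean wPLI over unordered channel pairs linking two regions.

    For ``region_a == region_b`` this is the intra-regional mean over the
    ``k*(k-1)/2`` within-region pairs (no self-pairs); otherwise the mean over
    all pairs with one endpoint in each region.
    """
    ia = _region_channels(region_a, cm.channels)
    ib = _region_channels(region_b, cm.channels)
    if set(ia) == set(ib):
        sub = cm.values[np.ix_(ia, ia)]
        iu = np.triu_indices(len(ia), k=1)
        return float(sub[iu].mean())
    if set(ia) & set(ib):
        raise ValueError("regions must be identical or disjoint")
    return float(cm.values[np.ix_(ia, ib)].mean())


def whole_brain_mean(cm: ConnectivityMatrix) -> float:
    """Mean of all unique off-diagonal (upper-triangle) wPLI values."""
    n = cm.values.shape[0]
    iu = np.triu_indices(n, k=1)
    return float(cm.values[iu].mean())
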