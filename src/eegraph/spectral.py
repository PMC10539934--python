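"""Multitaper power spectral density and band-power summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.signal import windows

from .preprocess import EpochSet

__all__ = [
    "BandSpec",
    "CANONICAL_BANDS",
    "PsdEstimate",
    "multitaper_psd",
    "band_power",
    "band_topography",
]


@dataclass(frozen=True)
class BandSpec:
    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.f_lo < self.f_hi):
            raise ValueError(f"invalid band edges for {self.name}: {self.f_lo}, {self.f_hi}")


#: The five canonical analysis bands.
CANONICAL_BANDS: tuple[BandSpec, ...] = (
    BandSpec("delta", 0.1, 4.0),
    BandSpec("theta", 4.0, 8.0),
    BandSpec("alpha", 8.0, 12.0),
    BandSpec("beta", 12.0, 30.0),
    BandSpec("gamma", 30.0, 45.0),
)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


@dataclass
class PsdEstimate:
    """Epoch-averaged PSD, ``power`` shaped (n_channels, n_freqs) in uV^2/Hz."""

    freqs: np.ndarray
    power: np.ndarray
    channels: tuple[str, ...]
    n_epochs: int

    def __post_init__(self) -> None:
        if np.any(self.power < 0):
            raise ValueError("PSD must be non-negative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")


def multitaper_psd(es: EpochSet, bandwidth: float | None = None) -> PsdEstimate:
    """DPSS multitaper PSD per channel, averaged over epochs.

    ``bandwidth`` is the full spectral bandwidth in Hz; the time-half-bandwidth
    product is ``NW = bandwidth * epoch_length / 2`` and ``2*NW - 1`` tapers
    are used.  Default bandwidth gives NW = 2 (3 tapers), a conventional
    choice for 2-s epochs.  One-sided density scaling: the integral of the
    estimate over [0, fs/2] approximates signal variance.
    """
    n = es.epochs.shape[2]
    if bandwidth is None:
        nw = 2.0
    else:
        nw = bandwidth * es.epoch_length / 2.0
    k = int(2 * nw - 1)
    if k < 1:
        raise ValueError(f"bandwidth too small: yields {k} tapers")
    tapers = windows.dpss(n, nw, Kmax=k)  # (k, n), unit-energy tapers

    freqs = np.fft.rfftfreq(n, d=1.0 / es.fs)
    # (n_epochs, n_channels, k, n_freqs)
    spec = np.fft.rfft(es.epochs[:, :, None, :] * tapers[None, None, :, :], axis=-1)
    psd = (np.abs(spec) ** 2) / es.fs
    # one-sided: double everything except DC and (for even n) Nyquist
    psd *= 2.0
    psd[..., 0] /= 2.0
    if n % 2 == 0:
        psd[..., -1] /= 2.0
    power = psd.mean(axis=2).mean(axis=0)  # average tapers, then epochs
    return PsdEstimate(freqs, power, es.channels, es.n_epochs)


def band_power(psd: PsdEstimate, band: BandSpec, mode: str = "mean") -> np.ndarray:
    """Per-channel band power over ``[f_lo, f_hi)``.

    ``mode='mean'`` averages PSD values across in-band frequencies (uV^2/Hz);
    ``mode='integral'`` integrates the density over the band (uV^2).
    """
    nyq = psd.freqs[-1]
    if band.f_lo >= nyq:
        raise ValueError(f"band {band.name} outside spectral range (nyquist={nyq})")
    sel = (psd.freqs >= band.f_lo) & (psd.freqs < band.f_hi)
    if not sel.any():
        raise ValueError(f"no frequency bins inside band {band.name}")
    if mode == "mean":
        return psd.power[:, sel].mean(axis=1)
    if mode == "integral":
        return np.trapezoid(psd.power[:, sel], psd.freqs[sel], axis=1)
    raise ValueError(f"unknown mode {mode!r}")


def band_topography(
    psds: Sequence[PsdEstimate] | Iterable[PsdEstimate],
    band: BandSpec,
    mode: str = "mean",
) -> dict[str, float]:
    """Group band-power topography: channel -> mean dB across subjects.

    dB re 1 uV^2/Hz (or 1 uV^2 in integral mode), i.e. ``10*log10(power)``
    averaged over subjects.  Tabular replacement for interpolated scalp maps.
    """
    psds = list(psds)
    if not psds:
        raise ValueError("empty group")
    channels = psds[0].channels
    powers = np.stack([band_power(p, band, mode=mode) for p in psds])
    with np.errstate(divide="ignore"):
        db = 10.0 * np.log10(powers)
    mean_db = db.mean(axis=0)
    return dict(zip(channels, mean_db.tolist()))
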