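"""Synthetic two-group EEG cohorts and canonical graph fixtures.

The signal model is deliberately simple and fully controllable:

* band-limited oscillations = 4th-order Butterworth band-passed white noise,
  scaled per band and group;
* phase-lagged coupling = a shared band-limited source added to two channels,
  one copy delayed by ``lag / (2*pi*f_center)`` seconds (Fourier shift), so
  the pair carries a constant-sign phase lag across the band;
* volume conduction = instantaneous linear mixing
  ``(1 - leakage) * own + leakage * mean(others)`` — exactly the zero-lag
  contamination that wPLI must ignore;
* reduced signal irregularity (lower sample entropy) = AR(1) broadband noise
  on the designated channels of the MCI group.

Every draw flows from ``numpy.random.default_rng`` seeded with
``(seed, group, subject_index)``, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import signal

from .graph import BinaryGraph
from .montage import CHANNELS, channel_index, validate_channels
from .preprocess import Recording
from .spectral import BAND_BY_NAME

__all__ = [
    "CouplingEdge",
    "CohortSpec",
    "generate_subject",
    "generate_cohort",
    "make_graph_fixture",
    "null_cohort_spec",
    "theta_effect_cohort_spec",
]

GROUPS = ("HC", "MCI")


@dataclass(frozen=True)
class CouplingEdge:
    """A constant-lag band-limited coupling between two channels."""

    chan_i: str
    chan_j: str
    band: str
    phase_lag: float  # radians at band center
    strength: float  # amplitude of the shared source (same units as noise_sd)


@dataclass
class CohortSpec:
    """Ground-truth description of a two-group synthetic cohort."""

    n_hc: int = 13
    n_mci: int = 12
    fs: float = 200.0
    duration: float = 110.0
    band_amplitudes: dict = field(default_factory=dict)  # group -> band -> amplitude
    coupling_edges: dict = field(default_factory=dict)  # group -> list[CouplingEdge]
    mixing_leakage: float = 0.0
    noise_sd: float = 5.0
    entropy_deficit_channels: tuple[str, ...] = ()
    entropy_deficit_ar: float = 0.9  # AR(1) coefficient on the deficit channels (MCI)
    band_channel_gains: dict = field(default_factory=dict)  # band -> channel -> gain
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_mci < 2:
            raise ValueError("each group needs at least 2 subjects")
        top = max(
            (BAND_BY_NAME[b].f_hi for g in self.band_amplitudes.values() for b in g),
            default=BAND_BY_NAME["gamma"].f_hi,
        )
        if self.fs <= 2 * top:
            raise ValueError(f"fs={self.fs} must exceed twice the highest band edge {top}")
        if not 0 <= self.mixing_leakage < 1:
            raise ValueError("mixing_leakage must lie in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.entropy_deficit_ar < 1:
            raise ValueError("entropy_deficit_ar must lie in [0, 1)")
        validate_channels(self.entropy_deficit_channels)
        for group, edges in self.coupling_edges.items():
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
            norm = []
            for e in edges:
                if not isinstance(e, CouplingEdge):
                    e = CouplingEdge(*e)
                channel_index(e.chan_i)
                channel_index(e.chan_j)
                if e.band not in BAND_BY_NAME:
                    raise ValueError(f"unknown band {e.band!r}")
                norm.append(e)
            self.coupling_edges[group] = norm
        for group in self.band_amplitudes:
            if group not in GROUPS:
                raise ValueError(f"unknown group {group!r}")
        self.entropy_deficit_channels = tuple(self.entropy_deficit_channels)

    # -- config I/O ---------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["coupling_edges"] = {
            g: [list(asdict(e).values()) for e in edges]
            for g, edges in self.coupling_edges.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortSpec":
        d = dict(d)
        d["coupling_edges"] = {
            g: [CouplingEdge(*e) for e in edges]
            for g, edges in d.get("coupling_edges", {}).items()
        }
        if "entropy_deficit_channels" in d:
            d["entropy_deficit_channels"] = tuple(d["entropy_deficit_channels"])
        return cls(**d)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _bandlimited_noise(rng: np.random.Generator, band: str, fs: float, n: int) -> np.ndarray:
    """Unit-SD band-limited noise via 4th-order Butterworth filtering."""
    b = BAND_BY_NAME[band]
    sos = signal.butter(4, [b.f_lo, b.f_hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _fourier_delay(x: np.ndarray, delay_s: float, fs: float) -> np.ndarray:
    """Circular time shift of ``x`` by ``delay_s`` seconds (frequency domain)."""
    freqs = np.fft.rfftfreq(x.size, d=1.0 / fs)
    return np.fft.irfft(np.fft.rfft(x) * np.exp(-2j * np.pi * freqs * delay_s), n=x.size)


def generate_subject(spec: CohortSpec, group: str, subject_index: int) -> Recording:
    """Generate one 19-channel recording; reproducible by (seed, group, index)."""
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if spec.duration < 2.0:
        raise ValueError("duration must cover at least one 2-s epoch")
    rng = np.random.default_rng([spec.seed, GROUPS.index(group), subject_index])
    n = round(spec.duration * spec.fs)
    n_ch = len(CHANNELS)
    data = np.empty((n_ch, n))

    # broadband noise, AR(1)-reddened on entropy-deficit channels of MCI
    deficit = {channel_index(c) for c in spec.entropy_deficit_channels} if group == "MCI" else set()
    for ci in range(n_ch):
        white = rng.standard_normal(n)
        if ci in deficit:
            phi = spec.entropy_deficit_ar
            ar = signal.lfilter([1.0], [1.0, -phi], white)
            data[ci] = spec.noise_sd * np.sqrt(1.0 - phi**2) * ar
        else:
            data[ci] = spec.noise_sd * white

    # per-band oscillatory power
    for band, amp in spec.band_amplitudes.get(group, {}).items():
        if amp == 0:
            continue
        gains = spec.band_channel_gains.get(band, {})
        for ci, ch in enumerate(CHANNELS):
            osc = _bandlimited_noise(rng, band, spec.fs, n)
            data[ci] += amp * gains.get(ch, 1.0) * osc

    # constant-lag coupling through shared delayed sources
    for edge in spec.coupling_edges.get(group, []):
        b = BAND_BY_NAME[edge.band]
        f_center = (b.f_lo + b.f_hi) / 2.0
        src = _bandlimited_noise(rng, edge.band, spec.fs, n)
        delay = edge.phase_lag / (2.0 * np.pi * f_center)
        data[channel_index(edge.chan_i)] += edge.strength * src
        data[channel_index(edge.chan_j)] += edge.strength * _fourier_delay(src, delay, spec.fs)

    # zero-lag instantaneous mixing (volume conduction surrogate)
    lam = spec.mixing_leakage
    if lam > 0:
        mix = (1.0 - lam) * np.eye(n_ch) + lam / (n_ch - 1) * (np.ones((n_ch, n_ch)) - np.eye(n_ch))
        data = mix @ data

    return Recording(
        CHANNELS, spec.fs, data,
        subject_id=f"{group.lower()}{subject_index:02d}", group=group,
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """All ``n_hc + n_mci`` recordings, HC first, each tagged with its group."""
    recs = [generate_subject(spec, "HC", i) for i in range(spec.n_hc)]
    recs += [generate_subject(spec, "MCI", i) for i in range(spec.n_mci)]
    return recs


def make_graph_fixture(
    kind: str, n_nodes: int, params: dict | None = None, seed: int = 0
) -> BinaryGraph:
    """Canonical graph fixtures with known properties.

    ``kind`` is one of complete, star, path, ring_lattice, watts_strogatz,
    erdos_renyi.  ``params``: ``k`` (lattice/WS neighbors), ``p`` (WS rewiring
    or ER edge probability).  Stochastic kinds are reproducible by seed.
    """
    params = params or {}
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    if kind == "complete":
        g = nx.complete_graph(n_nodes)
    elif kind == "star":
        g = nx.star_graph(n_nodes - 1)
    elif kind == "path":
        g = nx.path_graph(n_nodes)
    elif kind == "ring_lattice":
        g = nx.watts_strogatz_graph(n_nodes, params.get("k", 4), 0.0)
    elif kind == "watts_strogatz":
        g = nx.watts_strogatz_graph(n_nodes, params.get("k", 4), params.get("p", 0.1), seed=seed)
    elif kind == "erdos_renyi":
        g = nx.gnp_random_graph(n_nodes, params.get("p", 0.1), seed=seed)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    return BinaryGraph.from_networkx(g)


def null_cohort_spec(
    n_hc: int = 13, n_mci: int = 12, duration: float = 110.0, seed: int = 0,
    mixing_leakage: float = 0.0,
) -> CohortSpec:
    """Cohort with identical group parameters (no injected effect)."""
    amps = {g: {"delta": 1.5, "theta": 1.5, "alpha": 2.0, "beta": 1.0} for g in GROUPS}
    return CohortSpec(
        n_hc=n_hc, n_mci=n_mci, duration=duration, seed=seed,
        band_amplitudes=amps, mixing_leakage=mixing_leakage,
    )


#: Channels forming the MCI theta coupling clique of the effect cohort.
THETA_CLIQUE = ("F3", "Fz", "F4", "C3", "Cz", "C4")


def theta_effect_cohort_spec(
    n_hc: int = 13, n_mci: int = 12, duration: float = 110.0, seed: int = 0,
    strength: float = 6.0, mixing_leakage: float = 0.1,
) -> CohortSpec:
    """Cohort with a theta-band coupling difference between the groups.

    The MCI group carries strong constant-lag theta coupling on all pairs of a
    six-channel fronto-central clique (elevated local connectivity); the HC
    group has none.  The concentrated clique lowers the MCI group's theta
    global efficiency after top-N binarization, while the per-pair theta wPLI
    rises — both contrasts are then detectable by the downstream statistics.
    The default ``strength`` was chosen by a pilot power sweep so detection
    exceeds 80% of seeds at n = 13 vs 12.
    """
    spec = null_cohort_spec(n_hc, n_mci, duration, seed, mixing_leakage)
    clique = [
        CouplingEdge(a, b, "theta", np.pi / 2, strength)
        for k, a in enumerate(THETA_CLIQUE)
        for b in THETA_CLIQUE[k + 1:]
    ]
    spec.coupling_edges = {"MCI": clique}
    spec.entropy_deficit_channels = ("C3", "C4")
    return spec
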