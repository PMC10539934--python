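"""The 19-channel 10-20 scalp montage and its regional partition."""

from __future__ import annotations

#: Canonical channel order used throughout the package.
CHANNELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F3", "F4", "F7", "F8",
    "C3", "C4", "T3", "T4", "T5", "T6",
    "P3", "P4", "O1", "O2", "Cz", "Fz", "Pz",
)

#: Scalp regions used for intra/inter-regional connectivity averages.
REGIONS: dict[str, frozenset[str]] = {
    "frontal": frozenset({"Fp1", "Fp2", "F3", "F4", "F7", "F8", "Fz"}),
    "central": frozenset({"C3", "C4", "T3", "T4", "Cz"}),
    "parieto_occipital": frozenset({"P3", "P4", "O1", "O2", "T5", "T6", "Pz"}),
}

N_CHANNELS = len(CHANNELS)
#: Unordered channel pairs = n(n-1)/2.
N_PAIRS = N_CHANNELS * (N_CHANNELS - 1) // 2

_INDEX = {name.lower(): i for i, name in enumerate(CHANNELS)}


def channel_index(label: str) -> int:
    """Return the montage position of ``label`` (case-insensitive)."""
    try:
        return _INDEX[label.lower()]
    except KeyError:
        raise KeyError(f"unknown channel label {label!r}; montage has {CHANNELS}") from None


def validate_channels(labels) -> None:
    """Raise if any label is outside the montage or duplicated."""
    seen = set()
    for lab in labels:
        key = lab.lower()
        if key not in _INDEX:
            raise KeyError(f"unknown channel label {lab!r}")
        if key in seen:
            raise ValueError(f"duplicate channel label {lab!r}")
        seen.add(key)
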