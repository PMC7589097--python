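"""Canonical EEG frequency bands, channel montage and band-subset recipes.

The five classical scalp-EEG frequency bands and the nine-electrode frontal/
parieto-occipital montage used throughout the package.  Feature columns are
always named ``Band_Channel`` (e.g. ``Alpha_F7``) and ordered band-major:
all channels of the first band, then all channels of the next band, with the
channel order fixed by :data:`CHANNELS`.
"""

from __future__ import annotations

from typing import Iterable, Sequence

#: Band name -> (low Hz, high Hz).  Intervals are half-open [low, high) so
#: that a shared printed endpoint (4 Hz appears in both Delta and Theta)
#: maps every frequency bin to exactly one band.
BAND_RANGES: dict[str, tuple[float, float]] = {
    "Delta": (0.5, 4.0),
    "Theta": (4.0, 8.0),
    "Alpha": (8.0, 12.0),
    "Beta": (12.0, 30.0),
    "Gamma": (30.0, 100.0),
}

#: Canonical band order (frequency-range order).
BANDS: tuple[str, ...] = ("Delta", "Theta", "Alpha", "Beta", "Gamma")

#: Electrode order used for every band block.
CHANNELS: tuple[str, ...] = ("AF3", "AF4", "F3", "F7", "F8", "FC5", "O2", "P8", "T8")

#: Bands whose power rises in the *high*-workload state; the remaining
#: (slow-wave) bands rise in the low-workload / relaxed state.
HIGH_STATE_BANDS: frozenset[str] = frozenset({"Alpha", "Beta", "Gamma"})

#: Named band-subset recipes: combinations of bands commonly contrasted when
#: classifying workload.  Subset_1 is "every band that survives screening"
#: (Theta is typically screened out, leaving 36 columns over 9 channels).
SUBSET_RECIPES: dict[str, tuple[str, ...]] = {
    "Subset_1": ("Delta", "Alpha", "Beta", "Gamma"),
    "Subset_2": ("Alpha",),
    "Subset_3": ("Beta", "Gamma"),
    "Subset_4": ("Alpha", "Beta"),
    "Subset_5": ("Alpha", "Beta", "Gamma"),
    "Subset_6": ("Delta", "Alpha", "Beta"),
    "Subset_7": ("Delta", "Alpha", "Gamma"),
}


def column_name(band: str, channel: str) -> str:
    return f"{band}_{channel}"


def split_column_name(name: str) -> tuple[str, str]:
    """Split ``Band_Channel`` into its parts; raises on malformed names."""
    band, sep, channel = name.partition("_")
    if not sep or not band or not channel:
        raise ValueError(f"column name {name!r} is not of the form Band_Channel")
    return band, channel


def column_names(
    bands: Sequence[str] = BANDS, channels: Sequence[str] = CHANNELS
) -> list[str]:
    """Band-major column layout over the given bands and channels."""
    return [column_name(b, c) for b in bands for c in channels]


def sort_columns(names: Iterable[str]) -> list[str]:
    """Sort Band_Channel names band-major (canonical band order) then by
    the canonical channel order; unknown bands/channels sort last, stably."""
    band_rank = {b: i for i, b in enumerate(BANDS)}
    chan_rank = {c: i for i, c in enumerate(CHANNELS)}
    names = list(names)

    def key(name: str) -> tuple[int, int, str]:
        band, channel = split_column_name(name)
        return band_rank.get(band, len(BANDS)), chan_rank.get(channel, len(CHANNELS)), name

    return sorted(names, key=key)
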