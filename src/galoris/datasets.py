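"""Synthetic EEG-like data with known ground truth.

Two generators: :func:`generate_band_features` draws two-state (low/high
cognitive workload) band-power feature tables in which a chosen set of
informative columns carries a standardized mean shift between the states —
fast-wave columns (Alpha/Beta/Gamma) elevated in the high-workload state,
slow-wave columns (Delta/Theta) elevated in the low-workload state — while
the remaining columns are state-independent noise.  :func:`generate_raw_eeg`
synthesises raw traces as sums of in-band sinusoids plus white noise, so
the spectral extraction stage can be exercised against known frequencies.

Both are deterministic given their seed and never touch global random
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BAND_RANGES, BANDS, CHANNELS, HIGH_STATE_BANDS, column_names, split_column_name
from .features import BandFeatureMatrix, RawEegRecord

__all__ = ["SyntheticSpec", "generate_band_features", "generate_raw_eeg"]


class ConfigurationError(ValueError):
    """A synthetic-data specification field is invalid."""


@dataclass
class SyntheticSpec:
    """Conditions for a two-state band-feature draw.

    Defaults mirror the scale of a typical driving-workload recording
    session: 5 bands x 9 channels x 8210 epochs, balanced states.
    ``effect_size`` is the standardized mean shift (in units of
    ``noise_sd``) between the low- and high-workload states on the
    informative columns.
    """

    n_samples: int = 8210
    channels: tuple[str, ...] = CHANNELS
    bands: tuple[str, ...] = BANDS
    #: None -> every non-Theta column carries signal: fast-wave and Delta
    #: activity separate the workload states while Theta stays null, so the
    #: p <= 0.05 screen keeps a four-band (36-column) search space.
    informative_columns: tuple[str, ...] | None = None
    effect_size: float = 2.0
    noise_sd: float = 1.0
    state_prevalence: float = 0.5
    baseline_mean: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ConfigurationError(f"n_samples must be >= 1, got {self.n_samples}")
        if not 0.0 < self.state_prevalence < 1.0:
            raise ConfigurationError(
                f"state_prevalence must lie strictly in (0, 1), got {self.state_prevalence}"
            )
        if self.effect_size < 0:
            raise ConfigurationError(f"effect_size must be >= 0, got {self.effect_size}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        cols = self.column_names
        if self.informative_columns is None:
            self.informative_columns = tuple(
                c for c in cols if split_column_name(c)[0] != "Theta"
            )
            if not self.informative_columns:  # Theta-only layouts
                self.informative_columns = tuple(cols)
        unknown = [c for c in self.informative_columns if c not in cols]
        if unknown:
            raise ConfigurationError(f"informative_columns not in the layout: {unknown}")

    @property
    def column_names(self) -> list[str]:
        return column_names(self.bands, self.channels)

    @property
    def informative_mask(self) -> np.ndarray:
        informative = set(self.informative_columns)
        return np.array([c in informative for c in self.column_names])


def generate_band_features(
    spec: SyntheticSpec,
) -> tuple[BandFeatureMatrix, np.ndarray, np.ndarray]:
    """Draw a feature matrix, state labels, and the informative-column mask.

    Each column is Gaussian within a state.  An informative column's means
    differ by ``effect_size * noise_sd`` between states, signed by its
    band: +shift in the high state for Alpha/Beta/Gamma columns, -shift for
    Delta/Theta columns.  Labels are 1 for the high-workload state.
    """
    rng = np.random.default_rng(spec.seed)
    cols = spec.column_names
    n, p = spec.n_samples, len(cols)

    labels = (rng.random(n) < spec.state_prevalence).astype(int)
    values = spec.baseline_mean + spec.noise_sd * rng.standard_normal((n, p))

    shift = spec.effect_size * spec.noise_sd
    mask = spec.informative_mask
    high = labels == 1
    for j, col in enumerate(cols):
        if not mask[j]:
            continue
        band, _ = split_column_name(col)
        sign = 1.0 if band in HIGH_STATE_BANDS else -1.0
        values[high, j] += sign * shift

    matrix = BandFeatureMatrix(pd.DataFrame(values, columns=cols), standardized=False)
    return matrix, labels, mask


def generate_raw_eeg(
    band_amplitudes: dict[str, float],
    sampling_rate: float = 256.0,
    duration: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    channels: tuple[str, ...] = CHANNELS,
    band_ranges: dict[str, tuple[float, float]] | None = None,
) -> RawEegRecord:
    """Raw traces as per-band sinusoids plus white noise.

    For every band with a non-zero amplitude, each channel receives one
    sinusoid whose frequency is drawn uniformly strictly inside the band's
    range (avoiding the edges so no FFT bin is ambiguous between adjacent
    bands) with a random phase.  Requires ``sampling_rate >= 128`` Hz so a
    full analysis window fits into an epoch downstream.
    """
    if band_ranges is None:
        band_ranges = dict(BAND_RANGES)
    if sampling_rate < 128:
        raise ConfigurationError(
            f"sampling_rate must be >= 128 Hz, got {sampling_rate}"
        )
    unknown = [b for b in band_amplitudes if b not in band_ranges]
    if unknown:
        raise ConfigurationError(f"unknown bands in band_amplitudes: {unknown}")
    n = int(round(duration * sampling_rate))
    if n < 128:
        raise ValueError(
            f"duration {duration} s at {sampling_rate} Hz gives {n} samples; "
            "at least one 128-sample analysis window is required"
        )

    rng = np.random.default_rng(seed)
    t = np.arange(n) / sampling_rate
    traces = np.zeros((n, len(channels)))
    for band, amp in band_amplitudes.items():
        if amp == 0:
            continue
        low, high = band_ranges[band]
        # keep draws away from band edges: the 128-sample analysis window
        # downstream has 2 Hz bins, and a tone near a shared edge would
        # leak its spectral peak into the neighbouring band
        margin = 0.3 * (high - low)
        for c in range(len(channels)):
            freq = rng.uniform(low + margin, high - margin)
            phase = rng.uniform(0, 2 * np.pi)
            traces[:, c] += amp * np.sin(2 * np.pi * freq * t + phase)
    if noise_sd > 0:
        traces += noise_sd * rng.standard_normal(traces.shape)

    return RawEegRecord(pd.DataFrame(traces, columns=list(channels)), sampling_rate)


def write_features_csv(
    matrix: BandFeatureMatrix, labels: np.ndarray, path: str | Path
) -> None:
    """Write the feature table with a trailing binary ``label`` column."""
    out = matrix.values.copy()
    out["label"] = np.asarray(labels, dtype=int)
    out.to_csv(path, index=False)


def read_features_csv(path: str | Path) -> tuple[BandFeatureMatrix, np.ndarray | None]:
    """Read a feature table; a ``label`` column, if present, is split off."""
    df = pd.read_csv(path)
    labels = None
    if "label" in df.columns:
        labels = df.pop("label").to_numpy(dtype=int)
    return BandFeatureMatrix(df), labels
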