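"""Band-power feature extraction from raw EEG traces.

Raw multi-channel EEG (microvolts, fixed sampling rate) is band-pass
filtered with a zero-phase Butterworth filter, cut into fixed-length epochs,
and each epoch is reduced to one power value per (band, channel): the peak
magnitude of the Hanning-windowed FFT power spectrum over the frequency bins
falling inside the band's range.  The result is a samples x (band, channel)
feature matrix, optionally min-max standardized to [0, 1].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps

from .bands import BAND_RANGES, BANDS, column_name

__all__ = [
    "RawEegRecord",
    "BandFeatureMatrix",
    "bandpass_filter",
    "extract_band_powers",
    "standardize",
    "read_raw_eeg_csv",
]


@dataclass
class RawEegRecord:
    """Multi-channel EEG traces in microvolts at a fixed sampling rate.

    ``traces`` is a DataFrame with one column per channel; all channels
    share the same length and sampling rate.
    """

    traces: pd.DataFrame
    sampling_rate: float

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not isinstance(self.traces, pd.DataFrame):
            self.traces = pd.DataFrame(self.traces)

    @property
    def n_samples(self) -> int:
        return len(self.traces)

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def channels(self) -> list[str]:
        return list(self.traces.columns)

    def to_csv(self, path: str | Path) -> None:
        self.traces.to_csv(path, index=False)


def read_raw_eeg_csv(path: str | Path, sampling_rate: float) -> RawEegRecord:
    """Read comma-separated raw traces (channel-name header) back in."""
    return RawEegRecord(pd.read_csv(path), sampling_rate=sampling_rate)


@dataclass
class BandFeatureMatrix:
    """Samples x (band, channel) power-feature matrix.

    Columns are named ``Band_Channel`` and laid out band-major.  When
    ``standardized`` is true every value lies in [0, 1] and the original
    per-column minima / ranges are retained in ``scale_params`` so raw
    values can be looked up again.
    """

    values: pd.DataFrame
    standardized: bool = False
    band_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(BAND_RANGES)
    )
    scale_params: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            raise TypeError("values must be a DataFrame")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate column names in feature matrix")

    @property
    def column_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    def select_columns(self, names: list[str]) -> "BandFeatureMatrix":
        missing = [n for n in names if n not in self.values.columns]
        if missing:
            raise KeyError(f"columns not present: {missing}")
        return dataclasses.replace(self, values=self.values[names].copy())

    def to_csv(self, path: str | Path) -> None:
        self.values.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, standardized: bool = False) -> "BandFeatureMatrix":
        return cls(pd.read_csv(path), standardized=standardized)


def bandpass_filter(
    record: RawEegRecord,
    low: float = 1.0,
    high: float = 100.0,
    order: int = 5,
) -> RawEegRecord:
    """Zero-phase Butterworth band-pass filter of the given order.

    Forward-backward (``filtfilt``) application keeps epoch timing aligned
    with the unfiltered record.  ``high`` must stay below the Nyquist
    frequency.
    """
    nyquist = record.sampling_rate / 2.0
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got low={low}, high={high}")
    if high >= nyquist:
        raise ValueError(
            f"high cutoff {high} Hz must be below the Nyquist frequency "
            f"{nyquist} Hz; lower the cutoff or resample the record"
        )
    sos = sps.butter(order, [low, high], btype="bandpass", fs=record.sampling_rate, output="sos")
    filtered = sps.sosfiltfilt(sos, record.traces.to_numpy(), axis=0)
    return RawEegRecord(
        pd.DataFrame(filtered, columns=record.traces.columns),
        sampling_rate=record.sampling_rate,
    )


def _windowed_power_spectrum(segment: np.ndarray, window: np.ndarray) -> np.ndarray:
    """Power spectrum of one window: squared rFFT magnitude over window energy."""
    spec = np.fft.rfft(segment * window)
    return (spec.real**2 + spec.imag**2) / np.sum(window**2)


def extract_band_powers(
    record: RawEegRecord,
    window: int = 128,
    epoch_length: float = 5.0,
    band_ranges: dict[str, tuple[float, float]] | None = None,
) -> BandFeatureMatrix:
    """Per-epoch peak band power for every (band, channel) pair.

    The record is cut into consecutive ``epoch_length``-second epochs (one
    output row each).  Within an epoch, a Hanning window of ``window``
    samples is slid without overlap; per-frequency-bin power maxima are
    taken across the sub-windows, and each band's feature is the maximum
    over the bins inside its half-open [low, high) range.
    """
    if band_ranges is None:
        band_ranges = dict(BAND_RANGES)
    epoch_samples = int(round(epoch_length * record.sampling_rate))
    if epoch_samples < window:
        raise ValueError(
            f"epoch of {epoch_samples} samples is shorter than the "
            f"{window}-sample analysis window"
        )
    n_epochs = record.n_samples // epoch_samples
    if n_epochs < 1:
        raise ValueError(
            f"record of {record.n_samples} samples is shorter than one "
            f"{epoch_samples}-sample epoch"
        )

    han = np.hanning(window)
    freqs = np.fft.rfftfreq(window, d=1.0 / record.sampling_rate)
    bands = [b for b in BANDS if b in band_ranges] + [
        b for b in band_ranges if b not in BANDS
    ]
    band_bins = {
        b: (freqs >= band_ranges[b][0]) & (freqs < band_ranges[b][1]) for b in bands
    }

    data = record.traces.to_numpy()
    n_sub = epoch_samples // window
    rows = np.zeros((n_epochs, len(bands) * len(record.channels)))
    for e in range(n_epochs):
        epoch = data[e * epoch_samples : (e + 1) * epoch_samples]
        for c in range(epoch.shape[1]):
            bin_max = np.zeros(len(freqs))
            for s in range(n_sub):
                seg = epoch[s * window : (s + 1) * window, c]
                np.maximum(bin_max, _windowed_power_spectrum(seg, han), out=bin_max)
            for bi, band in enumerate(bands):
                mask = band_bins[band]
                rows[e, bi * epoch.shape[1] + c] = bin_max[mask].max() if mask.any() else 0.0

    columns = [column_name(b, c) for b in bands for c in record.channels]
    return BandFeatureMatrix(
        pd.DataFrame(rows, columns=columns), standardized=False, band_ranges=band_ranges
    )


def standardize(matrix: BandFeatureMatrix) -> BandFeatureMatrix:
    """Min-max scale every column to [0, 1]; constant columns map to 0.

    Idempotent: standardizing an already-standardized matrix returns it
    unchanged.  The per-column (min, range) pairs are kept in
    ``scale_params`` for inverse lookup.
    """
    if matrix.n_samples == 0:
        raise ValueError("cannot standardize an empty feature matrix")
    if matrix.standardized:
        return matrix
    mins = matrix.values.min(axis=0)
    ranges = matrix.values.max(axis=0) - mins
    safe_ranges = ranges.replace(0.0, 1.0)
    scaled = (matrix.values - mins) / safe_ranges
    scaled.loc[:, ranges == 0.0] = 0.0
    return BandFeatureMatrix(
        scaled,
        standardized=True,
        band_ranges=dict(matrix.band_ranges),
        scale_params=pd.DataFrame({"min": mins, "range": ranges}),
    )
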