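"""Band decomposition and time-window selection.

Band-pass filtering is zero-phase (forward-backward Butterworth), so the
output has the same length as the input and no group delay; a 4th-order
design applied twice gives well over 20 dB attenuation one octave beyond
the band edges.  Time is handled 0-based with half-open intervals
``[start, end)`` so adjacent windows never share a sample.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

from .io import Recording

__all__ = ["BandSignal", "BandFilter", "band_filter", "select_window", "segment_windows"]


@dataclasses.dataclass
class BandSignal:
    """A band-limited, possibly windowed view of one recording."""

    parent: str
    band_name: str
    band_edges: tuple[float, float]
    data: np.ndarray
    fs: float
    group_label: str = "unknown"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ValueError("band signal needs a non-empty channels x samples matrix")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def duration(self) -> float:
        return self.data.shape[1] / self.fs


class BandFilter(BaseEstimator, TransformerMixin):
    """Zero-phase Butterworth band-pass for channels x samples arrays.

    Parameters
    ----------
    low, high : float
        Pass-band edges in Hz, ``0 < low < high < fs/2``.
    fs : float
        Sampling rate in Hz.
    order : int, default 4
        Butterworth order of the one-way filter; applied forward and
        backward, so the effective attenuation slope is doubled.
    """

    def __init__(self, low: float = 8.0, high: float = 12.0, fs: float = 500.0, order: int = 4):
        self.low = low
        self.high = high
        self.fs = fs
        self.order = order

    def _sos(self) -> np.ndarray:
        if not (0 < self.low < self.high):
            raise ValueError(f"need 0 < low < high, got ({self.low}, {self.high})")
        if self.high >= self.fs / 2:
            raise ValueError(
                f"band edge {self.high} Hz at or above Nyquist ({self.fs / 2} Hz)"
            )
        return signal.butter(
            self.order, [self.low, self.high], btype="bandpass", fs=self.fs, output="sos"
        )

    def fit(self, X=None, y=None):
        self._sos()  # validate parameters
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        sos = self._sos()
        return signal.sosfiltfilt(sos, X, axis=-1)


def band_filter(rec: Recording, band: tuple[float, float], band_name: str | None = None) -> BandSignal:
    """Band-pass one recording into a :class:`BandSignal`."""
    low, high = band
    filt = BandFilter(low=low, high=high, fs=rec.fs)
    data = filt.fit(None).transform(rec.data)
    return BandSignal(
        parent=rec.subject_id,
        band_name=band_name or f"{low}-{high}Hz",
        band_edges=(low, high),
        data=data,
        fs=rec.fs,
        group_label=rec.group_label,
    )


def select_window(sig: BandSignal, start: float, end: float, fs: float | None = None) -> BandSignal:
    """Cut the half-open time interval ``[start, end)`` seconds."""
    fs = sig.fs if fs is None else fs
    duration = sig.data.shape[1] / fs
    if not (0 <= start < end):
        raise ValueError(f"need 0 <= start < end, got ({start}, {end})")
    if end > duration + 1e-9:
        raise ValueError(
            f"window ({start}, {end}) s outside recording; available duration {duration:g} s"
        )
    i0 = int(round(start * fs))
    i1 = int(round(end * fs))
    return dataclasses.replace(sig, data=sig.data[:, i0:i1])


def segment_windows(sig: BandSignal, length: float, stride: float | None = None) -> list[BandSignal]:
    """Cut into fixed-length segments; non-overlapping when stride == length."""
    if stride is None:
        stride = length
    duration = sig.duration
    if length <= 0 or stride <= 0:
        raise ValueError("length and stride must be positive")
    if length > duration + 1e-9:
        raise ValueError(f"segment length {length} s exceeds duration {duration:g} s")
    n_segments = int(np.floor((duration - length) / stride + 1e-9)) + 1
    return [
        select_window(sig, i * stride, i * stride + length) for i in range(n_segments)
    ]
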