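"""Epoched recordings and their segmented, windowed Fourier representation.

A recording is organized as ``channels x epochs x samples``.  Each epoch is
further divided into (possibly overlapping) segments which never cross epoch
boundaries; every segment is optionally demeaned, tapered and transformed with
an unnormalized real FFT.  All downstream inference quantities are scale free,
so no FFT normalization factor is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import get_window

from .errors import ConfigurationError, FrequencyError, ValidationError

__all__ = [
    "EpochedRecording",
    "SegmentationConfig",
    "SpectralTensor",
    "segment_epochs",
    "fourier_coefficients",
    "freq_to_bin",
]


@dataclass
class EpochedRecording:
    """Real multichannel time series cut into equal-length epochs.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_epochs, samples_per_epoch)``, in
        arbitrary physical units.
    fs
        Sampling rate in Hz, strictly positive.
    channel_labels
        One label per channel; generated as ``ch000, ch001, ...`` if omitted.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError(
                f"data must be 3-D (channels, epochs, samples), got shape {self.data.shape}"
            )
        if not np.isfinite(self.data).all():
            raise ValidationError("data contains non-finite samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling rate must be positive, got {self.fs}")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i:03d}" for i in range(self.n_channels)]
        elif len(self.channel_labels) != self.n_channels:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.data.shape[1]

    @property
    def samples_per_epoch(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class SegmentationConfig:
    """How to slice epochs into tapered segments.

    ``overlap_fraction`` is in ``[0, 1)``; consecutive segment starts advance
    by ``segment_len * (1 - overlap_fraction)`` rounded to integer samples.
    """

    segment_len: int
    overlap_fraction: float = 0.75
    window: str = "hann"
    demean: bool = True

    def __post_init__(self) -> None:
        if self.segment_len < 2:
            raise ConfigurationError(f"segment_len must be >= 2, got {self.segment_len}")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ConfigurationError(
                f"overlap_fraction must be in [0, 1), got {self.overlap_fraction}"
            )

    @property
    def step(self) -> int:
        """Integer sample advance between consecutive segment starts."""
        return max(1, int(round(self.segment_len * (1.0 - self.overlap_fraction))))

    def taper(self) -> np.ndarray:
        """Symmetric taper of length ``segment_len`` (all-ones for 'boxcar'/'none')."""
        if self.window in ("none", "boxcar", "rect"):
            return np.ones(self.segment_len)
        return get_window(self.window, self.segment_len, fftbins=False)


@dataclass
class SpectralTensor:
    """Complex Fourier coefficients, ``channels x epochs x segments x bins``.

    Bin ``b`` corresponds to frequency ``b * freq_resolution`` with
    ``freq_resolution = fs / segment_len``; bins run from 0 (DC) to the
    Nyquist bin ``segment_len // 2`` inclusive.
    """

    coeffs: np.ndarray
    fs: float
    freq_resolution: float
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_epochs(self) -> int:
        return self.coeffs.shape[1]

    @property
    def segments_per_epoch(self) -> int:
        return self.coeffs.shape[2]

    @property
    def n_bins(self) -> int:
        return self.coeffs.shape[3]

    @property
    def n_segments_total(self) -> int:
        return self.n_epochs * self.segments_per_epoch

    def bin_frequency(self, b: int) -> float:
        return b * self.freq_resolution

    def flat_coeffs(self) -> np.ndarray:
        """Coefficients with epoch and segment axes merged: (channels, segments, bins)."""
        c, e, s, f = self.coeffs.shape
        return self.coeffs.reshape(c, e * s, f)


def segment_epochs(rec: EpochedRecording, cfg: SegmentationConfig) -> np.ndarray:
    """Return the segment index table for a recording.

    Each row is ``(epoch, start, stop)`` with a half-open sample interval
    ``[start, stop)`` relative to the epoch; segments never cross epoch
    boundaries.

    Raises
    ------
    ConfigurationError
        If the segment is longer than an epoch.
    """
    n = rec.samples_per_epoch
    if cfg.segment_len > n:
        raise ConfigurationError(
            f"segment_len={cfg.segment_len} exceeds epoch length {n}"
        )
    starts = np.arange(0, n - cfg.segment_len + 1, cfg.step)
    rows = [
        (e, int(s), int(s) + cfg.segment_len)
        for e in range(rec.n_epochs)
        for s in starts
    ]
    return np.asarray(rows, dtype=int).reshape(-1, 3)


def fourier_coefficients(rec: EpochedRecording, cfg: SegmentationConfig) -> SpectralTensor:
    """Demean (optional), taper and Fourier-transform every segment.

    Uses the unnormalized real FFT; the absolute scale cancels in every
    statistically normalized downstream quantity.
    """
    n = rec.samples_per_epoch
    if cfg.segment_len > n:
        raise ConfigurationError(
            f"segment_len={cfg.segment_len} exceeds epoch length {n}"
        )
    starts = np.arange(0, n - cfg.segment_len + 1, cfg.step)
    # (channels, epochs, segments, segment_len)
    segs = np.stack([rec.data[:, :, s : s + cfg.segment_len] for s in starts], axis=2)
    if cfg.demean:
        segs = segs - segs.mean(axis=-1, keepdims=True)
    segs = segs * cfg.taper()
    coeffs = np.fft.rfft(segs, axis=-1)
    return SpectralTensor(
        coeffs=coeffs,
        fs=rec.fs,
        freq_resolution=rec.fs / cfg.segment_len,
        channel_labels=list(rec.channel_labels),
    )


def freq_to_bin(f: float, tensor: SpectralTensor) -> int:
    """Map a frequency in Hz to the nearest FFT bin of ``tensor``.

    Emits a warning (with the realized frequency) when the nearest bin is more
    than a quarter of the frequency resolution away from the request.

    Raises
    ------
    FrequencyError
        If ``f`` is negative or above the Nyquist frequency.
    """
    nyquist = tensor.fs / 2.0
    if f < 0 or f > nyquist + 1e-12:
        raise FrequencyError(f"frequency {f} Hz outside [0, {nyquist}] Hz")
    b = int(round(f / tensor.freq_resolution))
    b = min(b, tensor.n_bins - 1)
    realized = tensor.bin_frequency(b)
    if abs(f - realized) > tensor.freq_resolution / 4.0:
        warnings.warn(
            f"requested {f} Hz mapped to bin {b} at {realized} Hz "
            f"(resolution {tensor.freq_resolution} Hz)",
            stacklevel=2,
        )
    return b
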