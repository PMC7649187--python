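"""Automatic selection of a subject-specific alpha frequency and channel.

Single-channel (auto-)bicoherence of an alpha rhythm shows sharply localized
peaks at harmonic frequency pairs such as ``(f, 2f)``, while broadband
artifacts (e.g. heartbeat) produce smooth high-valued ridges.  A discrete
Laplace filter suppresses the ridges and enhances isolated peaks, so the
selector maximizes peakiness (the negated filtered magnitude) over channels
and a configurable alpha band, evaluated on the ``f2 = 2 f1`` diagonal.

Note the sign convention: at a local maximum of the bicoherence magnitude the
five-point Laplacian is negative, so "maximize peakiness" means maximizing the
negated Laplacian.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .bispectrum import FrequencyPair, bicoherence, cross_bispectrum, three_norm
from .errors import ConfigurationError, GridError
from .spectral import SpectralTensor, freq_to_bin

__all__ = [
    "BicoherencePlane",
    "AlphaSelection",
    "univariate_bicoherence",
    "bicoherence_plane",
    "discrete_laplacian",
    "select_alpha",
]

DEFAULT_BAND = (9.0, 13.0)
DEFAULT_STENCIL_OFFSET = 2.0


@dataclass
class BicoherencePlane:
    """Bicoherence magnitudes per channel on a regular (f1, f2) frequency grid.

    ``values`` has shape ``(n_channels, len(f1_grid), len(f2_grid))``;
    unevaluable points (e.g. ``f1 + f2`` above Nyquist, vanishing norms) are
    NaN, never zero-filled.
    """

    values: np.ndarray
    f1_grid: np.ndarray
    f2_grid: np.ndarray
    channel_labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.f1_grid = np.asarray(self.f1_grid, dtype=float)
        self.f2_grid = np.asarray(self.f2_grid, dtype=float)
        for g in (self.f1_grid, self.f2_grid):
            if g.size >= 2 and not np.allclose(np.diff(g), g[1] - g[0]):
                raise ConfigurationError("frequency grid must be regular")

    @property
    def grid_step(self) -> float:
        return float(self.f1_grid[1] - self.f1_grid[0])


@dataclass
class AlphaSelection:
    """Selected channel and fundamental frequency, with the peakiness score."""

    channel: int
    f_max: float
    score: float
    channel_label: str | None = None


def univariate_bicoherence(
    spec: SpectralTensor, channel: int, f1: float, f2: float
) -> complex:
    """Auto-bicoherence of one channel at ``(f1, f2)``.

    Exactly the cross-bispectrum / three-norm pipeline restricted to a single
    channel (i = j = k); NaN when any involved norm vanishes.
    """
    fp = FrequencyPair(f1, f2)
    b = cross_bispectrum(spec, fp, channels=[channel])
    n1 = three_norm(spec, fp.f1, channels=[channel])
    n2 = three_norm(spec, fp.f2, channels=[channel])
    n3 = three_norm(spec, fp.f3, channels=[channel])
    return complex(bicoherence(b, n1, n2, n3).values[0, 0, 0])


def bicoherence_plane(
    spec: SpectralTensor,
    f1_grid: np.ndarray,
    f2_grid: np.ndarray,
    channels: np.ndarray | list[int] | None = None,
) -> BicoherencePlane:
    """Evaluate |auto-bicoherence| for every channel on a (f1, f2) grid.

    Vectorized over the grid per channel; grid points with ``f1 + f2`` above
    Nyquist are NaN.
    """
    f1_grid = np.asarray(f1_grid, dtype=float)
    f2_grid = np.asarray(f2_grid, dtype=float)
    if channels is None:
        channels = np.arange(spec.n_channels)
    channels = np.asarray(channels, dtype=int)
    nyquist = spec.fs / 2.0

    b1 = np.array([freq_to_bin(f, spec) for f in f1_grid])
    b2 = np.array([freq_to_bin(f, spec) for f in f2_grid])
    # f3 bins per grid point; invalid above Nyquist
    f3 = f1_grid[:, None] + f2_grid[None, :]
    valid = f3 <= nyquist + 1e-12
    b3 = np.clip(b1[:, None] + b2[None, :], 0, spec.n_bins - 1)

    flat = spec.flat_coeffs()[channels]  # (C, S, bins)
    n_seg = flat.shape[1]
    out = np.full((channels.size, f1_grid.size, f2_grid.size), np.nan)
    norms = np.cbrt((np.abs(flat) ** 3).mean(axis=1))  # (C, bins)
    for ci in range(channels.size):
        x = flat[ci]  # (S, bins)
        x1 = x[:, b1]  # (S, n1)
        x2 = x[:, b2]  # (S, n2)
        x3c = np.conj(x[:, b3])  # (S, n1, n2)
        b = np.einsum("si,sj,sij->ij", x1, x2, x3c, optimize=True) / n_seg
        denom = norms[ci, b1][:, None] * norms[ci, b2][None, :] * norms[ci, b3]
        with np.errstate(divide="ignore", invalid="ignore"):
            mag = np.abs(b) / denom
        mag[~valid | (denom == 0)] = np.nan
        out[ci] = mag
    labels = [spec.channel_labels[c] for c in channels] if spec.channel_labels else None
    return BicoherencePlane(
        values=out, f1_grid=f1_grid, f2_grid=f2_grid, channel_labels=labels
    )


def discrete_laplacian(plane: BicoherencePlane, h: float) -> np.ndarray:
    """Five-point Laplace stencil with offset ``h`` applied to each channel plane.

    ``lap(f1, f2) = (v(f1-h, f2) + v(f1+h, f2) + v(f1, f2-h) + v(f1, f2+h)
    - 4 v(f1, f2)) / h**2``.  Points lacking any neighbor on the grid are NaN
    (unevaluated), never zero-filled.  ``h`` must be an integer multiple of
    the grid step.
    """
    step = plane.grid_step
    k = h / step
    if abs(k - round(k)) > 1e-9 or round(k) < 1:
        raise GridError(f"offset h={h} is not a positive multiple of grid step {step}")
    k = int(round(k))
    v = plane.values
    lap = np.full_like(v, np.nan)
    lap[:, k:-k, k:-k] = (
        v[:, : -2 * k, k:-k]
        + v[:, 2 * k :, k:-k]
        + v[:, k:-k, : -2 * k]
        + v[:, k:-k, 2 * k :]
        - 4.0 * v[:, k:-k, k:-k]
    ) / h**2
    return lap


def select_alpha(
    plane: BicoherencePlane,
    band: tuple[float, float] = DEFAULT_BAND,
    h: float = DEFAULT_STENCIL_OFFSET,
) -> AlphaSelection:
    """Pick the channel and fundamental frequency with the most peak-like
    bicoherence on the ``f2 = 2 f1`` diagonal within ``band`` (inclusive).

    The score is the negated Laplacian-filtered magnitude, so isolated peaks
    beat smooth ridges even when the ridge has larger raw bicoherence.  Ties
    are broken deterministically: lowest frequency first, then lowest channel
    index.
    """
    lap = discrete_laplacian(plane, h)
    lo, hi = band
    tol = 1e-9
    candidates = []
    for fi, f in enumerate(plane.f1_grid):
        if f < lo - tol or f > hi + tol:
            continue
        # tied second axis: f2 = 2 f
        f2_idx = np.where(np.abs(plane.f2_grid - 2.0 * f) < tol)[0]
        if f2_idx.size == 0:
            continue
        for ci in range(plane.values.shape[0]):
            score = -lap[ci, fi, f2_idx[0]]
            if np.isfinite(score):
                candidates.append((score, f, ci))
    if not candidates:
        raise ConfigurationError(
            "no evaluable (f, 2f) grid point in the requested band; "
            "the grid must cover [band_lo - h, 2*band_hi + h]"
        )
    best_score = max(c[0] for c in candidates)
    best = min(c for c in candidates if c[0] == best_score)
    label = plane.channel_labels[best[2]] if plane.channel_labels else None
    return AlphaSelection(
        channel=best[2], f_max=best[1], score=best[0], channel_label=label
    )
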