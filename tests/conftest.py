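"""Shared fixtures and independent reference oracles.

The oracle helpers here deliberately re-derive quantities with slow, direct
loops so they stay independent of the vectorized implementation paths they
are used to check.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pytest

from tacb import (
    EpochedRecording,
    SegmentationConfig,
    SpectralTensor,
    fourier_coefficients,
    simulate_recording,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_rec(rng):
    """Random 4-channel recording: 6 epochs of 128 samples at 64 Hz."""
    return EpochedRecording(data=rng.standard_normal((4, 6, 128)), fs=64.0)


@pytest.fixture
def small_spec(small_rec):
    return fourier_coefficients(
        small_rec, SegmentationConfig(segment_len=64, overlap_fraction=0.5)
    )


@pytest.fixture(scope="session")
def coupled_spec():
    """3-source simulation, 8 sensors, 60 epochs: strong genuine triple coupling."""
    rec = simulate_recording("three_sources", n_sensors=8, n_epochs=60, seed=7)
    return fourier_coefficients(rec, SegmentationConfig(segment_len=256))


@pytest.fixture(scope="session")
def null_spec():
    """Independent white-noise channels: the global null."""
    rng = np.random.default_rng(99)
    rec = EpochedRecording(data=rng.standard_normal((6, 60, 512)), fs=256.0)
    return fourier_coefficients(rec, SegmentationConfig(segment_len=256))


# ---------------------------------------------------------------------------
# oracles


def dft_oracle(x: np.ndarray) -> np.ndarray:
    """Direct O(N^2) DFT of a real 1-D signal (positive-frequency half)."""
    n = x.size
    k = np.arange(n // 2 + 1)
    angles = -2j * np.pi * np.outer(k, np.arange(n)) / n
    return np.exp(angles) @ x


def bispectrum_loop_oracle(
    spec: SpectralTensor, b1: int, b2: int, b3: int
) -> np.ndarray:
    """Explicit loop-and-mean estimate of the cross-bispectrum tensor."""
    flat = spec.flat_coeffs()
    c, s, _ = flat.shape
    out = np.zeros((c, c, c), dtype=complex)
    for i in range(c):
        for j in range(c):
            for k in range(c):
                acc = 0.0 + 0.0j
                for m in range(s):
                    acc += flat[i, m, b1] * flat[j, m, b2] * np.conj(flat[k, m, b3])
                out[i, j, k] = acc / s
    return out


def antisym_loop_oracle(values: np.ndarray, i: int, j: int, k: int) -> complex:
    """Signed sum over all six index permutations, by explicit enumeration."""
    base = (i, j, k)
    total = 0.0 + 0.0j
    for perm in permutations(range(3)):
        inversions = sum(
            1 for a in range(3) for b in range(a + 1, 3) if perm[a] > perm[b]
        )
        sign = -1 if inversions % 2 else 1
        total += sign * values[base[perm[0]], base[perm[1]], base[perm[2]]]
    return total


def laplacian_stencil_oracle(plane: np.ndarray, k: int, h: float) -> np.ndarray:
    """Pointwise five-point stencil on one 2-D plane; NaN where out of range."""
    n1, n2 = plane.shape
    out = np.full((n1, n2), np.nan)
    for a in range(n1):
        for b in range(n2):
            if a - k < 0 or a + k >= n1 or b - k < 0 or b + k >= n2:
                continue
            out[a, b] = (
                plane[a - k, b]
                + plane[a + k, b]
                + plane[a, b - k]
                + plane[a, b + k]
                - 4.0 * plane[a, b]
            ) / h**2
    return out


def make_spectral_tensor(coeffs: np.ndarray, fs: float = 64.0) -> SpectralTensor:
    """Wrap raw coefficients (channels, epochs, segments, bins) for direct tests."""
    seg_len = 2 * (coeffs.shape[-1] - 1)
    return SpectralTensor(
        coeffs=np.asarray(coeffs, dtype=complex),
        fs=fs,
        freq_resolution=fs / seg_len,
        channel_labels=[f"ch{i:03d}" for i in range(coeffs.shape[0])],
    )
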