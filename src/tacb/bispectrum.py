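"""Cross-bispectrum, three-norm bicoherence and the totally antisymmetric part.

The cross-bispectrum at a frequency pair ``(f1, f2)`` couples Fourier
coefficients at ``f1``, ``f2`` and ``f1 + f2``; its totally antisymmetric
combination over the three channel indices statistically vanishes unless at
least three distinct sources interact, because any mixture of at most two
sources (or of independent pairwise-interacting systems) contributes only
index-symmetric terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

from .errors import ConfigurationError, FrequencyError
from .spectral import SpectralTensor, freq_to_bin

__all__ = [
    "FrequencyPair",
    "BispectrumTensor",
    "ThreeNormVector",
    "BicoherenceTensor",
    "PairwiseAntisymMatrix",
    "TACBTensor",
    "cross_bispectrum",
    "three_norm",
    "bicoherence",
    "antisymmetrize_pairwise",
    "tacb",
    "tacb_from_spectra",
]

#: Signed permutations defining the total antisymmetrization: the sum of the
#: three even permutations minus the sum of the three odd ones.
_EVEN_PERMS = ((0, 1, 2), (2, 0, 1), (1, 2, 0))
_ODD_PERMS = ((1, 0, 2), (2, 1, 0), (0, 2, 1))


@dataclass(frozen=True)
class FrequencyPair:
    """Frequency pair ``(f1, f2)`` with the derived third frequency ``f1 + f2``."""

    f1: float
    f2: float

    def __post_init__(self) -> None:
        if self.f1 < 0 or self.f2 < 0:
            raise FrequencyError("frequencies must be nonnegative")

    @property
    def f3(self) -> float:
        return self.f1 + self.f2


@dataclass
class BispectrumTensor:
    """Complex ``B[i, j, k]`` over channel triples at a fixed frequency pair."""

    values: np.ndarray
    pair: FrequencyPair
    n_segments_averaged: int
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass
class ThreeNormVector:
    """Per-channel three-norm ``(mean |X(f)|^3)^(1/3)`` at one frequency."""

    values: np.ndarray
    f: float


@dataclass
class BicoherenceTensor:
    """Cross-bispectrum normalized by the product of three-norms; |b| <= 1.

    Entries where any norm vanishes are undefined: NaN in ``values`` and True
    in ``undefined``.
    """

    values: np.ndarray
    pair: FrequencyPair
    undefined: np.ndarray


@dataclass
class PairwiseAntisymMatrix:
    """Antisymmetric combination over the last two channel indices, per (i, j)."""

    values: np.ndarray
    pair: FrequencyPair


@dataclass
class TACBTensor:
    """Totally antisymmetric cross-bispectrum, stored per unordered triple i<j<k.

    The full third-order tensor is antisymmetric under any index swap and
    vanishes on any entry with a repeated index, so the ``i < j < k`` entries
    carry all information (a factor-6 memory saving); ``expand`` rebuilds the
    full tensor from them.
    """

    n_channels: int
    triples: np.ndarray  # (n_triples, 3) int, rows sorted i < j < k
    values: np.ndarray  # (n_triples,) complex
    pair: FrequencyPair
    channel_labels: list[str] = field(default_factory=list)

    @property
    def n_triples(self) -> int:
        return self.triples.shape[0]

    def expand(self) -> np.ndarray:
        """Full antisymmetric ``(n, n, n)`` tensor with zeros on repeated indices."""
        full = np.zeros((self.n_channels,) * 3, dtype=complex)
        for a, b, c in _EVEN_PERMS:
            idx = (self.triples[:, a], self.triples[:, b], self.triples[:, c])
            full[idx] = self.values
        for a, b, c in _ODD_PERMS:
            idx = (self.triples[:, a], self.triples[:, b], self.triples[:, c])
            full[idx] = -self.values
        return full


def canonical_triples(n_channels: int) -> np.ndarray:
    """All unordered channel triples ``i < j < k`` (no repeated indices)."""
    return np.asarray(list(combinations(range(n_channels), 3)), dtype=int).reshape(-1, 3)


def _resolve_bins(spec: SpectralTensor, fp: FrequencyPair) -> tuple[int, int, int]:
    if fp.f3 > spec.fs / 2.0 + 1e-12:
        raise FrequencyError(
            f"f1 + f2 = {fp.f3} Hz exceeds Nyquist {spec.fs / 2.0} Hz"
        )
    return (
        freq_to_bin(fp.f1, spec),
        freq_to_bin(fp.f2, spec),
        freq_to_bin(fp.f3, spec),
    )


def cross_bispectrum(
    spec: SpectralTensor,
    fp: FrequencyPair,
    channels: np.ndarray | list[int] | None = None,
) -> BispectrumTensor:
    """Average of ``X_i(f1) X_j(f2) conj(X_k(f1+f2))`` over all segments.

    The expectation is approximated by a uniform average over the segments of
    all epochs.
    """
    b1, b2, b3 = _resolve_bins(spec, fp)
    flat = spec.flat_coeffs()
    labels = list(spec.channel_labels)
    if channels is not None:
        channels = np.asarray(channels, dtype=int)
        flat = flat[channels]
        labels = [labels[c] for c in channels]
    x1 = flat[:, :, b1]
    x2 = flat[:, :, b2]
    x3c = np.conj(flat[:, :, b3])
    n_seg = x1.shape[1]
    values = np.einsum("is,js,ks->ijk", x1, x2, x3c, optimize=True) / n_seg
    return BispectrumTensor(
        values=values, pair=fp, n_segments_averaged=n_seg, channel_labels=labels
    )


def three_norm(
    spec: SpectralTensor,
    f: float,
    channels: np.ndarray | list[int] | None = None,
) -> ThreeNormVector:
    """Cube root of the mean cubed coefficient magnitude, per channel."""
    b = freq_to_bin(f, spec)
    flat = spec.flat_coeffs()
    if channels is not None:
        flat = flat[np.asarray(channels, dtype=int)]
    mags = np.abs(flat[:, :, b])
    return ThreeNormVector(values=np.cbrt((mags**3).mean(axis=1)), f=f)


def bicoherence(
    bisp: BispectrumTensor,
    n1: ThreeNormVector,
    n2: ThreeNormVector,
    n3: ThreeNormVector,
) -> BicoherenceTensor:
    """Normalize a cross-bispectrum by the outer product of three-norms.

    Entries with a vanishing norm are flagged as undefined (NaN), never
    silently set to zero.
    """
    denom = np.einsum("i,j,k->ijk", n1.values, n2.values, n3.values)
    undefined = denom == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        values = bisp.values / denom
    values[undefined] = np.nan
    return BicoherenceTensor(values=values, pair=bisp.pair, undefined=undefined)


def antisymmetrize_pairwise(bisp: BispectrumTensor) -> PairwiseAntisymMatrix:
    """Difference ``B[i, i, j] - B[i, j, i]`` for every channel pair (i, j)."""
    v = bisp.values
    if v.ndim != 3 or len({v.shape[0], v.shape[1], v.shape[2]}) != 1:
        raise ConfigurationError(f"expected a cubic tensor, got shape {v.shape}")
    values = np.einsum("iij->ij", v) - np.einsum("iji->ij", v)
    return PairwiseAntisymMatrix(values=values, pair=bisp.pair)


def tacb(bisp: BispectrumTensor) -> TACBTensor:
    """Signed sum of the cross-bispectrum over all six channel-index permutations.

    Warns when ``f1 == f2``: the cross-bispectrum is then symmetric in its
    first two indices and the result is identically zero.
    """
    if bisp.pair.f1 == bisp.pair.f2:
        warnings.warn(
            "f1 == f2: the totally antisymmetric part is identically zero",
            stacklevel=2,
        )
    v = bisp.values
    # transpose(v, p)[i,j,k] == v[(i,j,k)[p[0]], (i,j,k)[p[1]], (i,j,k)[p[2]]]
    full = np.zeros_like(v)
    for perm in _EVEN_PERMS:
        full += np.transpose(v, perm)
    for perm in _ODD_PERMS:
        full -= np.transpose(v, perm)
    triples = canonical_triples(bisp.n_channels)
    values = full[triples[:, 0], triples[:, 1], triples[:, 2]]
    return TACBTensor(
        n_channels=bisp.n_channels,
        triples=triples,
        values=values,
        pair=bisp.pair,
        channel_labels=list(bisp.channel_labels),
    )


def tacb_from_spectra(
    spec: SpectralTensor,
    fp: FrequencyPair,
    channels: np.ndarray | list[int] | None = None,
) -> TACBTensor:
    """Convenience: cross-bispectrum followed by total antisymmetrization."""
    return tacb(cross_bispectrum(spec, fp, channels=channels))


def signed_permutation_sum(values: np.ndarray, i: int, j: int, k: int) -> complex:
    """Brute-force reference: sum of sign(pi) * B[pi(i), pi(j), pi(k)] over S3.

    Kept as a readable cross-check of the vectorized antisymmetrization; used
    by the test-suite oracles and intentionally independent of :func:`tacb`.
    """
    total = 0.0 + 0.0j
    base = (i, j, k)
    for perm in permutations(range(3)):
        sign = _perm_sign(perm)
        total += sign * values[base[perm[0]], base[perm[1]], base[perm[2]]]
    return total


def _perm_sign(perm: tuple[int, ...]) -> int:
    inversions = sum(
        1 for a in range(3) for b in range(a + 1, 3) if perm[a] > perm[b]
    )
    return -1 if inversions % 2 else 1
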