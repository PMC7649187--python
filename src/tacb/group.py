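"""Group-level aggregation of per-subject scaled coupling values.

Per-subject Q values (one per unordered channel triple) are averaged across
subjects into a triple map, marginalized over two channel indices into a
per-channel map, and compared between groups with a label-permutation test
followed by Benjamini-Hochberg correction across channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bispectrum import canonical_triples
from .errors import ValidationError
from .nullstats import correct_multiple

__all__ = [
    "SubjectQSet",
    "GroupMaps",
    "subject_average",
    "channel_marginal",
    "fixed_channel_slice",
    "group_permutation_test",
]


@dataclass
class SubjectQSet:
    """Per-triple nonnegative Q values of one subject on a fixed montage."""

    subject: str
    n_channels: int
    q: np.ndarray
    channel_labels: list[str] = field(default_factory=list)
    group: str | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        expected = canonical_triples(self.n_channels).shape[0]
        if self.q.size != expected:
            raise ValidationError(
                f"subject {self.subject}: {self.q.size} Q values for "
                f"{self.n_channels} channels (expected {expected} triples)"
            )
        if np.any(self.q < 0) or not np.isfinite(self.q).all():
            raise ValidationError(f"subject {self.subject}: Q must be finite and >= 0")

    def full_tensor(self) -> np.ndarray:
        """Symmetric (n, n, n) tensor: Q on all 6 permutations, 0 on repeats."""
        full = np.zeros((self.n_channels,) * 3)
        t = canonical_triples(self.n_channels)
        for a, b, c in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
            full[t[:, a], t[:, b], t[:, c]] = self.q
        return full


@dataclass
class GroupMaps:
    """Subject-averaged triple map and its per-channel marginal."""

    triple_average: np.ndarray  # canonical, per triple i<j<k
    channel_marginal: np.ndarray  # per channel
    n_channels: int
    channel_labels: list[str] = field(default_factory=list)


def _check_montage(qsets: list[SubjectQSet]) -> None:
    if not qsets:
        raise ValidationError("need at least one subject")
    ref = qsets[0]
    for qs in qsets[1:]:
        if qs.n_channels != ref.n_channels or (
            qs.channel_labels
            and ref.channel_labels
            and qs.channel_labels != ref.channel_labels
        ):
            raise ValidationError(
                f"montage mismatch between subjects {ref.subject} and {qs.subject}"
            )


def subject_average(qsets: list[SubjectQSet]) -> np.ndarray:
    """Elementwise mean of per-triple Q over subjects (canonical i<j<k order)."""
    _check_montage(qsets)
    return np.mean([qs.q for qs in qsets], axis=0)


def channel_marginal(qsets: list[SubjectQSet]) -> np.ndarray:
    """Per-channel mean ``(1 / (M N^2)) sum_{m,j,k} Q[i,j,k,m]``.

    The prefactor divides by the full ``N^2`` partner count even though
    entries with repeated indices are identically zero, so the marginal sits
    slightly below the off-diagonal mean by construction.
    """
    _check_montage(qsets)
    n = qsets[0].n_channels
    m = len(qsets)
    acc = np.zeros(n)
    t = canonical_triples(n)
    for qs in qsets:
        # each triple containing channel i contributes 2 entries to sum_{j,k}
        np.add.at(acc, t[:, 0], 2.0 * qs.q)
        np.add.at(acc, t[:, 1], 2.0 * qs.q)
        np.add.at(acc, t[:, 2], 2.0 * qs.q)
    return acc / (m * n**2)


def group_maps(qsets: list[SubjectQSet]) -> GroupMaps:
    return GroupMaps(
        triple_average=subject_average(qsets),
        channel_marginal=channel_marginal(qsets),
        n_channels=qsets[0].n_channels,
        channel_labels=list(qsets[0].channel_labels),
    )


def fixed_channel_slice(
    triple_average: np.ndarray, n_channels: int
) -> tuple[np.ndarray, int]:
    """Matrix over (i, j) at the third channel of the maximizing triple.

    ``k0`` is the last index of the globally maximal triple entry of the full
    (symmetric) tensor; ties resolve to the lowest flat index.  The returned
    matrix keeps its structural zeros wherever an index equals ``k0``.
    """
    t = canonical_triples(n_channels)
    full = np.zeros((n_channels,) * 3)
    for a, b, c in ((0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)):
        full[t[:, a], t[:, b], t[:, c]] = triple_average
    k0 = int(np.unravel_index(np.argmax(full), full.shape)[2])
    return full[:, :, k0], k0


def group_permutation_test(
    qsets_a: list[SubjectQSet],
    qsets_b: list[SubjectQSet],
    n_perm: int = 10000,
    seed: int | np.random.Generator | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided label-permutation test of the per-channel marginal difference.

    The statistic per channel is ``mean_A(marginal) - mean_B(marginal)``; the
    null is built by permuting group labels, with the add-one convention
    ``p = (1 + #{|perm| >= |observed|}) / (1 + n_perm)`` so p is never zero.
    P-values are Benjamini-Hochberg corrected across channels.
    """
    if len(qsets_a) < 2 or len(qsets_b) < 2:
        raise ValidationError("need at least 2 subjects per group")
    _check_montage(qsets_a + qsets_b)
    if n_perm < 100:
        warnings.warn(f"n_perm={n_perm} is low; p-values will be coarse", stacklevel=2)
    rng = np.random.default_rng(seed)

    per_subject = np.stack(
        [channel_marginal([qs]) for qs in qsets_a + qsets_b]
    )  # (n_subjects, n_channels)
    n_a = len(qsets_a)
    n_tot = per_subject.shape[0]
    observed = per_subject[:n_a].mean(axis=0) - per_subject[n_a:].mean(axis=0)

    exceed = np.zeros(per_subject.shape[1])
    for _ in range(n_perm):
        idx = rng.permutation(n_tot)
        stat = per_subject[idx[:n_a]].mean(axis=0) - per_subject[idx[n_a:]].mean(axis=0)
        exceed += np.abs(stat) >= np.abs(observed)
    pvals = (1.0 + exceed) / (1.0 + n_perm)
    reject, threshold = correct_multiple(pvals, method="benjamini_hochberg", alpha=alpha)

    labels = qsets_a[0].channel_labels or [
        f"ch{i:03d}" for i in range(per_subject.shape[1])
    ]
    return pd.DataFrame(
        {
            "channel": labels,
            "mean_a": per_subject[:n_a].mean(axis=0),
            "mean_b": per_subject[n_a:].mean(axis=0),
            "difference": observed,
            "p": pvals,
            "significant": reject,
        }
    )
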