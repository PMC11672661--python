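"""Parameter-matrix clustering: column centering, Ward linkage, group cuts,
the stratified validation holdout, and group composition summaries.

Ward's method is implemented directly on cluster means and sizes: at each
step the pair of clusters whose merge least increases the total
within-cluster sum of squares is joined,

    delta(A, B) = |A| |B| / (|A| + |B|) * ||mean(A) - mean(B)||^2 ,

with ties broken by the lexicographically smallest pair of cluster indices
(leaves are 0..n-1, the t-th merge creates cluster n+t) so that the
dendrogram is reproducible.  Heights are the delta values, which are
non-decreasing along the merge sequence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import SystemRecord

__all__ = [
    "Dendrogram",
    "GroupAssignment",
    "center_columns",
    "ward_linkage",
    "cut_to_groups",
    "stratified_holdout",
    "element_occurrence",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge history.

    ``merges[t] = (left, right, height, size)`` joins clusters ``left`` and
    ``right`` (scipy-style indices) into cluster ``n_leaves + t``.
    """

    n_leaves: int
    merges: tuple[tuple[int, int, float, int], ...]

    def __post_init__(self) -> None:
        if len(self.merges) != self.n_leaves - 1:
            raise ValueError("a dendrogram over n leaves has n-1 merges")

    def members(self) -> list[set[int]]:
        """Leaf sets of every node, indexed 0..2n-2."""
        sets = [{i} for i in range(self.n_leaves)]
        for left, right, _, _ in self.merges:
            sets.append(sets[left] | sets[right])
        return sets


@dataclass(frozen=True)
class GroupAssignment:
    """A k-group labelling together with its train/validation split."""

    labels: dict[str, int]
    k: int
    train_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.validation_ids)
        if overlap:
            raise ValueError(f"ids in both splits: {sorted(overlap)[:5]}")
        if set(self.train_ids) | set(self.validation_ids) != set(self.labels):
            raise ValueError("train + validation must cover all labelled ids")
        if any(not 0 <= g < self.k for g in self.labels.values()):
            raise ValueError("labels must lie in 0..k-1")


def center_columns(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Subtract each column's mean; returns (centered, means)."""
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("expected a non-empty 2-D matrix")
    means = X.mean(axis=0)
    return X - means, means


def ward_linkage(points: np.ndarray) -> Dendrogram:
    """Ward minimum-variance agglomeration of the rows of ``points``."""
    X = np.asarray(points, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least two points")
    n = X.shape[0]
    means = {i: X[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    merges = []
    for t in range(n - 1):
        best = None
        active = sorted(means)
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                diff = means[i] - means[j]
                delta = sizes[i] * sizes[j] / (sizes[i] + sizes[j]) * float(diff @ diff)
                if best is None or delta < best[0] - 1e-15 * max(abs(best[0]), 1.0):
                    best = (delta, i, j)
        delta, i, j = best
        new = n + t
        size = sizes[i] + sizes[j]
        means[new] = (sizes[i] * means[i] + sizes[j] * means[j]) / size
        sizes[new] = size
        del means[i], means[j], sizes[i], sizes[j]
        merges.append((i, j, delta, size))
    return Dendrogram(n_leaves=n, merges=tuple(merges))


def cut_to_groups(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Labels (0..k-1) for the k clusters left after undoing the last k-1 merges.

    Group indices are assigned by decreasing cluster size; ties go to the
    cluster containing the smallest leaf index.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in 1..{n}, got {k}")
    sets = dendrogram.members()
    # nodes alive after performing the first n-k merges
    alive = set(range(n))
    for t in range(n - k):
        left, right, _, _ = dendrogram.merges[t]
        alive -= {left, right}
        alive.add(n + t)
    clusters = sorted((sets[node] for node in alive),
                      key=lambda s: (-len(s), min(s)))
    labels = np.empty(n, dtype=int)
    for g, cluster in enumerate(clusters):
        labels[list(cluster)] = g
    return labels


def stratified_holdout(labels: Sequence[int], fraction: float = 0.10,
                       seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Per-cluster uniform random holdout; returns (train_idx, validation_idx).

    Each cluster of size s contributes round-half-away-from-zero(fraction*s)
    validation members, floored at 1 for clusters of size >= 2 and 0 for
    singletons.  Deterministic for a fixed seed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    val: list[int] = []
    for g in np.unique(labels):
        idx = np.flatnonzero(labels == g)
        s = len(idx)
        n_hold = int(np.floor(fraction * s + 0.5))
        if s >= 2:
            n_hold = max(n_hold, 1)
        else:
            n_hold = 0
        n_hold = min(n_hold, s - 1)  # never empty a cluster
        if n_hold > 0:
            val.extend(rng.choice(idx, size=n_hold, replace=False))
    val_idx = np.array(sorted(val), dtype=int)
    train_idx = np.setdiff1d(np.arange(len(labels)), val_idx)
    return train_idx, val_idx


def element_occurrence(members: Sequence[SystemRecord]) -> dict[str, float]:
    """Average atoms of each element per member molecule, to 2 decimals."""
    if not members:
        raise ValueError("empty member list")
    totals: dict[str, int] = {}
    for rec in members:
        for el, n in rec.composition.items():
            totals[el] = totals.get(el, 0) + n
    return {el: round(count / len(members), 2) for el, count in sorted(totals.items())}
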