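"""Kennard-Stone representative sampling and the three-way data split.

Kennard-Stone is a deterministic max-min-distance design: the first two
picks are the most distant pair, and each later pick maximizes its minimum
Euclidean distance to everything already selected. Splitting train /
development / test this way spreads each subset across descriptor space
rather than leaving any region to chance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .descriptors import DescriptorMatrix


@dataclass
class SplitAssignment:
    """Disjoint train/dev/test id lists covering the full compound set."""

    train_ids: list[str]
    dev_ids: list[str]
    test_ids: list[str]
    method: str = "kennard_stone_sequential"
    distance_kind: str = "euclidean"
    deterministic: bool = True  # KS uses no randomness

    def subset_of(self, cid: str) -> str:
        for name, ids in (("train", self.train_ids), ("dev", self.dev_ids),
                          ("test", self.test_ids)):
            if cid in ids:
                return name
        raise KeyError(cid)


def kennard_stone_order(x: np.ndarray, n_select: int) -> list[int]:
    """Kennard-Stone selection order as row indices into ``x``.

    Ties at any step (coincident max-min distances) are broken by the lowest
    original row index; of the initial maximally distant pair the lower index
    is emitted first. Fully deterministic.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[0]
    if not 2 <= n_select <= n:
        raise ValueError(f"n_select must be in [2, {n}], got {n_select}")
    d = squareform(pdist(x, metric="euclidean"))
    # argmax on the flattened matrix lands on the lexicographically smallest
    # (i, j) among tied maxima, i.e. the lowest-index pair
    i, j = np.unravel_index(np.argmax(d), d.shape)
    selected = [min(i, j), max(i, j)]
    min_dist = np.minimum(d[selected[0]], d[selected[1]])
    remaining = np.ones(n, dtype=bool)
    remaining[selected] = False
    while len(selected) < n_select:
        masked = np.where(remaining, min_dist, -np.inf)
        nxt = int(np.argmax(masked))  # argmax takes the first (lowest-index) tie
        selected.append(nxt)
        remaining[nxt] = False
        min_dist = np.minimum(min_dist, d[nxt])
    return selected


def kennard_stone(m: DescriptorMatrix, n_select: int) -> list[str]:
    """Kennard-Stone selection of ``n_select`` compound ids, in pick order."""
    idx = kennard_stone_order(m.values, n_select)
    return [m.compound_ids[i] for i in idx]


def three_way_split(
    m: DescriptorMatrix, sizes: tuple[int, int, int]
) -> SplitAssignment:
    """Sequential Kennard-Stone split into train / development / test.

    KS picks ``n_train`` compounds from the full matrix as the training set;
    a second KS pass over the remainder picks ``n_dev`` for development; the
    residue is the test set. Sizes must sum to the number of compounds.
    """
    n_train, n_dev, n_test = sizes
    if n_train + n_dev + n_test != m.n_compounds:
        raise ValueError(
            f"sizes {sizes} sum to {n_train + n_dev + n_test}, "
            f"but the matrix has {m.n_compounds} compounds"
        )
    train_ids = kennard_stone(m, n_train)
    rest_ids = [c for c in m.compound_ids if c not in set(train_ids)]
    rest = m.subset_rows(rest_ids)
    if n_dev >= 2:
        dev_ids = kennard_stone(rest, n_dev)
    elif n_dev == 1:
        # degenerate: KS needs >= 2 picks; take the point farthest from the mean
        centered = rest.values - rest.values.mean(axis=0)
        dev_ids = [rest_ids[int(np.argmax((centered ** 2).sum(axis=1)))]]
    else:
        dev_ids = []
    test_ids = [c for c in rest_ids if c not in set(dev_ids)]
    return SplitAssignment(train_ids=train_ids, dev_ids=dev_ids, test_ids=test_ids)
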