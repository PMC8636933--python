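"""Tanimoto similarity for continuous and dichotomous descriptors.

For binary fingerprints the classic bit-count form is used,
``S = c / (a + b - c)`` with ``a``/``b`` the on-bit counts of each molecule
and ``c`` the shared on-bits. For continuous descriptor vectors the
generalized form ``S = x.y / (|x|^2 + |y|^2 - x.y)`` applies; it ranges over
[-1/3, 1]. On 0/1 vectors the two forms coincide.

Within-class pairwise similarity summaries quantify how well a
representation clusters carcinogens (or non-carcinogens) together — the
discrimination-power analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np

from .descriptors import BINARY, DescriptorMatrix


@dataclass
class SimilaritySummary:
    """Mean/sd of all unordered within-class Tanimoto pairs."""

    class_label: object
    n_pairs: int
    mean: float
    sd: float
    values: np.ndarray | None = None


def _check_pair(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"vector length mismatch: {x.shape} vs {y.shape}")
    return x, y


def tanimoto_continuous(x: Sequence[float], y: Sequence[float]) -> float:
    """Generalized Tanimoto coefficient for continuous descriptor vectors.

    Returns ``x.y / (|x|^2 + |y|^2 - x.y)``. When both vectors are all-zero
    the ratio is 0/0; by convention 0.0 is returned with a warning ("no
    evidence of similarity").
    """
    x, y = _check_pair(x, y)
    num = float(x @ y)
    denom = float(x @ x) + float(y @ y) - num
    if denom == 0.0 and num == 0.0:
        warnings.warn("both vectors all-zero; Tanimoto defined as 0.0", stacklevel=2)
        return 0.0
    return num / denom


def tanimoto_binary(x: Sequence[float], y: Sequence[float]) -> float:
    """Tanimoto coefficient for bit vectors: ``c / (a + b - c)``."""
    x, y = _check_pair(x, y)
    if not (np.isin(x, (0, 1)).all() and np.isin(y, (0, 1)).all()):
        raise ValueError("tanimoto_binary requires 0/1 vectors")
    a, b, c = x.sum(), y.sum(), (x * y).sum()
    denom = a + b - c
    if denom == 0:
        warnings.warn("both fingerprints empty; Tanimoto defined as 0.0", stacklevel=2)
        return 0.0
    return float(c / denom)


def pairwise_tanimoto(m: DescriptorMatrix, ids: Sequence[str]) -> np.ndarray:
    """All unordered-pair coefficients among ``ids``, matched to ``m.kind``."""
    sub = m.subset_rows(list(ids))
    fn = tanimoto_binary if m.kind == BINARY else tanimoto_continuous
    return np.array([fn(sub.values[i], sub.values[j])
                     for i, j in combinations(range(sub.n_compounds), 2)])


def within_class_similarity(
    m: DescriptorMatrix,
    labels: Sequence[int],
    class_label: int,
    keep_values: bool = False,
) -> SimilaritySummary:
    """Pairwise Tanimoto summary over the compounds of one class.

    ``labels`` aligns with ``m.compound_ids``. Self-pairs are excluded; the
    number of pairs is k(k-1)/2 for k class members. The standard deviation
    is the population sd over pairs.
    """
    labels = np.asarray(labels)
    if labels.shape[0] != m.n_compounds:
        raise ValueError("labels must align with the descriptor matrix rows")
    ids = [c for c, l in zip(m.compound_ids, labels) if l == class_label]
    if len(ids) < 2:
        raise ValueError(f"class {class_label!r} has {len(ids)} member(s); need >= 2")
    vals = pairwise_tanimoto(m, ids)
    return SimilaritySummary(
        class_label=class_label,
        n_pairs=len(vals),
        mean=float(vals.mean()),
        sd=float(vals.std()),
        values=vals if keep_values else None,
    )
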