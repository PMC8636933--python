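"""Synthetic labeled descriptor datasets with controllable class separation.

The generator emulates the shape of a curated rodent-bioassay compound set:
863 compounds at roughly a 65/35 carcinogen/non-carcinogen split by default,
with a MACCS-like binary fingerprint block (Bernoulli bits) and a
Mol2vec-like continuous block (Gaussian features). A chosen number of
"informative" features differ between classes — by a bit-probability gap
for the binary block and a mean shift (in sd units) for the continuous
block — while the rest are class-independent noise. Everything is fully
determined by the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptors import BINARY, CONTINUOUS, DescriptorMatrix


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic dataset draw.

    ``effect_size`` acts as the bit-probability gap for informative binary
    features (base rate 0.3 vs 0.3 + gap) and as the class mean shift in sd
    units for informative continuous features.
    """

    n_compounds: int = 863
    positive_fraction: float = 0.65
    n_binary_features: int = 166
    n_continuous_features: int = 300
    n_informative: int = 20
    effect_size: float = 0.5
    binary_base_rate: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.positive_fraction < 1.0:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.n_informative > min(self.n_binary_features, self.n_continuous_features):
            raise ValueError("n_informative exceeds a feature-block size")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0.0 < self.binary_base_rate < 1.0:
            raise ValueError("binary_base_rate must lie in (0, 1)")
        if self.n_compounds < 2:
            raise ValueError("need at least two compounds")


def generate_synthetic(
    spec: SyntheticSpec,
) -> tuple[DescriptorMatrix, DescriptorMatrix, np.ndarray]:
    """Draw one dataset: (binary matrix, continuous matrix, 0/1 labels).

    The positive count is ``round(positive_fraction * n_compounds)`` exactly;
    labels are shuffled so classes are interleaved. Informative features
    occupy the first ``n_informative`` columns of each block.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_compounds
    n_pos = int(round(spec.positive_fraction * n))
    labels = np.zeros(n, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    ids = [f"syn_{i:04d}" for i in range(n)]

    # informative bits: Bernoulli(base) for negatives, Bernoulli(base + gap)
    # for positives; the gap saturates so probabilities stay in [0, 1]
    bit_p = np.full((n, spec.n_binary_features), spec.binary_base_rate)
    bit_gap = min(spec.effect_size, 1.0 - spec.binary_base_rate)
    bit_p[np.ix_(labels == 1, np.arange(spec.n_informative))] = (
        spec.binary_base_rate + bit_gap
    )
    binary = (rng.random((n, spec.n_binary_features)) < bit_p).astype(float)

    continuous = rng.standard_normal((n, spec.n_continuous_features))
    continuous[np.ix_(labels == 1, np.arange(spec.n_informative))] += spec.effect_size

    bmat = DescriptorMatrix(
        ids, binary, [f"bit_{j}" for j in range(spec.n_binary_features)], BINARY,
        metadata={"synthetic": True, "seed": spec.seed},
    )
    cmat = DescriptorMatrix(
        ids, continuous, [f"cont_{j}" for j in range(spec.n_continuous_features)],
        CONTINUOUS, metadata={"synthetic": True, "seed": spec.seed},
    )
    return bmat, cmat, labels


# Fixed fixture: ~30 valid, diverse organic structures with arbitrary 0/1
# fixture labels, for exercising fingerprint and filter code paths offline.
_FIXTURE_SMILES: list[tuple[str, str, int]] = [
    ("fix_00", "C", 0),
    ("fix_01", "CC", 0),
    ("fix_02", "CCO", 0),
    ("fix_03", "CC(=O)O", 0),
    ("fix_04", "c1ccccc1", 1),
    ("fix_05", "Cc1ccccc1", 1),
    ("fix_06", "c1ccc2ccccc2c1", 1),
    ("fix_07", "c1ccc2c(c1)ccc1ccccc12", 1),
    ("fix_08", "CC(C)Cc1ccc(cc1)C(C)C(=O)O", 0),
    ("fix_09", "CC(=O)Oc1ccccc1C(=O)O", 0),
    ("fix_10", "CN1CCC[C@H]1c1cccnc1", 1),
    ("fix_11", "CN(C)CCCN1c2ccccc2Sc2ccccc21", 1),
    ("fix_12", "O=C(O)c1ccccc1O", 0),
    ("fix_13", "NCCc1ccc(O)c(O)c1", 0),
    ("fix_14", "Nc1ccc(cc1)S(N)(=O)=O", 0),
    ("fix_15", "ClC(Cl)=C(Cl)Cl", 1),
    ("fix_16", "ClCCl", 1),
    ("fix_17", "BrCCBr", 1),
    ("fix_18", "Nc1ccccc1", 1),
    ("fix_19", "Nc1ccc2ccccc2c1", 1),
    ("fix_20", "O=[N+]([O-])c1ccccc1", 1),
    ("fix_21", "CCN(CC)N=O", 1),
    ("fix_22", "C1CCCCC1", 0),
    ("fix_23", "C1CCOC1", 0),
    ("fix_24", "CC(C)=CCCC(C)=CCO", 0),
    ("fix_25", "OCC1OC(O)C(O)C(O)C1O", 0),
    ("fix_26", "CC12CCC3c4ccc(O)cc4CCC3C1CCC2O", 1),
    ("fix_27", "O=C1CCCCC1", 0),
    ("fix_28", "CSc1ccccc1", 0),
    ("fix_29", "FC(F)(F)c1ccccc1", 0),
    ("fix_30", "O=C(Nc1ccccc1)c1ccccc1", 0),
]


def make_fixture_smiles() -> list[tuple[str, str, int]]:
    """Fixed list of (compound_id, smiles, fixture_label) triples.

    The structures are valid and span aromatic, aliphatic, halogenated and
    heteroatom-rich chemistry; the labels are arbitrary fixture values, not
    bioassay calls.
    """
    return [tuple(row) for row in _FIXTURE_SMILES]
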