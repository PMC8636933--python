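"""Chemical representations and descriptor preprocessing.

Three representations are supported: 166-key MACCS fingerprints (computed
natively with RDKit), Mol2vec-style substructure embeddings (applied from a
user-supplied embedding table by summing substructure vectors), and arbitrary
external descriptor tables (e.g. Mold2 output) ingested from CSV.

Preprocessing follows a two-step rule used widely in QSAR work: drop
zero-variance descriptors, then drop one of every pair of descriptors whose
pairwise correlation exceeds 0.9.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys
from rdkit.Chem.rdMolDescriptors import GetMorganFingerprint

BINARY = "binary_fingerprint"
CONTINUOUS = "continuous"


class DescriptorError(ValueError):
    """Raised for malformed descriptor input (bad SMILES, bad table, ...)."""


@dataclass
class DescriptorMatrix:
    """Compounds x features numeric matrix with a representation kind.

    Parameters
    ----------
    compound_ids
        Stable, unique identifiers, one per row.
    values
        2-D float array, shape ``(n_compounds, n_features)``.
    feature_names
        One name per column.
    kind
        ``"binary_fingerprint"`` (entries in {0, 1}) or ``"continuous"``.
    metadata
        Free-form provenance notes (e.g. MACCS bit-length convention).
    """

    compound_ids: list[str]
    values: np.ndarray
    feature_names: list[str]
    kind: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.compound_ids = [str(c) for c in self.compound_ids]
        self.feature_names = [str(f) for f in self.feature_names]
        if self.values.ndim != 2:
            raise DescriptorError("values must be a 2-D matrix")
        n, p = self.values.shape
        if n != len(self.compound_ids):
            raise DescriptorError(
                f"row count {n} != number of compound ids {len(self.compound_ids)}"
            )
        if p != len(self.feature_names):
            raise DescriptorError(
                f"column count {p} != number of feature names {len(self.feature_names)}"
            )
        if p == 0:
            raise DescriptorError("matrix must have at least one feature")
        if len(set(self.compound_ids)) != n:
            dupes = sorted({c for c in self.compound_ids if self.compound_ids.count(c) > 1})
            raise DescriptorError(f"duplicate compound ids: {dupes}")
        if self.kind not in (BINARY, CONTINUOUS):
            raise DescriptorError(f"unknown kind {self.kind!r}")
        if self.kind == BINARY and not np.isin(self.values, (0.0, 1.0)).all():
            raise DescriptorError("binary_fingerprint matrix has entries outside {0,1}")
        if not np.isfinite(self.values).all():
            raise DescriptorError("matrix contains non-finite values")

    @property
    def n_compounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.compound_ids, name="compound_id"),
            columns=self.feature_names,
        )

    def subset_rows(self, ids: Sequence[str]) -> "DescriptorMatrix":
        """Return the sub-matrix for ``ids``, in the given order."""
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        missing = [c for c in ids if c not in pos]
        if missing:
            raise DescriptorError(f"unknown compound ids: {missing[:5]}")
        idx = [pos[c] for c in ids]
        return DescriptorMatrix(
            list(ids), self.values[idx], list(self.feature_names), self.kind,
            dict(self.metadata),
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


@dataclass
class EmbeddingTable:
    """Maps substructure identifiers to fixed-dimension vectors.

    A reserved ``"UNK"`` entry, if present, is used for out-of-vocabulary
    substructures; otherwise unknowns contribute the zero vector.
    """

    vectors: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self.vectors = {str(k): np.asarray(v, dtype=float) for k, v in self.vectors.items()}
        if not self.vectors:
            raise DescriptorError("embedding table is empty")
        dims = {v.shape for v in self.vectors.values()}
        if len(dims) != 1 or next(iter(dims))[0] < 1 or len(next(iter(dims))) != 1:
            raise DescriptorError(f"embedding vectors must share one positive dimension, got {dims}")

    @property
    def dim(self) -> int:
        return next(iter(self.vectors.values())).shape[0]

    def lookup(self, key: str) -> np.ndarray:
        v = self.vectors.get(key)
        if v is not None:
            return v
        unk = self.vectors.get("UNK")
        if unk is not None:
            return unk
        return np.zeros(self.dim)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EmbeddingTable":
        df = pd.read_csv(path, index_col=0)
        return cls({str(k): row.to_numpy(dtype=float) for k, row in df.iterrows()})


def _parse_smiles(smiles_list: Sequence[str]) -> list[Chem.Mol]:
    mols = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise DescriptorError(f"record {i}: unparseable SMILES {smi!r}")
        mols.append(mol)
    return mols


def compute_maccs(
    smiles_list: Sequence[str], compound_ids: Sequence[str] | None = None
) -> DescriptorMatrix:
    """Compute 166-key MACCS fingerprints.

    RDKit emits 167 bits with bit 0 permanently unset (a 1-based indexing
    convention); bit 0 is dropped here so columns are exactly the 166 keys,
    named ``maccs_1`` ... ``maccs_166``. The convention is recorded in the
    matrix metadata. SMILES are parsed (hence canonicalized) before
    fingerprinting, so kekulized and aromatic spellings of one molecule give
    identical rows.
    """
    mols = _parse_smiles(smiles_list)
    if compound_ids is None:
        compound_ids = [f"cmpd_{i}" for i in range(len(mols))]
    rows = np.zeros((len(mols), 167))
    for i, mol in enumerate(mols):
        fp = MACCSkeys.GenMACCSKeys(mol)
        rows[i, list(fp.GetOnBits())] = 1.0
    return DescriptorMatrix(
        list(compound_ids),
        rows[:, 1:],  # bit 0 is a dummy in RDKit's 167-bit layout
        [f"maccs_{k}" for k in range(1, 167)],
        BINARY,
        metadata={"bit_convention": "rdkit-167-dummy-bit0-dropped", "n_keys": 166},
    )


def morgan_substructure_ids(mol: Chem.Mol, radius: int = 1) -> list[str]:
    """Morgan substructure identifiers (radii 0..radius), with multiplicity.

    These are the identifiers Mol2vec-style embeddings are keyed on: every
    atom contributes one identifier per radius.
    """
    info: dict[int, tuple] = {}
    GetMorganFingerprint(mol, radius, bitInfo=info)
    ids = []
    for ident, hits in info.items():
        ids.extend([str(ident)] * len(hits))
    return ids


def embed_mol2vec(
    smiles_list: Sequence[str],
    table: EmbeddingTable,
    compound_ids: Sequence[str] | None = None,
    radius: int = 1,
) -> DescriptorMatrix:
    """Molecule vectors as the sum of their substructures' embedding vectors.

    Each molecule is decomposed into Morgan substructure identifiers (all
    radii up to ``radius``); its row is the element-wise sum of the table
    vectors of those identifiers, occurrences counted with multiplicity.
    Unknown identifiers fall back to the table's ``"UNK"`` vector if present,
    else the zero vector.
    """
    mols = _parse_smiles(smiles_list)
    if compound_ids is None:
        compound_ids = [f"cmpd_{i}" for i in range(len(mols))]
    rows = np.zeros((len(mols), table.dim))
    for i, mol in enumerate(mols):
        for ident in morgan_substructure_ids(mol, radius):
            rows[i] += table.lookup(ident)
    return DescriptorMatrix(
        list(compound_ids), rows, [f"emb_{j}" for j in range(table.dim)], CONTINUOUS,
        metadata={"embedding_dim": table.dim, "morgan_radius": radius},
    )


def load_descriptor_table(path: str | Path, kind: str | None = None) -> DescriptorMatrix:
    """Ingest a descriptor CSV: first column compound ids, header = feature names.

    ``kind`` is inferred when not given: a table whose cells are all 0/1 is
    treated as a binary fingerprint, anything else as continuous.
    """
    df = pd.read_csv(path, index_col=0)
    if df.shape[1] == 0:
        raise DescriptorError(f"{path}: no feature columns")
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise DescriptorError(f"{path}: duplicate compound ids {dupes}")
    if df.isna().any().any():
        r, c = next(zip(*np.nonzero(df.isna().to_numpy())))
        raise DescriptorError(
            f"{path}: blank/missing cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise DescriptorError(f"{path}: non-numeric cell ({exc})") from exc
    if kind is None:
        kind = BINARY if np.isin(values, (0.0, 1.0)).all() else CONTINUOUS
    return DescriptorMatrix(
        [str(i) for i in df.index], values, [str(c) for c in df.columns], kind,
        metadata={"source": str(path)},
    )


def remove_zero_variance(m: DescriptorMatrix) -> DescriptorMatrix:
    """Drop every column whose values are all identical.

    The dropped feature names are recorded under
    ``metadata["dropped_zero_variance"]``.
    """
    keep = ~np.all(m.values == m.values[0, :], axis=0)
    if not keep.any():
        raise DescriptorError("all descriptors have zero variance; nothing to model")
    dropped = [f for f, k in zip(m.feature_names, keep) if not k]
    meta = dict(m.metadata)
    meta["dropped_zero_variance"] = dropped
    return DescriptorMatrix(
        list(m.compound_ids), m.values[:, keep],
        [f for f, k in zip(m.feature_names, keep) if k], m.kind, meta,
    )


def correlation_filter(
    m: DescriptorMatrix, threshold: float = 0.9, absolute: bool = True
) -> DescriptorMatrix:
    """Keep one descriptor of every pair correlated more than ``threshold``.

    Columns are scanned left to right; a column is dropped if its Pearson
    correlation with any earlier *retained* column exceeds the threshold
    (strictly greater). ``absolute=True`` (default) compares |r|, treating
    anti-correlated descriptors as equally redundant. Zero-variance columns
    must have been removed first. The dropped features and their retained
    partners are recorded under ``metadata["dropped_correlated"]``.
    """
    x = m.values
    if np.any(np.all(x == x[0, :], axis=0)):
        raise DescriptorError("remove zero-variance descriptors before correlation filtering")
    corr = np.corrcoef(x, rowvar=False)
    if corr.ndim == 0:  # single column
        corr = np.ones((1, 1))
    cmp_mat = np.abs(corr) if absolute else corr
    kept: list[int] = []
    dropped: dict[str, str] = {}
    for j in range(x.shape[1]):
        partner = next((i for i in kept if cmp_mat[i, j] > threshold), None)
        if partner is None:
            kept.append(j)
        else:
            dropped[m.feature_names[j]] = m.feature_names[partner]
    meta = dict(m.metadata)
    meta["dropped_correlated"] = dropped
    meta["correlation_threshold"] = threshold
    meta["correlation_absolute"] = absolute
    return DescriptorMatrix(
        list(m.compound_ids), x[:, kept], [m.feature_names[j] for j in kept], m.kind, meta,
    )


def preprocess(
    m: DescriptorMatrix, threshold: float = 0.9, absolute: bool = True
) -> DescriptorMatrix:
    """Two-step preprocessing: zero-variance removal then correlation filter."""
    return correlation_filter(remove_zero_variance(m), threshold, absolute)


def write_drop_report(m: DescriptorMatrix, path: str | Path) -> None:
    """JSON sidecar naming dropped features and the reason for each."""
    report = {
        "zero_variance": m.metadata.get("dropped_zero_variance", []),
        "correlated_with": m.metadata.get("dropped_correlated", {}),
        "retained": m.feature_names,
    }
    Path(path).write_text(json.dumps(report, indent=2))


def load_smiles_table(path: str | Path) -> pd.DataFrame:
    """Read a compound table (CSV/TSV) with columns compound_id, smiles[, label]."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    required = {"compound_id", "smiles"}
    if not required.issubset(df.columns):
        raise DescriptorError(f"{path}: need columns {sorted(required)}, got {list(df.columns)}")
    return df


def load_sdf(path: str | Path) -> pd.DataFrame:
    """Read an SDF (V2000) into a compound table with SMILES.

    Uses the ``compound_id`` / ``label`` SD properties when present, falling
    back to the molecule title and a missing label.
    """
    rows = []
    supplier = Chem.SDMolSupplier(str(path))
    for i, mol in enumerate(supplier):
        if mol is None:
            raise DescriptorError(f"{path}: record {i} failed to parse")
        props = mol.GetPropsAsDict()
        cid = str(props.get("compound_id", mol.GetProp("_Name") or f"sdf_{i}"))
        rows.append({
            "compound_id": cid,
            "smiles": Chem.MolToSmiles(mol),
            "label": props.get("label", np.nan),
        })
    return pd.DataFrame(rows)
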