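"""Library screening: admissibility filters and probability-binned risk report.

Before scoring an external compound library, structures a QSAR model cannot
speak to are removed: organometallics (any atom outside a configurable
organic-element list), heavy molecules (molecular weight above a cutoff,
default 1000 Da), and compounds already present in the modeling data
(matched by InChIKey). Predicted probabilities are then binned into ten
0.1-wide intervals; compounds at or above 0.5 are flagged as carcinogenicity
risk and at or above 0.9 as high concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors

# Elements ordinarily handled by organic QSAR descriptors; anything else
# marks the molecule as organometallic/inorganic.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Se", "Br", "I"}
)

BIN_EDGES = np.round(np.arange(0.0, 1.1, 0.1), 10)


@dataclass
class ExclusionLog:
    compound_id: str
    reason: str


@dataclass
class ScreeningReport:
    """Per-bin counts/fractions plus risk tallies for one screened library."""

    bin_edges: list[float]
    bin_counts: list[int]
    bin_fractions: list[float]
    n_screened: int
    n_risk: int
    n_high_concern: int
    risk_cutoff: float = 0.5
    high_concern_cutoff: float = 0.9
    n_filtered_out: int = 0
    exclusions: list[ExclusionLog] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "bin_edges": self.bin_edges,
            "bin_counts": self.bin_counts,
            "bin_fractions": self.bin_fractions,
            "n_screened": self.n_screened,
            "n_risk": self.n_risk,
            "n_high_concern": self.n_high_concern,
            "risk_cutoff": self.risk_cutoff,
            "high_concern_cutoff": self.high_concern_cutoff,
            "n_filtered_out": self.n_filtered_out,
            "exclusion_reasons": {
                r: sum(1 for e in self.exclusions if e.reason.startswith(r))
                for r in ("unparseable", "organometallic", "heavy", "overlap")
            },
        }


def inchikey(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return Chem.MolToInchiKey(mol) if mol is not None else None


def filter_library(
    compounds: Sequence[tuple[str, str]],
    training_inchikeys: Iterable[str] = (),
    mw_cutoff: float = 1000.0,
    organic_elements: frozenset[str] = ORGANIC_ELEMENTS,
) -> tuple[list[tuple[str, str]], list[ExclusionLog]]:
    """Split (compound_id, smiles) pairs into admissible ones and an exclusion log.

    Exclusion reasons, checked in order: unparseable structure,
    organometallic (atom outside ``organic_elements``), heavy (MW above
    ``mw_cutoff``), overlap (InChIKey matches the modeling set). Unparseable
    structures are logged, never fatal.
    """
    known = set(training_inchikeys)
    kept: list[tuple[str, str]] = []
    log: list[ExclusionLog] = []
    for cid, smi in compounds:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            log.append(ExclusionLog(cid, f"unparseable: {smi!r}"))
            continue
        alien = {a.GetSymbol() for a in mol.GetAtoms()} - organic_elements
        if alien:
            log.append(ExclusionLog(cid, f"organometallic: contains {sorted(alien)}"))
            continue
        mw = Descriptors.MolWt(mol)
        if mw > mw_cutoff:
            log.append(ExclusionLog(cid, f"heavy: MW {mw:.1f} > {mw_cutoff}"))
            continue
        if known and Chem.MolToInchiKey(mol) in known:
            log.append(ExclusionLog(cid, "overlap: InChIKey matches modeling set"))
            continue
        kept.append((cid, smi))
    return kept, log


def bin_probabilities(
    probs: Sequence[float],
    risk_cutoff: float = 0.5,
    high_concern_cutoff: float = 0.9,
    exclusions: Sequence[ExclusionLog] = (),
) -> ScreeningReport:
    """Bin probabilities into [0,0.1), [0.1,0.2), ..., [0.9,1.0].

    Every probability lands in exactly one bin (the last bin is closed at
    1.0). Risk / high-concern tallies use inclusive cutoffs (prob >= cutoff).
    """
    probs = np.asarray(probs, dtype=float)
    if probs.size and (probs.min() < 0.0 or probs.max() > 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    counts, _ = np.histogram(probs, bins=BIN_EDGES)
    n = probs.size
    return ScreeningReport(
        bin_edges=[float(e) for e in BIN_EDGES],
        bin_counts=[int(c) for c in counts],
        bin_fractions=[float(c / n) if n else 0.0 for c in counts],
        n_screened=int(n),
        n_risk=int((probs >= risk_cutoff).sum()),
        n_high_concern=int((probs >= high_concern_cutoff).sum()),
        risk_cutoff=risk_cutoff,
        high_concern_cutoff=high_concern_cutoff,
        n_filtered_out=len(exclusions),
        exclusions=list(exclusions),
    )
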