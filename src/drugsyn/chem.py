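"""SMILES parsing and atom featurization.

A drug is represented as an undirected molecular graph: heavy atoms are
nodes, covalent bonds are edges (hydrogens stay implicit). Each atom carries
five descriptors — element symbol, heavy-atom degree, implicit valence,
attached-hydrogen count, and aromaticity — encoded as fixed-width one-hot
blocks so every molecule maps into the same feature space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = [
    "ATOM_VOCAB",
    "FEATURE_DIM",
    "MolecularGraph",
    "SmilesParseError",
    "smiles_to_graph",
    "featurize_atoms",
    "read_drug_table",
]

#: Fixed element vocabulary; anything else falls into the trailing "other" slot.
ATOM_VOCAB: tuple[str, ...] = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P", "B")

_COUNT_CAP = 5  # degree/valence/H-count one-hots cover 0..5 plus an overflow bucket
_COUNT_WIDTH = _COUNT_CAP + 2

#: Total width of an atom feature row: symbol one-hot (+other) + three capped
#: count one-hots + aromatic flag.
FEATURE_DIM = (len(ATOM_VOCAB) + 1) + 3 * _COUNT_WIDTH + 1


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class MolecularGraph:
    """An undirected heavy-atom graph with per-atom feature rows.

    Attributes
    ----------
    smiles : the input string, kept verbatim for atom-level reporting.
    num_atoms : number of heavy atoms.
    node_features : float matrix ``[num_atoms, FEATURE_DIM]``.
    edges : unordered bond pairs ``(i, j)`` with ``i < j``, no duplicates.
    atom_symbols : element symbol per node, parser order.
    aromatic_flags : aromaticity per node (used by reporting and the
        synthetic planted rule).
    """

    smiles: str
    num_atoms: int
    node_features: np.ndarray
    edges: list[tuple[int, int]] = field(default_factory=list)
    atom_symbols: list[str] = field(default_factory=list)
    aromatic_flags: list[bool] = field(default_factory=list)

    def adjacency(self, self_loops: bool = True) -> np.ndarray:
        """Dense symmetric adjacency; self-loops included by default because
        the attention neighborhood of every atom contains the atom itself."""
        a = np.zeros((self.num_atoms, self.num_atoms), dtype=np.float64)
        for i, j in self.edges:
            a[i, j] = a[j, i] = 1.0
        if self_loops:
            np.fill_diagonal(a, 1.0)
        return a

    @property
    def aromatic_fraction(self) -> float:
        return float(np.mean(self.aromatic_flags)) if self.num_atoms else 0.0

    def to_dict(self) -> dict:
        """Debug dump (JSON-serializable)."""
        return {
            "smiles": self.smiles,
            "num_atoms": self.num_atoms,
            "atom_symbols": list(self.atom_symbols),
            "edges": [list(e) for e in self.edges],
            "node_features": self.node_features.tolist(),
        }


def _onehot(index: int, width: int) -> np.ndarray:
    v = np.zeros(width, dtype=np.float64)
    v[index] = 1.0
    return v


def _capped_onehot(count: int) -> np.ndarray:
    return _onehot(min(count, _COUNT_CAP + 1), _COUNT_WIDTH)


def _atom_feature_row(atom: Chem.Atom) -> np.ndarray:
    sym = atom.GetSymbol()
    sym_idx = ATOM_VOCAB.index(sym) if sym in ATOM_VOCAB else len(ATOM_VOCAB)
    return np.concatenate([
        _onehot(sym_idx, len(ATOM_VOCAB) + 1),
        _capped_onehot(atom.GetDegree()),            # adjacent heavy atoms
        _capped_onehot(atom.GetImplicitValence()),   # implicit valence
        _capped_onehot(atom.GetTotalNumHs()),        # attached hydrogens
        np.array([1.0 if atom.GetIsAromatic() else 0.0]),
    ])


def smiles_to_graph(smiles: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Node order follows RDKit's atom order for the given spelling, which is
    deterministic for a fixed input. Raises :class:`SmilesParseError` for
    unparsable input and ``ValueError`` for empty input.
    """
    if not isinstance(smiles, str) or not smiles.strip():
        raise ValueError("SMILES string must be non-empty text")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"could not parse SMILES: {smiles!r}")
    n = mol.GetNumAtoms()
    edges = sorted(
        (min(b.GetBeginAtomIdx(), b.GetEndAtomIdx()),
         max(b.GetBeginAtomIdx(), b.GetEndAtomIdx()))
        for b in mol.GetBonds()
    )
    graph = MolecularGraph(
        smiles=smiles,
        num_atoms=n,
        node_features=np.empty((0, FEATURE_DIM)),
        edges=edges,
        atom_symbols=[a.GetSymbol() for a in mol.GetAtoms()],
        aromatic_flags=[a.GetIsAromatic() for a in mol.GetAtoms()],
    )
    graph.node_features = np.stack([_atom_feature_row(a) for a in mol.GetAtoms()])
    return graph


def featurize_atoms(graph: MolecularGraph) -> np.ndarray:
    """Return the ``[num_atoms, FEATURE_DIM]`` atom descriptor matrix."""
    return graph.node_features


def read_drug_table(path) -> dict[str, MolecularGraph]:
    """Read a delimited drug table with columns ``drug_id, smiles`` (or plain
    SMILES one per line) and parse every entry."""
    import pandas as pd

    df = pd.read_csv(path)
    if "smiles" in df.columns:
        id_col = "drug_id" if "drug_id" in df.columns else df.columns[0]
        pairs = zip(df[id_col].astype(str), df["smiles"].astype(str))
    else:
        # single-column file of bare SMILES
        col = df.columns[0]
        values = [col] + df[col].astype(str).tolist()
        pairs = ((s, s) for s in values)
    graphs: dict[str, MolecularGraph] = {}
    for drug_id, smi in pairs:
        graphs[drug_id] = smiles_to_graph(smi)
    return graphs
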