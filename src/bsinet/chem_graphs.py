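"""SMILES to bidirected molecular graphs with per-atom feature vectors.

Small-molecule drugs enter the graph-attention branch as heavy-atom graphs:
every bond contributes a directed edge in each direction and every atom
carries a fixed-width feature vector built from one-hot blocks over a frozen
chemical vocabulary.  Self-loops are added so that every atom has a
non-empty attention neighborhood, which keeps the attention softmax defined
even for single-atom molecules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

__all__ = ["FeaturizerConfig", "MolecularGraph", "atom_feature_vector",
           "smiles_to_graph"]


@dataclass(frozen=True)
class FeaturizerConfig:
    """Frozen atom-feature vocabulary.

    Out-of-vocabulary elements map to the reserved final "other" slot of the
    element block; degree, hybridization and H-count blocks likewise end in
    an overflow slot.  Stereochemistry is ignored: attention operates on
    connectivity only.
    """

    elements: tuple = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")
    max_degree: int = 5
    hybridizations: tuple = ("S", "SP", "SP2", "SP3", "SP3D", "SP3D2")
    max_total_h: int = 4

    @property
    def width(self) -> int:
        # each one-hot block carries a trailing overflow slot
        return ((len(self.elements) + 1) + (self.max_degree + 2) + 1 + 1 + 1
                + (len(self.hybridizations) + 1) + (self.max_total_h + 2))


@dataclass
class MolecularGraph:
    """Bidirected heavy-atom graph of one small molecule.

    `edges` holds ordered (src, dst) pairs and is closed under reversal;
    after `add_self_loops` every node also appears exactly once as (i, i).
    """

    drug_id: str
    node_features: np.ndarray          # (n_atoms, d_atom)
    edges: list = field(default_factory=list)

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    def add_self_loops(self) -> "MolecularGraph":
        loops = {(i, i) for i in range(self.n_atoms)}
        existing = set(map(tuple, self.edges))
        self.edges = list(self.edges) + sorted(loops - existing)
        return self

    def edge_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        if not self.edges:
            return np.zeros(0, dtype=np.intp), np.zeros(0, dtype=np.intp)
        e = np.asarray(self.edges, dtype=np.intp)
        return e[:, 0], e[:, 1]

    def to_json(self) -> str:
        return json.dumps({
            "drug_id": self.drug_id,
            "n_atoms": self.n_atoms,
            "edges": [list(map(int, e)) for e in self.edges],
            "node_features": self.node_features.tolist(),
        })

    @staticmethod
    def from_json(text: str) -> "MolecularGraph":
        d = json.loads(text)
        return MolecularGraph(
            drug_id=d["drug_id"],
            node_features=np.asarray(d["node_features"], dtype=np.float64),
            edges=[tuple(e) for e in d["edges"]],
        )


def _one_hot(value, vocab) -> list[float]:
    """One-hot over `vocab` plus a trailing overflow slot."""
    vec = [0.0] * (len(vocab) + 1)
    try:
        vec[list(vocab).index(value)] = 1.0
    except ValueError:
        vec[-1] = 1.0
    return vec


def atom_feature_vector(atom: Chem.Atom, config: FeaturizerConfig | None = None) -> np.ndarray:
    """Fixed-width feature vector for one (parsed) atom.

    Blocks, in order: element one-hot, heavy degree one-hot, formal charge,
    aromatic flag, ring-membership flag, hybridization one-hot, total
    hydrogen count one-hot.
    """
    cfg = config or FeaturizerConfig()
    vec: list[float] = []
    vec += _one_hot(atom.GetSymbol(), cfg.elements)
    vec += _one_hot(atom.GetDegree(), range(cfg.max_degree + 1))
    vec.append(float(atom.GetFormalCharge()))
    vec.append(1.0 if atom.GetIsAromatic() else 0.0)
    vec.append(1.0 if atom.IsInRing() else 0.0)
    vec += _one_hot(str(atom.GetHybridization()), cfg.hybridizations)
    vec += _one_hot(atom.GetTotalNumHs(), range(cfg.max_total_h + 1))
    out = np.asarray(vec, dtype=np.float64)
    assert out.shape[0] == cfg.width
    return out


class SmilesParseError(ValueError):
    pass


def smiles_to_graph(smiles: str, drug_id: str = "",
                    config: FeaturizerConfig | None = None,
                    self_loops: bool = True) -> MolecularGraph:
    """Parse a SMILES string into a bidirected heavy-atom graph.

    Hydrogens stay implicit (they contribute to the H-count feature only).
    Raises :class:`SmilesParseError` naming the offending string on invalid
    or empty input.
    """
    cfg = config or FeaturizerConfig()
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"unparsable SMILES: {smiles!r}")
    feats = np.stack([atom_feature_vector(a, cfg) for a in mol.GetAtoms()])
    edges: list[tuple[int, int]] = []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        edges.append((i, j))
        edges.append((j, i))
    g = MolecularGraph(drug_id=drug_id or smiles, node_features=feats, edges=edges)
    if self_loops:
        g.add_self_loops()
    return g
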