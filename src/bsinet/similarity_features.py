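"""Drug-drug similarity and interaction matrices, and their fused feature blocks.

Four kinds of square drug-by-drug matrices feed the classifier:

* binary interaction matrices (small-molecule/small-molecule and
  biotech/biotech) built from edge lists;
* Tanimoto structural similarity on circular (Morgan radius-2, 2048-bit)
  fingerprints for small molecules;
* cosine similarity between rows of the drug-by-target interaction matrix,
  for both drug populations;
* normalized Needleman-Wunsch global-alignment similarity between biotech
  amino-acid sequences (BLOSUM62, affine gaps), with multi-chain drugs
  aligned on their concatenated chains.

The per-population fused block is the elementwise sum of the interaction
matrix and the two similarity matrices; one row of it is the similarity
feature vector of one drug.

Degenerate inputs (empty fingerprint, all-zero target row) get similarity 0
everywhere, including the diagonal: "no evidence" rather than 0/0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "InteractionMatrix", "SimilarityMatrix", "FusedFeatureBlock",
    "morgan_fingerprints", "tanimoto_similarity", "interaction_cosine",
    "global_alignment_similarity", "interaction_matrix_from_edges", "fuse",
]


@dataclass
class InteractionMatrix:
    """Binary interaction matrix with explicit row/column identifier lists."""

    values: np.ndarray
    row_ids: list
    col_ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        assert set(np.unique(self.values)) <= {0.0, 1.0}, "entries must be 0/1"


@dataclass
class SimilarityMatrix:
    """Square symmetric matrix of pairwise similarities in [0, 1]."""

    values: np.ndarray
    ids: list

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        n = len(self.ids)
        assert self.values.shape == (n, n)


@dataclass
class FusedFeatureBlock:
    """Elementwise sum of one interaction and two similarity matrices."""

    values: np.ndarray
    ids: list


def interaction_matrix_from_edges(edges, row_ids, col_ids=None,
                                  symmetric: bool = False) -> InteractionMatrix:
    """Build a 0/1 matrix from (id_a, id_b) edge pairs.

    With ``symmetric=True`` the matrix is square over `row_ids`, symmetrized,
    and the diagonal forced to zero (drug-drug interaction convention).
    """
    col_ids = row_ids if col_ids is None else col_ids
    ri = {d: i for i, d in enumerate(row_ids)}
    ci = {d: i for i, d in enumerate(col_ids)}
    m = np.zeros((len(row_ids), len(col_ids)))
    for a, b in edges:
        if a not in ri or b not in ci:
            raise KeyError(f"edge ({a}, {b}) references an unknown identifier")
        m[ri[a], ci[b]] = 1.0
        if symmetric:
            m[ri[b], ci[a]] = 1.0
    if symmetric:
        np.fill_diagonal(m, 0.0)
    return InteractionMatrix(m, list(row_ids), list(col_ids))


def morgan_fingerprints(smiles_list, ids, radius: int = 2,
                        n_bits: int = 2048) -> list[frozenset]:
    """Circular (ECFP-style) fingerprints as sets of on-bit indices."""
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    out = []
    for drug_id, smi in zip(ids, smiles_list):
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparsable SMILES for {drug_id}: {smi!r}")
        fp = gen.GetFingerprint(mol)
        out.append(frozenset(fp.GetOnBits()))
    return out


def tanimoto_similarity(fingerprints: list[frozenset], ids=None) -> SimilarityMatrix:
    """Pairwise Tanimoto coefficient |Fi ∩ Fj| / |Fi ∪ Fj| on bit sets.

    Any pair involving an empty fingerprint (including the self pair) is 0.
    """
    n = len(fingerprints)
    ids = list(ids) if ids is not None else list(range(n))
    m = np.zeros((n, n))
    for i in range(n):
        fi = fingerprints[i]
        if not fi:
            continue
        for j in range(i, n):
            fj = fingerprints[j]
            if not fj:
                continue
            inter = len(fi & fj)
            union = len(fi) + len(fj) - inter
            m[i, j] = m[j, i] = inter / union
    return SimilarityMatrix(m, ids)


def interaction_cosine(M: InteractionMatrix) -> SimilarityMatrix:
    """Cosine similarity between drug rows of a drug-by-target matrix.

    Rows with no targets yield 0 against everything, themselves included.
    """
    v = M.values
    norms = np.linalg.norm(v, axis=1)
    safe = np.where(norms > 0, norms, 1.0)
    unit = v / safe[:, None]
    sim = unit @ unit.T
    sim[norms == 0, :] = 0.0
    sim[:, norms == 0] = 0.0
    sim = np.clip((sim + sim.T) / 2.0, 0.0, 1.0)
    return SimilarityMatrix(sim, list(M.row_ids))


_ALIGNER = None


def _aligner() -> Align.PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        a = Align.PairwiseAligner()
        a.mode = "global"
        a.substitution_matrix = substitution_matrices.load("BLOSUM62")
        a.open_gap_score = -10.0
        a.extend_gap_score = -1.0
        _ALIGNER = a
    return _ALIGNER


def global_alignment_similarity(sequences: list[str], ids=None) -> SimilarityMatrix:
    """Normalized Needleman-Wunsch global-alignment similarity.

    Raw affine-gap alignment scores S(i,j) under BLOSUM62 (gap open 10,
    extend 1) are normalized as S(i,j) / sqrt(S(i,i) * S(j,j)) and clipped to
    [0, 1], so self-similarity is exactly 1 for every non-empty sequence.
    """
    n = len(sequences)
    ids = list(ids) if ids is not None else list(range(n))
    for drug_id, seq in zip(ids, sequences):
        if not seq:
            raise ValueError(f"empty sequence for drug {drug_id}")
    aligner = _aligner()
    seqs = [s.upper() for s in sequences]
    self_scores = np.array([aligner.score(s, s) for s in seqs])
    m = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw = aligner.score(seqs[i], seqs[j])
            denom = np.sqrt(self_scores[i] * self_scores[j])
            m[i, j] = m[j, i] = np.clip(raw / denom, 0.0, 1.0) if denom > 0 else 0.0
    return SimilarityMatrix(m, ids)


def fuse(I: InteractionMatrix, T: SimilarityMatrix, S: SimilarityMatrix) -> FusedFeatureBlock:
    """Elementwise sum of an interaction matrix and two similarity matrices.

    No rescaling is applied; entries therefore lie in [0, 3].
    """
    if not (I.values.shape == T.values.shape == S.values.shape):
        raise ValueError("fuse: shape mismatch between matrices")
    if not (list(I.row_ids) == list(T.ids) == list(S.ids)):
        raise ValueError("fuse: id-order mismatch between matrices")
    return FusedFeatureBlock(I.values + T.values + S.values, list(T.ids))
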