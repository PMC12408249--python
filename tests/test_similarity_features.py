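"""Similarity matrices, interaction matrices and fused feature blocks."""

import numpy as np
import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from bsinet.similarity_features import (InteractionMatrix, fuse,
                                        global_alignment_similarity,
                                        interaction_cosine,
                                        interaction_matrix_from_edges,
                                        morgan_fingerprints,
                                        tanimoto_similarity)


# ---------------------------------------------------------------- Tanimoto --

def test_tanimoto_identity_disjoint_and_hand_value():
    fps = [frozenset({1, 2, 3}), frozenset({2, 3, 4}), frozenset({9, 10}),
           frozenset()]
    m = tanimoto_similarity(fps).values
    assert m[0, 0] == 1.0                       # identical non-empty
    assert m[0, 2] == 0.0                       # disjoint
    assert m[0, 1] == pytest.approx(2 / 4)      # {2,3} over {1,2,3,4}
    assert m[3, 3] == 0.0                       # empty fingerprint: no evidence
    np.testing.assert_array_equal(m, m.T)


@settings(max_examples=100, derandomize=True)
@given(st.lists(st.frozensets(st.integers(0, 63), min_size=1, max_size=20),
                min_size=2, max_size=6))
def test_tanimoto_matches_brute_force_set_arithmetic(fps):
    m = tanimoto_similarity(fps).values
    for i, a in enumerate(fps):
        for j, b in enumerate(fps):
            expected = len(a & b) / len(a | b)
            assert m[i, j] == pytest.approx(expected)
            assert 0.0 <= m[i, j] <= 1.0


def test_tanimoto_agrees_with_rdkit_on_real_fingerprints():
    smiles = ["CCO", "CCN", "c1ccccc1", "Cc1ccccc1", "CC(=O)O", "C1CCCCC1"]
    fps = morgan_fingerprints(smiles, list(range(len(smiles))))
    m = tanimoto_similarity(fps).values
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
    bvs = [gen.GetFingerprint(Chem.MolFromSmiles(s)) for s in smiles]
    for i in range(len(smiles)):
        for j in range(len(smiles)):
            assert m[i, j] == pytest.approx(
                DataStructs.TanimotoSimilarity(bvs[i], bvs[j]), abs=1e-12)


# --------------------------------------------------------- cosine similarity --

def test_interaction_cosine_examples():
    M = InteractionMatrix(np.array([[1, 1, 0], [1, 0, 1], [0, 1, 0],
                                    [0, 0, 0]]), list("abcd"), list("xyz"))
    s = interaction_cosine(M).values
    assert s[0, 0] == pytest.approx(1.0)
    assert s[0, 1] == pytest.approx(0.5)          # dot 1 over sqrt2*sqrt2
    assert s[1, 2] == pytest.approx(0.0)          # orthogonal target sets
    assert s[3, 3] == 0.0 and s[3, 0] == 0.0      # all-zero row: no evidence
    np.testing.assert_allclose(s, s.T)


def test_interaction_cosine_matches_direct_computation(rng):
    v = (rng.random((8, 12)) < 0.3).astype(float)
    s = interaction_cosine(InteractionMatrix(v, list(range(8)),
                                             list(range(12)))).values
    for i in range(8):
        for j in range(8):
            ni, nj = np.linalg.norm(v[i]), np.linalg.norm(v[j])
            expected = 0.0 if ni == 0 or nj == 0 else v[i] @ v[j] / (ni * nj)
            assert s[i, j] == pytest.approx(expected, abs=1e-12)


# ------------------------------------------------------------- global alignment --

def _gotoh_global(a: str, b: str, open_pen=10.0, extend_pen=1.0):
    """Independent affine-gap global alignment (end gaps penalized); the first
    gap position costs `open_pen`, each further position `extend_pen`."""
    blosum = substitution_matrices.load("BLOSUM62")
    n, m = len(a), len(b)
    NEG = -1e18
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)   # gap in b (consume a)
    Y = np.full((n + 1, m + 1), NEG)   # gap in a (consume b)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -open_pen - (i - 1) * extend_pen
    for j in range(1, m + 1):
        Y[0, j] = -open_pen - (j - 1) * extend_pen
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = blosum[a[i - 1], b[j - 1]]
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] - open_pen, X[i - 1, j] - extend_pen,
                          Y[i - 1, j] - open_pen)
            Y[i, j] = max(M[i, j - 1] - open_pen, Y[i, j - 1] - extend_pen,
                          X[i, j - 1] - open_pen)
    return max(M[n, m], X[n, m], Y[n, m])


def test_alignment_self_similarity_and_monotonicity():
    m = global_alignment_similarity(["AAAA", "AAAA", "WWWW"]).values
    assert m[0, 0] == 1.0 and m[0, 1] == 1.0
    assert m[0, 2] < 1.0


def test_alignment_matches_textbook_dynamic_programming():
    seqs = ["HEAGAWGHEE", "PAWHEAE", "MKTAYIAKQR"]
    m = global_alignment_similarity(seqs).values
    selfs = [_gotoh_global(s, s) for s in seqs]
    for i in range(3):
        for j in range(3):
            raw = _gotoh_global(seqs[i], seqs[j])
            expected = np.clip(raw / np.sqrt(selfs[i] * selfs[j]), 0.0, 1.0)
            assert m[i, j] == pytest.approx(expected, abs=1e-9), (i, j)


def test_alignment_empty_sequence_names_the_drug():
    with pytest.raises(ValueError, match="DRUGX"):
        global_alignment_similarity(["AAAA", ""], ids=["OK", "DRUGX"])


# ------------------------------------------------------------------------ fuse --

def test_fuse_sums_elementwise_without_rescaling():
    ids = ["a", "b"]
    I = interaction_matrix_from_edges([("a", "b")], ids, symmetric=True)
    from bsinet.similarity_features import SimilarityMatrix
    T = SimilarityMatrix(np.array([[1.0, 0.3], [0.3, 1.0]]), ids)
    S = SimilarityMatrix(np.array([[1.0, 0.5], [0.5, 1.0]]), ids)
    block = fuse(I, T, S)
    np.testing.assert_allclose(block.values, [[2.0, 1.8], [1.8, 2.0]])
    assert (block.values >= 0).all() and (block.values <= 3).all()


def test_fuse_rejects_mismatches():
    from bsinet.similarity_features import SimilarityMatrix
    I = interaction_matrix_from_edges([], ["a", "b"], symmetric=True)
    T = SimilarityMatrix(np.eye(2), ["a", "b"])
    bad_shape = SimilarityMatrix(np.eye(3), ["a", "b", "c"])
    with pytest.raises(ValueError, match="shape"):
        fuse(I, T, bad_shape)
    bad_ids = SimilarityMatrix(np.eye(2), ["b", "a"])
    with pytest.raises(ValueError, match="id-order"):
        fuse(I, T, bad_ids)


def test_interaction_matrix_symmetric_zero_diagonal():
    m = interaction_matrix_from_edges([("a", "b"), ("b", "c"), ("a", "a")],
                                      ["a", "b", "c"], symmetric=True)
    np.testing.assert_array_equal(m.values, m.values.T)
    assert np.all(np.diag(m.values) == 0)
    with pytest.raises(KeyError):
        interaction_matrix_from_edges([("a", "zzz")], ["a", "b"], symmetric=True)
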