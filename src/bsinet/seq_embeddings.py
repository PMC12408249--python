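"""Fixed-length embeddings of biotech (protein) drugs.

Each biotech drug is one or more amino-acid chains.  Chains are embedded
independently by a pluggable :class:`SequenceEmbedder` and the per-chain
vectors are averaged (unweighted) into a single drug-level embedding, so a
drug whose chains are permuted gets the same vector.

The default embedder is an offline, deterministic k-mer composition hash:
overlapping 3-mers of the chain are hashed into `d_emb` buckets, counted,
and the count vector L2-normalized.  It preserves the downstream tensor
contract of a transformer protein language model (one real vector of width
`d_emb`, default 1024, per chain) without any pretrained weights; a real
language-model embedder can be plugged in behind the same interface.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Protocol

import numpy as np

__all__ = ["ProteinRecord", "SequenceEmbedder", "KmerHashEmbedder",
           "embed_record", "embed_records"]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWYX"


@dataclass
class ProteinRecord:
    """A biotech drug: an identifier plus one or more amino-acid chains."""

    drug_id: str
    chains: list[str]

    def __post_init__(self):
        if not self.chains:
            raise ValueError(f"protein record {self.drug_id} has no chains")
        for i, c in enumerate(self.chains):
            if not c:
                raise ValueError(f"protein record {self.drug_id} chain {i} is empty")

    @property
    def concatenated(self) -> str:
        return "".join(self.chains)


class SequenceEmbedder(Protocol):
    d_emb: int

    def embed(self, chain: str) -> np.ndarray: ...


class KmerHashEmbedder:
    """Deterministic k-mer composition embedding.

    Each overlapping k-mer (default k=3) is hashed (BLAKE2, salted with
    `seed`) to one of `d_emb` buckets; the bucket-count vector is
    L2-normalized.  Chains shorter than k fall back to 1-mers.
    """

    def __init__(self, d_emb: int = 1024, k: int = 3, seed: int = 0):
        self.d_emb = int(d_emb)
        self.k = int(k)
        self.seed = int(seed)
        self._salt = str(seed).encode()

    def _bucket(self, kmer: str) -> int:
        h = hashlib.blake2b(kmer.encode(), digest_size=8, salt=self._salt[:16])
        return int.from_bytes(h.digest(), "big") % self.d_emb

    def embed(self, chain: str) -> np.ndarray:
        chain = chain.upper()
        k = self.k if len(chain) >= self.k else 1
        vec = np.zeros(self.d_emb)
        for i in range(len(chain) - k + 1):
            vec[self._bucket(chain[i:i + k])] += 1.0
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def embed_record(record: ProteinRecord, embedder: SequenceEmbedder) -> np.ndarray:
    """Arithmetic mean of the per-chain embeddings of one biotech drug."""
    chains = []
    for i, chain in enumerate(record.chains):
        try:
            v = np.asarray(embedder.embed(chain), dtype=np.float64)
        except Exception as exc:  # noqa: BLE001 - re-raise with provenance
            raise RuntimeError(
                f"embedder failed on drug {record.drug_id}, chain {i}") from exc
        if v.shape != (embedder.d_emb,):
            raise ValueError(
                f"embedder returned shape {v.shape} (expected ({embedder.d_emb},)) "
                f"for drug {record.drug_id}, chain {i}")
        chains.append(v)
    return np.mean(chains, axis=0)


def embed_records(records: list[ProteinRecord],
                  embedder: SequenceEmbedder) -> np.ndarray:
    """Stack drug-level embeddings into a (n_drugs, d_emb) matrix."""
    return np.stack([embed_record(r, embedder) for r in records])
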