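"""Download-free synthetic corpus with a planted, learnable interaction rule.

The generator emulates the shape of a curated drug-interaction corpus: a
population of small molecules (SMILES), a population of biotech drugs
(amino-acid chains, 1-3 per drug), within-population interaction edge lists,
drug-target edge lists, and a labelled set of cross-population pairs.

Learnable structure is planted through latent clusters:

* each small-molecule cluster shares a chemical scaffold, so within-cluster
  Tanimoto similarity exceeds between-cluster similarity by construction;
* each biotech cluster shares base chains (mutated per drug), so alignment
  similarity and sequence embeddings are cluster-informative; drugs with
  multiple chains share a common first chain, mirroring real multi-chain
  biologics;
* drug-target edges are drawn from per-cluster target blocks, making the
  interaction-derived cosine similarities informative;
* the pair label is a deterministic function of the two latent clusters
  (optionally flipped with probability `label_noise`); whole cluster-pair
  combinations are designated non-interacting to form the negative class,
  so the negative class is itself predictable from the features.

The class-frequency profile is deliberately long-tailed (a Zipf-like
allocation of cluster combinations to classes) to stress stratification and
support-weighted metrics.  Everything is reproducible from the seed, and the
written files are exactly the formats the production readers consume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem

__all__ = ["SyntheticConfig", "SyntheticCorpus", "generate"]

# substituent prefixes prepended to a cluster scaffold; all yield valid SMILES
_SUBSTITUENTS = [
    "C", "CC", "CCC", "CCCC", "CC(C)", "O", "OC", "OCC", "N", "NC", "NCC",
    "Cl", "F", "Br", "N(C)C", "OC(C)",
    "CC(C)C", "OCC(C)", "NCC(C)", "ClC", "FC", "FCC", "ClCC", "BrC",
    "OCCO", "NCCO", "CCO", "CCN", "OCCC", "NCCC", "CC(N)", "CC(O)",
]

# one scaffold family per small-molecule cluster (cycled if more clusters)
_SCAFFOLDS = [
    "c1ccccc1",          # benzenes
    "c1ccncc1",          # pyridines
    "C1CCCCC1",          # cyclohexanes
    "CCOCCN",            # amino ethers
    "CC(=O)NCC",         # amides
    "c1ccc2ccccc2c1",    # naphthalenes
    "C1CCNCC1",          # piperidines
    "CC(=O)OCC",         # esters
]

_AA = "ACDEFGHIKLMNPQRSTVWY"


@dataclass
class SyntheticConfig:
    n_small: int = 120
    n_biotech: int = 30
    n_targets: int = 40            # per-population target pool size
    n_classes: int = 8             # including the negative class at index 0
    n_sm_clusters: int = 5
    n_bt_clusters: int = 4
    label_noise: float = 0.0
    negative_fraction: float = 0.2
    no_target_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if not (0.0 <= self.label_noise < 0.5):
            raise ValueError("label_noise must be in [0, 0.5)")
        if min(self.n_small, self.n_biotech, self.n_targets) < 1:
            raise ValueError("all counts must be positive")
        if self.n_sm_clusters > self.n_small or self.n_bt_clusters > self.n_biotech:
            raise ValueError("more clusters than drugs")
        n_combos = self.n_sm_clusters * self.n_bt_clusters
        if n_combos < self.n_classes:
            raise ValueError(
                f"{n_combos} cluster combinations cannot cover {self.n_classes} classes")


@dataclass
class SyntheticCorpus:
    config: SyntheticConfig
    sm_ids: list
    smiles: list
    bt_ids: list
    chains: dict                   # bt_id -> list of chains
    ssi_edges: list                # (sm_id, sm_id)
    bbi_edges: list                # (bt_id, bt_id)
    sti_edges: list                # (sm_id, target_id)
    bti_edges: list                # (bt_id, target_id)
    sm_targets: list
    bt_targets: list
    pairs: list                    # (sm_id, bt_id, label_name)
    label_vocab: list              # index -> label name, negative at 0
    sm_clusters: np.ndarray
    bt_clusters: np.ndarray
    rule: dict = field(default_factory=dict)   # (sm_cluster, bt_cluster) -> class

    def write(self, out_dir: str | Path) -> dict:
        """Write the corpus in the on-disk formats the readers consume."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "smiles": out / "smiles.csv", "fasta": out / "biotech.fasta",
            "ssi": out / "ssi_edges.csv", "bbi": out / "bbi_edges.csv",
            "sti": out / "sti_edges.csv", "bti": out / "bti_edges.csv",
            "pairs": out / "pairs.csv", "labels": out / "labels.json",
            "clusters": out / "clusters.json",
        }
        with open(paths["smiles"], "w") as fh:
            fh.write("drug_id,smiles\n")
            for d, s in zip(self.sm_ids, self.smiles):
                fh.write(f"{d},{s}\n")
        with open(paths["fasta"], "w") as fh:
            for d in self.bt_ids:
                for ci, chain in enumerate(self.chains[d], start=1):
                    fh.write(f">{d}_chain{ci}\n{chain}\n")
        for key, edges, header in (
                ("ssi", self.ssi_edges, "drug_id_a,drug_id_b"),
                ("bbi", self.bbi_edges, "drug_id_a,drug_id_b"),
                ("sti", self.sti_edges, "drug_id,target_id"),
                ("bti", self.bti_edges, "drug_id,target_id")):
            with open(paths[key], "w") as fh:
                fh.write(header + "\n")
                for a, b in edges:
                    fh.write(f"{a},{b}\n")
        with open(paths["pairs"], "w") as fh:
            fh.write("sm_id,bt_id,label\n")
            for s, b, lab in self.pairs:
                fh.write(f"{s},{b},{lab}\n")
        with open(paths["labels"], "w") as fh:
            json.dump(self.label_vocab, fh, indent=0)
        with open(paths["clusters"], "w") as fh:
            json.dump({"sm": {d: int(c) for d, c in zip(self.sm_ids, self.sm_clusters)},
                       "bt": {d: int(c) for d, c in zip(self.bt_ids, self.bt_clusters)},
                       "rule": {f"{i},{j}": int(c)
                                for (i, j), c in sorted(self.rule.items())}},
                      fh, indent=0, sort_keys=True)
        return {k: str(v) for k, v in paths.items()}


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    chars = list(seq)
    for i in range(len(chars)):
        if rng.random() < rate:
            chars[i] = _AA[rng.integers(len(_AA))]
    return "".join(chars)


def _cluster_sizes(n: int, k: int) -> np.ndarray:
    base = np.full(k, n // k)
    base[: n % k] += 1
    return base


def _combo_rule(cfg: SyntheticConfig) -> dict:
    """Deterministic (sm_cluster, bt_cluster) -> class map with a long tail.

    The first combinations (in row-major order) become the negative class
    until `negative_fraction` of all pairs is reached; the rest are dealt to
    the positive classes with Zipf-like multiplicities.
    """
    combos = [(i, j) for i in range(cfg.n_sm_clusters)
              for j in range(cfg.n_bt_clusters)]
    sm_sz = _cluster_sizes(cfg.n_small, cfg.n_sm_clusters)
    bt_sz = _cluster_sizes(cfg.n_biotech, cfg.n_bt_clusters)
    sizes = {c: int(sm_sz[c[0]] * bt_sz[c[1]]) for c in combos}
    total = sum(sizes.values())
    n_pos = cfg.n_classes - 1
    rule: dict = {}
    neg_budget = cfg.negative_fraction * total
    acc = 0.0
    queue = list(combos)
    while queue and acc + sizes[queue[0]] <= neg_budget and len(queue) > n_pos:
        c = queue.pop(0)
        rule[c] = 0
        acc += sizes[c]
    # Zipf-like allocation of remaining combos over positive classes
    m = len(queue)
    weights = 1.0 / np.arange(1, n_pos + 1)
    alloc = np.maximum(1, np.floor(m * weights / weights.sum()).astype(int))
    while alloc.sum() > m:
        alloc[np.argmax(alloc)] -= 1
    alloc[0] += m - alloc.sum()
    cls = 1
    for count in alloc:
        for _ in range(count):
            rule[queue.pop(0)] = cls
        cls += 1
    return rule


def generate(cfg: SyntheticConfig | None = None) -> SyntheticCorpus:
    """Generate a full corpus; byte-identical output for identical configs."""
    cfg = cfg or SyntheticConfig()
    rng = np.random.default_rng(cfg.seed)

    # --- small molecules: cluster scaffolds with substituent edits ---
    sm_sizes = _cluster_sizes(cfg.n_small, cfg.n_sm_clusters)
    sm_ids, smiles, sm_clusters = [], [], []
    for c in range(cfg.n_sm_clusters):
        scaffold = _SCAFFOLDS[c % len(_SCAFFOLDS)]
        for i in range(sm_sizes[c]):
            sub = _SUBSTITUENTS[i % len(_SUBSTITUENTS)]
            # second substitution round keeps SMILES distinct past the list length
            extra = _SUBSTITUENTS[(i // len(_SUBSTITUENTS)) % len(_SUBSTITUENTS)] \
                if i >= len(_SUBSTITUENTS) else ""
            smi = extra + sub + scaffold
            if Chem.MolFromSmiles(smi) is None:  # pragma: no cover - template guard
                raise RuntimeError(f"internal template produced invalid SMILES {smi!r}")
            sm_ids.append(f"SM{len(sm_ids):04d}")
            smiles.append(smi)
            sm_clusters.append(c)
    sm_clusters = np.array(sm_clusters)

    # --- biotech drugs: shared first chain, cluster base chains, mutations ---
    shared_chain = "".join(_AA[k] for k in rng.integers(0, len(_AA), 40))
    bt_bases = ["".join(_AA[k] for k in rng.integers(0, len(_AA), 100))
                for _ in range(cfg.n_bt_clusters)]
    bt_bases2 = ["".join(_AA[k] for k in rng.integers(0, len(_AA), 80))
                 for _ in range(cfg.n_bt_clusters)]
    bt_sizes = _cluster_sizes(cfg.n_biotech, cfg.n_bt_clusters)
    bt_ids, bt_clusters, chains = [], [], {}
    for c in range(cfg.n_bt_clusters):
        for _ in range(bt_sizes[c]):
            drug_id = f"BT{len(bt_ids):04d}"
            n_chain = int(rng.integers(1, 4))
            drug_chains = []
            if n_chain >= 2:
                drug_chains.append(_mutate(shared_chain, 0.02, rng))
            drug_chains.append(_mutate(bt_bases[c], 0.08, rng))
            if n_chain == 3:
                drug_chains.append(_mutate(bt_bases2[c], 0.08, rng))
            chains[drug_id] = drug_chains
            bt_ids.append(drug_id)
            bt_clusters.append(c)
    bt_clusters = np.array(bt_clusters)

    # --- drug-target edges from per-cluster target blocks ---
    sm_targets = [f"TS{i:03d}" for i in range(cfg.n_targets)]
    bt_targets = [f"TB{i:03d}" for i in range(cfg.n_targets)]

    def target_edges(ids, clusters, n_clusters, targets):
        block = max(1, len(targets) // n_clusters)
        edges = []
        for d, c in zip(ids, clusters):
            if rng.random() < cfg.no_target_fraction:
                continue  # drugs with no targets are kept in the roster
            pool = targets[c * block:(c + 1) * block] or targets
            n_pick = int(rng.integers(2, min(5, len(pool)) + 1))
            picks = rng.choice(len(pool), size=min(n_pick, len(pool)), replace=False)
            edges += [(d, pool[p]) for p in sorted(picks)]
        return edges

    sti_edges = target_edges(sm_ids, sm_clusters, cfg.n_sm_clusters, sm_targets)
    bti_edges = target_edges(bt_ids, bt_clusters, cfg.n_bt_clusters, bt_targets)

    # --- within-population interaction edges, cluster-assortative ---
    def dd_edges(ids, clusters, p_in, p_out):
        edges = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                p = p_in if clusters[i] == clusters[j] else p_out
                if rng.random() < p:
                    edges.append((ids[i], ids[j]))
        return edges

    ssi_edges = dd_edges(sm_ids, sm_clusters, 0.15, 0.01)
    bbi_edges = dd_edges(bt_ids, bt_clusters, 0.30, 0.03)

    # --- planted pair labels ---
    rule = _combo_rule(cfg)
    width = len(str(cfg.n_classes - 1))
    label_vocab = ["negative"] + [f"type_{i:0{width}d}" for i in range(1, cfg.n_classes)]
    pairs = []
    for si, s in enumerate(sm_ids):
        for bi, b in enumerate(bt_ids):
            lab = rule[(int(sm_clusters[si]), int(bt_clusters[bi]))]
            if cfg.label_noise > 0 and rng.random() < cfg.label_noise:
                others = [c for c in range(cfg.n_classes) if c != lab]
                lab = others[rng.integers(len(others))]
            pairs.append((s, b, label_vocab[lab]))

    return SyntheticCorpus(
        config=cfg, sm_ids=sm_ids, smiles=smiles, bt_ids=bt_ids, chains=chains,
        ssi_edges=ssi_edges, bbi_edges=bbi_edges, sti_edges=sti_edges,
        bti_edges=bti_edges, sm_targets=sm_targets, bt_targets=bt_targets,
        pairs=pairs, label_vocab=label_vocab, sm_clusters=sm_clusters,
        bt_clusters=bt_clusters, rule=rule)
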