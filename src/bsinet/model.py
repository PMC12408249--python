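"""The full interaction-class prediction network.

A labelled example is a (small-molecule, biotech) drug pair.  The
small-molecule side contributes a graph-attention embedding of its molecular
graph concatenated with its fused similarity row; the biotech side
contributes its protein-sequence embedding concatenated with its fused
similarity row.  The two sides are concatenated and classified by a two
hidden-layer MLP with a softmax output over the interaction classes
(31 positive classes plus one negative class at full scale).

Width contract at the default configuration:

    graph branch            -> 512
    512 ‖ SSf row (2148)    -> 2660
    emb (1024) ‖ BBf (196)  -> 1220
    2660 ‖ 1220             -> 3880 -> MLP -> 32-class softmax

Training minimizes multiclass cross-entropy with Adam.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .chem_graphs import MolecularGraph
from .gat_core import GATLayerParams, gat_layer_forward, init_gat_params

__all__ = ["BSINetConfig", "PairExample", "BSINet", "GraphBatch",
           "small_molecule_vector", "biotech_vector", "cross_entropy"]


@dataclass
class BSINetConfig:
    """Architecture and training hyperparameters (defaults = full scale)."""

    gat1_out: int = 128
    gat1_heads: int = 4
    gat2_out: int = 256
    gat2_heads: int = 4
    dropout: float = 0.2
    fc_out: int = 512
    ssf_width: int = 2148
    bbf_width: int = 196
    emb_width: int = 1024
    n_classes: int = 32
    mlp_hidden: tuple = (2048, 512)
    learning_rate: float = 1e-3
    epsilon: float = 0.05          # stop when epoch training loss drops below
    max_epochs: int = 10
    batch_size: int = 256
    gat_activation: str = "elu"
    negative_slope: float = 0.2
    norm: str = "layer"            # inter-layer node-feature normalization

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")

    @property
    def pair_width(self) -> int:
        return self.fc_out + self.ssf_width + self.emb_width + self.bbf_width

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @staticmethod
    def from_json(text: str) -> "BSINetConfig":
        d = json.loads(text)
        d["mlp_hidden"] = tuple(d["mlp_hidden"])
        return BSINetConfig(**d)


@dataclass
class PairExample:
    """One assembled (small-molecule, biotech) pair with its class index."""

    sm_id: str
    bt_id: str
    graph: MolecularGraph
    ssf_row: np.ndarray
    bbf_row: np.ndarray
    emb: np.ndarray
    label: int


def small_molecule_vector(branch_out: np.ndarray, ssf_row: np.ndarray,
                          cfg: BSINetConfig) -> np.ndarray:
    """Graph-branch embedding ‖ fused similarity row (branch first)."""
    if branch_out.shape[-1] != cfg.fc_out or ssf_row.shape[-1] != cfg.ssf_width:
        raise ValueError("small-molecule vector width mismatch")
    return np.concatenate([branch_out, ssf_row], axis=-1)


def biotech_vector(emb: np.ndarray, bbf_row: np.ndarray,
                   cfg: BSINetConfig) -> np.ndarray:
    """Sequence embedding ‖ fused similarity row (embedding first)."""
    if emb.shape[-1] != cfg.emb_width or bbf_row.shape[-1] != cfg.bbf_width:
        raise ValueError("biotech vector width mismatch")
    return np.concatenate([emb, bbf_row], axis=-1)


def cross_entropy(y: np.ndarray, p: np.ndarray, clamp: float = 1e-12) -> float:
    """−Σ_i y_i log p_i for a one-hot y and probability vector p."""
    p = np.clip(np.asarray(p, dtype=np.float64), clamp, None)
    return float(-(np.asarray(y, dtype=np.float64) * np.log(p)).sum())


class _Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (d_in + d_out))
        self.W = Tensor(rng.normal(0.0, scale, (d_in, d_out)), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class _LayerNorm:
    def __init__(self, width: int):
        self.g = Tensor(np.ones(width), requires_grad=True)
        self.b = Tensor(np.zeros(width), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.layer_norm(x, self.g, self.b)

    def parameters(self):
        return [self.g, self.b]


class GraphBatch:
    """Disjoint union of molecular graphs for one vectorized forward pass."""

    def __init__(self, graphs: list[MolecularGraph]):
        feats, srcs, dsts, gids = [], [], [], []
        offset = 0
        for gi, g in enumerate(graphs):
            if g.n_atoms == 0:
                raise ValueError(f"empty graph for drug {g.drug_id}")
            feats.append(g.node_features)
            s, d = g.edge_arrays()
            srcs.append(s + offset)
            dsts.append(d + offset)
            gids.append(np.full(g.n_atoms, gi, dtype=np.intp))
            offset += g.n_atoms
        self.node_features = np.concatenate(feats, axis=0)
        self.src = np.concatenate(srcs)
        self.dst = np.concatenate(dsts)
        self.graph_ids = np.concatenate(gids)
        self.n_graphs = len(graphs)


class BSINet:
    """Graph-attention interaction classifier with explicit NumPy parameters."""

    def __init__(self, cfg: BSINetConfig, d_atom: int, seed: int = 0):
        self.cfg = cfg
        self.d_atom = d_atom
        self.rng = np.random.default_rng(seed)
        rng = self.rng
        self.gat1 = init_gat_params(d_atom, cfg.gat1_out, cfg.gat1_heads, rng,
                                    combine="concat", activation=cfg.gat_activation,
                                    negative_slope=cfg.negative_slope)
        w1 = self.gat1.out_width
        self.norm1 = _LayerNorm(w1)
        self.gat2 = init_gat_params(w1, cfg.gat2_out, cfg.gat2_heads, rng,
                                    combine="concat", activation=cfg.gat_activation,
                                    negative_slope=cfg.negative_slope)
        w2 = self.gat2.out_width
        self.norm2 = _LayerNorm(w2)
        self.fc = _Linear(w2, cfg.fc_out, rng)
        self.h1 = _Linear(cfg.pair_width, cfg.mlp_hidden[0], rng)
        self.h2 = _Linear(cfg.mlp_hidden[0], cfg.mlp_hidden[1], rng)
        self.out = _Linear(cfg.mlp_hidden[1], cfg.n_classes, rng)

    def parameters(self) -> list[Tensor]:
        params = self.gat1.parameters() + self.norm1.parameters() \
            + self.gat2.parameters() + self.norm2.parameters()
        for layer in (self.fc, self.h1, self.h2, self.out):
            params += layer.parameters()
        return params

    # -- graph branch --------------------------------------------------------
    def graph_branch_batch(self, batch: GraphBatch, training: bool = False) -> Tensor:
        cfg = self.cfg
        h = Tensor(batch.node_features)
        h = gat_layer_forward(h, batch.src, batch.dst, self.gat1)
        h = self.norm1(h)
        h = ad.dropout(h, cfg.dropout, self.rng, training)
        h = gat_layer_forward(h, batch.src, batch.dst, self.gat2)
        h = self.norm2(h)
        h = ad.dropout(h, cfg.dropout, self.rng, training)
        h = ad.relu(self.fc(h))
        return ad.segment_mean(h, batch.graph_ids, batch.n_graphs)

    def graph_branch(self, graph: MolecularGraph, training: bool = False) -> np.ndarray:
        """Embed one molecular graph into a `fc_out`-vector."""
        return self.graph_branch_batch(GraphBatch([graph]), training).data[0]

    # -- full forward ----------------------------------------------------------
    def _logits(self, graphs: GraphBatch, graph_index: np.ndarray,
                ssf_rows: np.ndarray, embs: np.ndarray, bbf_rows: np.ndarray,
                training: bool) -> Tensor:
        cfg = self.cfg
        gvec = self.graph_branch_batch(graphs, training)
        branch = ad.take_rows(gvec, graph_index)            # (B, fc_out)
        x = ad.concat([branch, Tensor(ssf_rows), Tensor(embs), Tensor(bbf_rows)],
                      axis=-1)                              # (B, pair_width)
        x = ad.dropout(ad.relu(self.h1(x)), cfg.dropout, self.rng, training)
        x = ad.dropout(ad.relu(self.h2(x)), cfg.dropout, self.rng, training)
        return self.out(x)

    def forward_batch(self, pairs: list[PairExample], training: bool = False,
                      labels: np.ndarray | None = None):
        """Probabilities for a batch of pairs; with `labels`, also the loss
        Tensor for backpropagation."""
        unique: dict[str, int] = {}
        graphs: list[MolecularGraph] = []
        gidx = np.empty(len(pairs), dtype=np.intp)
        for i, p in enumerate(pairs):
            if p.sm_id not in unique:
                unique[p.sm_id] = len(graphs)
                graphs.append(p.graph)
            gidx[i] = unique[p.sm_id]
        ssf = np.stack([p.ssf_row for p in pairs])
        emb = np.stack([p.emb for p in pairs])
        bbf = np.stack([p.bbf_row for p in pairs])
        if ssf.shape[1] != self.cfg.ssf_width or bbf.shape[1] != self.cfg.bbf_width \
                or emb.shape[1] != self.cfg.emb_width:
            raise ValueError("pair feature widths do not match the configuration")
        logits = self._logits(GraphBatch(graphs), gidx, ssf, emb, bbf, training)
        probs = ad.softmax(logits.data)
        if labels is None:
            return probs
        loss = ad.softmax_cross_entropy(logits, np.asarray(labels))
        return probs, loss

    def forward(self, pair: PairExample, training: bool = False) -> np.ndarray:
        """Class-probability vector (length n_classes, sums to 1) for one pair."""
        return self.forward_batch([pair], training=training)[0]

    # -- persistence --------------------------------------------------------------
    def _named_params(self) -> dict:
        named = {}
        for i, t in enumerate(self.gat1.parameters()):
            named[f"gat1.{i}"] = t
        for i, t in enumerate(self.gat2.parameters()):
            named[f"gat2.{i}"] = t
        for name, layer in (("norm1", self.norm1), ("norm2", self.norm2),
                            ("fc", self.fc), ("h1", self.h1), ("h2", self.h2),
                            ("out", self.out)):
            for i, t in enumerate(layer.parameters()):
                named[f"{name}.{i}"] = t
        return named

    def save(self, path: str):
        named = {k: t.data for k, t in self._named_params().items()}
        np.savez(path, __config__=np.frombuffer(
            self.cfg.to_json().encode(), dtype=np.uint8),
            __d_atom__=np.array([self.d_atom]), **named)

    @staticmethod
    def load(path: str) -> "BSINet":
        archive = np.load(path)
        cfg = BSINetConfig.from_json(bytes(archive["__config__"]).decode())
        model = BSINet(cfg, int(archive["__d_atom__"][0]))
        for name, t in model._named_params().items():
            t.data = archive[name].astype(np.float64)
        return model
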