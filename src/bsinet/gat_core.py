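"""Multi-head graph attention layer.

For node features h and a directed edge j→i (j a neighbor of i, self-loops
included), one head computes

    e_ij   = LeakyReLU( aᵀ [W h_i ‖ W h_j] )
    α_ij   = softmax_j( e_ij )            over j ∈ N(i)
    h'_i   = σ( Σ_j α_ij W h_j )

and head outputs are combined by concatenation (default here, giving width
K·d_out) or averaging (width d_out).  The implementation is edge-parallel
NumPy with reverse-mode gradients from :mod:`bsinet._autodiff`; the
neighborhood softmax uses per-node max subtraction for overflow safety.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import (Tensor, concat, elu, leaky_relu, segment_softmax,
                        segment_sum, take_rows)

__all__ = ["GATLayerParams", "attention_score", "attention_coefficients",
           "gat_layer_forward", "init_gat_params"]

_ACTIVATIONS = {
    "elu": elu,
    "relu": lambda t: leaky_relu(t, 0.0),
    "identity": lambda t: t,
}


@dataclass
class GATLayerParams:
    """Parameters of one multi-head attention layer.

    W[k] is (d_out, d_in) and a[k] is (2·d_out,) for head k.  `combine`
    chooses between concatenating head outputs (layer width K·d_out) and
    averaging them (width d_out).
    """

    W: list          # K tensors, each (d_out, d_in)
    a: list          # K tensors, each (2*d_out,)
    negative_slope: float = 0.2
    combine: str = "concat"
    activation: str = "elu"
    _extra: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.K < 1:
            raise ValueError("need at least one attention head")
        if self.combine not in ("concat", "average"):
            raise ValueError(f"unknown combine mode {self.combine!r}")
        shapes_w = {tuple(w.shape) for w in self.W}
        shapes_a = {tuple(av.shape) for av in self.a}
        if len(shapes_w) != 1 or len(shapes_a) != 1:
            raise ValueError("all heads must share (d_in, d_out)")

    @property
    def K(self) -> int:
        return len(self.W)

    @property
    def d_in(self) -> int:
        return self.W[0].shape[1]

    @property
    def d_out(self) -> int:
        return self.W[0].shape[0]

    @property
    def out_width(self) -> int:
        return self.K * self.d_out if self.combine == "concat" else self.d_out

    def parameters(self) -> list[Tensor]:
        return list(self.W) + list(self.a)


def init_gat_params(d_in: int, d_out: int, n_heads: int,
                    rng: np.random.Generator, combine: str = "concat",
                    activation: str = "elu",
                    negative_slope: float = 0.2) -> GATLayerParams:
    """Glorot-initialized layer parameters."""
    scale_w = np.sqrt(2.0 / (d_in + d_out))
    scale_a = np.sqrt(2.0 / (2 * d_out + 1))
    W = [Tensor(rng.normal(0.0, scale_w, (d_out, d_in)), requires_grad=True)
         for _ in range(n_heads)]
    a = [Tensor(rng.normal(0.0, scale_a, 2 * d_out), requires_grad=True)
         for _ in range(n_heads)]
    return GATLayerParams(W=W, a=a, negative_slope=negative_slope,
                          combine=combine, activation=activation)


def attention_score(h_i: np.ndarray, h_j: np.ndarray, W: np.ndarray,
                    a: np.ndarray, negative_slope: float = 0.2) -> float:
    """Unnormalized attention score of edge j→i for one head.

    Not symmetric in (i, j) in general: `a` weighs the transformed source
    and destination features differently.
    """
    h_i, h_j = np.atleast_1d(np.asarray(h_i, float)), np.atleast_1d(np.asarray(h_j, float))
    W = np.atleast_2d(np.asarray(W, float))
    a = np.asarray(a, float)
    if h_i.shape[0] != W.shape[1] or h_j.shape[0] != W.shape[1]:
        raise ValueError("feature width does not match W")
    z = a @ np.concatenate([W @ h_i, W @ h_j])
    return float(z if z > 0 else negative_slope * z)


def attention_coefficients(scores: np.ndarray) -> np.ndarray:
    """Softmax-normalized attention coefficients over one neighborhood."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size == 0:
        raise ValueError("empty neighborhood: add self-loops before attention")
    z = scores - scores.max()
    ez = np.exp(z)
    return ez / ez.sum()


def gat_layer_forward(node_features: Tensor | np.ndarray,
                      src: np.ndarray, dst: np.ndarray,
                      params: GATLayerParams,
                      return_alpha: bool = False):
    """One multi-head attention layer over a (possibly batched) graph.

    `src`/`dst` are aligned edge arrays; edge e carries the message
    src[e] → dst[e], so N(i) = {src[e] : dst[e] = i}.  Every node must
    appear as a destination (guaranteed by self-loops).  Returns the
    (n_nodes, out_width) embedding Tensor, plus the per-head edge attention
    coefficients when `return_alpha` is set.
    """
    h = node_features if isinstance(node_features, Tensor) else Tensor(node_features)
    n = h.shape[0]
    if len(src) == 0:
        raise ValueError("graph has no edges (self-loops missing?)")
    present = np.zeros(n, dtype=bool)
    present[np.asarray(dst)] = True
    if not present.all():
        raise ValueError("some nodes have empty neighborhoods; add self-loops")
    act = _ACTIVATIONS[params.activation]

    head_outputs = []
    alphas = []
    for W, a in zip(params.W, params.a):
        W = W if isinstance(W, Tensor) else Tensor(W)
        a = a if isinstance(a, Tensor) else Tensor(a)
        hw = h @ W.T                           # (n, d_out)
        d_out = params.d_out
        s_dst = hw @ a.narrow(0, d_out).reshape(d_out, 1)   # (n, 1)
        s_src = hw @ a.narrow(d_out, 2 * d_out).reshape(d_out, 1)
        e = leaky_relu(take_rows(s_dst, dst) + take_rows(s_src, src),
                       params.negative_slope)          # (E, 1)
        alpha = segment_softmax(e, dst, n)             # (E, 1)
        msgs = alpha * take_rows(hw, src)              # (E, d_out)
        agg = segment_sum(msgs, dst, n)                # (n, d_out)
        head_outputs.append(act(agg))
        alphas.append(alpha.data[:, 0])

    if params.combine == "concat":
        out = concat(head_outputs, axis=-1)
    else:
        out = head_outputs[0]
        for ho in head_outputs[1:]:
            out = out + ho
        out = out / params.K
    return (out, np.stack(alphas)) if return_alpha else out
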