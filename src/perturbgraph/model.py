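"""The two GNN modules: response prediction f_r and perturbagen discovery f_p.

Both modules share one architecture. Each node's input feature is built
from learnable per-node embedding tables (different between nodes, shared
across samples): a d-dimensional embedding selected by the quantile bin of
the node's expression value, a d-dimensional embedding for its second
attribute (the perturbation flag in f_r, the treated-state expression bin
in f_p), and a d-dimensional positional embedding — concatenated to a 3d
vector. K message-passing layers (mean aggregation over in-neighbors, one
learned linear map on the concatenated [h_i || mean_j h_j], ReLU update)
produce node embeddings, which a two-layer feedforward head maps to a
scalar per node: a value in [0, 1] for f_r (predicted post-perturbation
expression) or an unbounded score for f_p (likelihood the node is a
therapeutic target).

Perturbation flags in f_r may be *soft* (values in [0, 1]) so that cycle
training can differentiate through f_p's output: a soft flag f selects the
interpolation (1-f) * E[0] + f * E[1] between the node's two flag
embeddings, and the soft pass runs on the unmutilated graph.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from . import autodiff as ad
from ._seeds import rng_for
from .autodiff import Tensor
from .errors import ValidationError
from .graphs import ProxyCausalGraph


# ---------------------------------------------------------------------------
# Expression binning
# ---------------------------------------------------------------------------


def fit_bins(expression: np.ndarray, B: int, per_gene: bool = True) -> np.ndarray:
    """Quantile bin thresholds for expression values.

    ``expression`` is genes x samples in [0, 1]. Returns an (n_genes, B-1)
    array of thresholds at the equally spaced quantiles 1/B, ..., (B-1)/B
    (linear interpolation). With ``per_gene=False`` the same global
    thresholds are used for every gene. A constant gene yields identical
    thresholds, which maps all of its training values to bin 0.
    """
    if B < 2:
        raise ValidationError("B must be >= 2")
    expression = np.asarray(expression, float)
    qs = np.arange(1, B) / B
    if per_gene:
        thr = np.quantile(expression, qs, axis=1).T  # (n, B-1)
    else:
        glob = np.quantile(expression.ravel(), qs)
        thr = np.tile(glob, (expression.shape[0], 1))
    return np.ascontiguousarray(thr)


def assign_bins(x: np.ndarray, thresholds: np.ndarray) -> np.ndarray:
    """Bin index per value: the count of thresholds strictly below it.

    ``x`` is (S, n) or (n,); thresholds (n, B-1). A value equal to a
    threshold falls in the lower bin; constant-gene thresholds send the
    gene's own value to bin 0.
    """
    x = np.atleast_2d(np.asarray(x, float))
    return (x[:, :, None] > thresholds[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# Node feature encoding
# ---------------------------------------------------------------------------


class NodeFeatureEncoding:
    """Per-node embedding tables turning (expression, second attribute)
    pairs into 3d-dimensional node features.

    ``second`` selects what the second attribute is: "flag" (f_r: a
    perturbation flag in [0, 1], embedded by linear interpolation between
    two per-node states) or "expression" (f_p: a second expression value,
    embedded through its own bin table using the same thresholds).
    """

    def __init__(self, thresholds: np.ndarray, d: int, seed: int,
                 second: str = "flag", dtype: str = "float64"):
        if second not in ("flag", "expression"):
            raise ValidationError(f"unknown second-attribute kind {second!r}")
        self.dtype = np.dtype(dtype)
        self.thresholds = np.asarray(thresholds, float)
        self.n, bm1 = self.thresholds.shape
        self.B = bm1 + 1
        self.d = d
        self.second = second
        sd = 1.0 / np.sqrt(d)
        rng = rng_for(seed, "encoding", second)
        dt = self.dtype
        self.bin_table = ad.parameter(rng.normal(0, sd, (self.n, self.B, d)).astype(dt))
        n_second = 2 if second == "flag" else self.B
        self.second_table = ad.parameter(
            rng.normal(0, sd, (self.n, n_second, d)).astype(dt))
        self.pos_table = ad.parameter(rng.normal(0, sd, (self.n, d)).astype(dt))

    def parameters(self) -> list[Tensor]:
        return [self.bin_table, self.second_table, self.pos_table]

    def encode(self, x: np.ndarray, second: Union[np.ndarray, Tensor]) -> Tensor:
        """Encode a batch: x (S, n) expression, ``second`` (S, n) flags or
        expression values. Returns (S, n, 3d)."""
        x = np.atleast_2d(np.asarray(x, float))
        S, n = x.shape
        if n != self.n:
            raise ValidationError(f"expected {self.n} nodes, got {n}")
        bin_emb = ad.gather_nodes(self.bin_table, assign_bins(x, self.thresholds))
        if self.second == "flag":
            f = second if isinstance(second, Tensor) else Tensor(
                np.atleast_2d(np.asarray(second)).astype(self.dtype))
            if f.data.shape != (S, n):
                raise ValidationError("flag shape must match expression shape")
            e0 = ad.gather_nodes(self.second_table, np.zeros((S, n), int))
            e1 = ad.gather_nodes(self.second_table, np.ones((S, n), int))
            fe = f.reshape(S, n, 1)
            sec_emb = e0 + fe * (e1 - e0)
        else:
            sec = np.atleast_2d(np.asarray(second, float))
            sec_emb = ad.gather_nodes(self.second_table, assign_bins(sec, self.thresholds))
        pos = Tensor(np.broadcast_to(self.pos_table.data[None], (S, n, self.d)),
                     parents=(self.pos_table,))
        pos._backward = lambda g: self.pos_table.accumulate(g.sum(axis=0))
        pos.requires_grad = self.pos_table.requires_grad
        return ad.concat([sec_emb, bin_emb, pos], axis=-1)


def encode_nodes(x: np.ndarray, flags: np.ndarray, enc: NodeFeatureEncoding) -> np.ndarray:
    """Single-sample node-feature matrix (n x 3d) as a plain array."""
    return enc.encode(np.atleast_2d(x), np.atleast_2d(flags)).data[0]


# ---------------------------------------------------------------------------
# Adjacency normalization
# ---------------------------------------------------------------------------


def aggregation_matrix(g: ProxyCausalGraph, aggregator: str = "mean") -> np.ndarray:
    """Adjacency operator matching a model's aggregator: row-normalized
    in-neighbor matrix for "mean", the raw 0/1 in-neighbor matrix for
    "sum"."""
    if aggregator == "mean":
        return normalized_adjacency(g)
    if aggregator == "sum":
        return g.adjacency_matrix()
    raise ValidationError(f"unknown aggregator {aggregator!r}")


def normalized_adjacency(g: ProxyCausalGraph) -> np.ndarray:
    """Row-normalized in-neighbor matrix for mean aggregation.

    Entry [i, j] = 1/indeg(i) if arc j -> i exists. Rows of in-degree-0
    nodes are zero, so such nodes aggregate nothing (sources and
    intervened nodes after mutilation).
    """
    A = g.adjacency_matrix()
    deg = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        An = np.where(deg > 0, A / np.maximum(deg, 1e-300), 0.0)
    return An


# ---------------------------------------------------------------------------
# Core GNN
# ---------------------------------------------------------------------------


class _GNNCore:
    """Shared architecture of f_r and f_p (encoding -> K layers -> head)."""

    def __init__(self, thresholds: np.ndarray, d: int, K: int, seed: int,
                 second: str, aggregator: str = "mean", dtype: str = "float64"):
        if K < 0:
            raise ValidationError("K must be >= 0")
        if aggregator not in ("mean", "sum"):
            raise ValidationError(f"unknown aggregator {aggregator!r}")
        self.enc = NodeFeatureEncoding(thresholds, d, seed, second=second,
                                       dtype=dtype)
        self.d, self.K = d, K
        self.aggregator = aggregator
        self.dtype = np.dtype(dtype)
        dt = self.dtype
        F = 3 * d
        rng = rng_for(seed, "gnn", second)
        self.layers: list[tuple[Tensor, Tensor]] = []
        for k in range(K):
            W = ad.parameter(rng.normal(0, 1.0 / np.sqrt(2 * F), (2 * F, F)).astype(dt))
            b = ad.parameter(np.zeros(F, dtype=dt))
            self.layers.append((W, b))
        hidden = 2 * d
        self.head_W1 = ad.parameter(rng.normal(0, 1.0 / np.sqrt(F), (F, hidden)).astype(dt))
        self.head_b1 = ad.parameter(np.zeros(hidden, dtype=dt))
        self.head_W2 = ad.parameter(
            rng.normal(0, 1.0 / np.sqrt(hidden), (hidden, 1)).astype(dt))
        self.head_b2 = ad.parameter(np.zeros(1, dtype=dt))

    def parameters(self) -> list[Tensor]:
        ps = self.enc.parameters()
        for W, b in self.layers:
            ps += [W, b]
        ps += [self.head_W1, self.head_b1, self.head_W2, self.head_b2]
        return ps

    def set_requires_grad(self, flag: bool) -> None:
        for p in self.parameters():
            p.requires_grad = flag

    def _logits(self, A_norm, H: Tensor) -> Tensor:
        # A_norm: (n, n), (S, n, n), or a (stack, slices) pair of grouped
        # adjacencies; dense maps run as single 2-D GEMMs
        S, n, _ = H.data.shape
        for W, b in self.layers:
            if isinstance(A_norm, tuple):
                agg = ad.grouped_matmul(A_norm[0], A_norm[1], H)
            else:
                agg = ad.matmul_const(A_norm, H)
            F_in = H.data.shape[-1]
            Hcat = ad.concat([H, agg], axis=-1).reshape(S * n, 2 * F_in)
            H = ad.relu(Hcat @ W + b).reshape(S, n, W.data.shape[1])
        F = H.data.shape[-1]
        h = ad.relu(H.reshape(S * n, F) @ self.head_W1 + self.head_b1)
        out = h @ self.head_W2 + self.head_b2
        return out.reshape(S, n)

    # -- checkpointing -------------------------------------------------

    def state_arrays(self) -> dict[str, np.ndarray]:
        named = {"enc.bin": self.enc.bin_table, "enc.second": self.enc.second_table,
                 "enc.pos": self.enc.pos_table,
                 "head.W1": self.head_W1, "head.b1": self.head_b1,
                 "head.W2": self.head_W2, "head.b2": self.head_b2}
        for k, (W, b) in enumerate(self.layers):
            named[f"layer{k}.W"] = W
            named[f"layer{k}.b"] = b
        return {k: v.data for k, v in named.items()}

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for k, v in self.state_arrays().items():
            v[...] = arrays[k]

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}


class ResponseModel(_GNNCore):
    """f_r: predicts the post-perturbation expression state in [0, 1]^n."""

    def __init__(self, thresholds: np.ndarray, d: int = 16, K: int = 2,
                 seed: int = 0, aggregator: str = "mean", dtype: str = "float64"):
        super().__init__(thresholds, d, K, seed, second="flag",
                         aggregator=aggregator, dtype=dtype)

    def forward_logits(self, A_norm: np.ndarray, x_in: np.ndarray,
                       u_flags: Union[np.ndarray, Tensor]) -> Tensor:
        """Pre-sigmoid node outputs; used by the training losses."""
        H = self.enc.encode(x_in, u_flags)
        return self._logits(A_norm, H)

    def forward(self, A_norm: np.ndarray, x_in: np.ndarray,
                u_flags: Union[np.ndarray, Tensor]) -> np.ndarray:
        """Predicted post-perturbation state, (S, n) in [0, 1]."""
        return ad.sigmoid(self.forward_logits(A_norm, x_in, u_flags)).data


class PerturbagenModel(_GNNCore):
    """f_p: scores every node's likelihood of being a therapeutic target."""

    def __init__(self, thresholds: np.ndarray, d: int = 16, K: int = 2,
                 seed: int = 0, aggregator: str = "mean", dtype: str = "float64"):
        super().__init__(thresholds, d, K, seed, second="expression",
                         aggregator=aggregator, dtype=dtype)

    def forward_scores(self, A_norm: np.ndarray, x_d: np.ndarray,
                       x_t: np.ndarray) -> Tensor:
        H = self.enc.encode(x_d, x_t)
        return self._logits(A_norm, H)

    def forward(self, A_norm: np.ndarray, x_d: np.ndarray, x_t: np.ndarray,
                tie_rule: str = "index", seed: Optional[int] = None
                ) -> list["PerturbagenRanking"]:
        scores = self.forward_scores(A_norm, np.atleast_2d(x_d),
                                     np.atleast_2d(x_t)).data
        return [rank_nodes(row, tie_rule=tie_rule, seed=seed) for row in scores]


# ---------------------------------------------------------------------------
# Rankings
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbagenRanking:
    """Per-node scores plus the induced total order (node indices, best
    first). ``tie_rule`` records how equal scores were ordered."""

    scores: np.ndarray
    order: np.ndarray
    tie_rule: str = "index"

    def top(self, k: int) -> np.ndarray:
        return self.order[:k]

    def rank_of(self, node_index: int) -> int:
        """1-based rank of a node."""
        return int(np.nonzero(self.order == node_index)[0][0]) + 1


def rank_nodes(scores: np.ndarray, tie_rule: str = "index",
               seed: Optional[int] = None) -> PerturbagenRanking:
    """Total order of nodes by non-increasing score.

    Ties are broken by ascending node index (default) or by a seeded
    shuffle (``tie_rule="shuffle"``).
    """
    scores = np.asarray(scores, float)
    if np.any(np.isnan(scores)):
        raise ValidationError("scores contain NaN")
    n = scores.shape[0]
    if tie_rule == "index":
        order = np.argsort(-scores, kind="stable")
    elif tie_rule == "shuffle":
        if seed is None:
            raise ValidationError("tie_rule='shuffle' requires a seed")
        perm = rng_for(seed, "tie-shuffle").permutation(n)
        order = perm[np.argsort(-scores[perm], kind="stable")]
    else:
        raise ValidationError(f"unknown tie rule {tie_rule!r}")
    return PerturbagenRanking(scores=scores, order=order, tie_rule=tie_rule)


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(model: _GNNCore, path: str | Path) -> None:
    """Serialize architecture config + parameters; loading reproduces
    forward outputs bit-identically on the same platform."""
    path = Path(path)
    cfg = {
        "kind": "response" if isinstance(model, ResponseModel) else "perturbagen",
        "d": model.d, "K": model.K, "aggregator": model.aggregator,
        "B": model.enc.B, "dtype": model.dtype.name,
    }
    arrays = {f"param/{k}": v for k, v in model.state_arrays().items()}
    np.savez(path, thresholds=model.enc.thresholds,
             config=np.frombuffer(json.dumps(cfg).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path: str | Path) -> _GNNCore:
    with np.load(Path(path), allow_pickle=False) as z:
        cfg = json.loads(bytes(z["config"]).decode())
        cls = ResponseModel if cfg["kind"] == "response" else PerturbagenModel
        model = cls(z["thresholds"], d=cfg["d"], K=cfg["K"],
                    aggregator=cfg["aggregator"], dtype=cfg.get("dtype", "float64"))
        model.load_state_arrays(
            {k[len("param/"):]: z[k] for k in z.files if k.startswith("param/")}
        )
    return model
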