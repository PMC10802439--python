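"""Proxy causal graphs: gene-gene networks used as imperfect stand-ins for
the causal graph among genes.

A :class:`ProxyCausalGraph` stores named nodes and directed arcs; undirected
inputs (PPI-like networks) are doubled into a pair of arcs per edge so that
do-operator mutilation — deleting the arcs *into* intervened nodes — is well
defined for both graph kinds. This module also provides the edge-corruption
procedures used in robustness studies (bridge-edge removal, random-edge
removal), confidence-quantile filtering, and undirected shortest-path
distances for network-proximity analyses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._seeds import rng_for
from .errors import FormatError, ValidationError

Arc = tuple[str, str]

ORIGIN_DIRECTED = "directed"
ORIGIN_UNDIRECTED = "undirected-doubled"


@dataclass(frozen=True)
class InterventionSet:
    """A non-empty set of gene nodes acted on by an intervention.

    ``kind`` distinguishes disease-causing perturbations from therapeutic
    perturbagens; the graph surgery they induce is identical.
    """

    members: frozenset[str]
    kind: str = "perturbagen"  # {"disease", "perturbagen"}

    def __post_init__(self):
        object.__setattr__(self, "members", frozenset(self.members))
        if not self.members:
            raise ValidationError("intervention set must be non-empty")
        if self.kind not in ("disease", "perturbagen"):
            raise ValidationError(f"unknown intervention kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(sorted(self.members))


@dataclass(frozen=True)
class ProxyCausalGraph:
    """Directed graph over named gene nodes with optional arc confidences.

    Invariants: no duplicate arcs, every arc endpoint is a listed node,
    at least one node. ``origin`` records whether the graph came from a
    directed edge list or from doubling an undirected one.
    """

    node_ids: tuple[str, ...]
    arcs: tuple[Arc, ...]
    confidences: Optional[Mapping[Arc, float]] = None
    origin: str = ORIGIN_DIRECTED
    _index: Mapping[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if len(self.node_ids) == 0:
            raise ValidationError("graph must have at least one node")
        if len(set(self.node_ids)) != len(self.node_ids):
            raise ValidationError("duplicate node ids")
        if len(set(self.arcs)) != len(self.arcs):
            raise ValidationError("duplicate arcs")
        nodes = set(self.node_ids)
        for a, b in self.arcs:
            if a not in nodes or b not in nodes:
                raise ValidationError(f"arc ({a!r}, {b!r}) has unknown endpoint")
        if self.confidences is not None:
            for arc, c in self.confidences.items():
                if not (0.0 <= c <= 1.0):
                    raise ValidationError(
                        f"confidence {c} for arc {arc} outside [0, 1]"
                    )
        object.__setattr__(
            self, "_index", {n: i for i, n in enumerate(self.node_ids)}
        )

    # -- basic views ---------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_arcs(self) -> int:
        return len(self.arcs)

    def node_index(self, node: str) -> int:
        try:
            return self._index[node]
        except KeyError:
            raise ValidationError(f"unknown node {node!r}") from None

    def has_node(self, node: str) -> bool:
        return node in self._index

    def in_neighbors(self, node: str) -> list[str]:
        self.node_index(node)
        return [a for a, b in self.arcs if b == node]

    def to_networkx(self, directed: bool = True) -> nx.Graph:
        """Export to networkx; ``directed=False`` gives the undirected view."""
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(self.node_ids)
        g.add_edges_from(self.arcs)
        return g

    def undirected_edges(self) -> set[frozenset[str]]:
        """The undirected edge set (canonical unordered pairs)."""
        return {frozenset((a, b)) for a, b in self.arcs}

    def adjacency_matrix(self) -> np.ndarray:
        """Dense n x n matrix A with A[i, j] = 1 iff arc j -> i exists.

        Row i indexes the in-neighborhood of node i, the orientation used
        for message passing (information flows along arcs).
        """
        A = np.zeros((self.n_nodes, self.n_nodes))
        for a, b in self.arcs:
            A[self._index[b], self._index[a]] = 1.0
        return A


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_edge_list(
    path: str | Path,
    directed: bool = False,
    confidence_column: Optional[str] = None,
) -> ProxyCausalGraph:
    """Read a TSV/CSV edge list into a :class:`ProxyCausalGraph`.

    The file needs a header with at least two columns (source, target);
    an optional confidence column holds values in [0, 1]. Undirected input
    is doubled into two arcs per edge. Duplicate rows collapse; node order
    is first-appearance order.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"empty edge-list file: {path}") from None
    if df.shape[1] < 2:
        raise FormatError(f"edge list needs >= 2 columns, got {df.shape[1]}")
    if df.shape[0] == 0:
        raise ValidationError(f"edge-list file has no rows: {path}")
    src_col, tgt_col = df.columns[:2]
    if confidence_column is not None and confidence_column not in df.columns:
        raise FormatError(
            f"confidence column {confidence_column!r} not in {list(df.columns)}"
        )

    node_ids: list[str] = []
    seen: set[str] = set()
    arcs: list[Arc] = []
    arc_seen: set[Arc] = set()
    conf: dict[Arc, float] = {}
    for row in df.itertuples(index=False):
        a, b = str(getattr(row, src_col)), str(getattr(row, tgt_col))
        for v in (a, b):
            if v not in seen:
                seen.add(v)
                node_ids.append(v)
        c = None
        if confidence_column is not None:
            c = float(getattr(row, confidence_column))
            if not (0.0 <= c <= 1.0) or math.isnan(c):
                raise ValidationError(f"confidence {c} outside [0, 1]")
        pairs = [(a, b)] if directed else [(a, b), (b, a)]
        for arc in pairs:
            if arc in arc_seen:
                continue
            arc_seen.add(arc)
            arcs.append(arc)
            if c is not None:
                conf[arc] = c
    return ProxyCausalGraph(
        node_ids=tuple(node_ids),
        arcs=tuple(arcs),
        confidences=conf if confidence_column is not None else None,
        origin=ORIGIN_DIRECTED if directed else ORIGIN_UNDIRECTED,
    )


def save_edge_list(g: ProxyCausalGraph, path: str | Path) -> None:
    """Write the arc list back to TSV (``source\\ttarget[\\tconfidence]``).

    Arcs are written as stored, so a mutilated or corrupted graph
    round-trips losslessly through ``load_edge_list(..., directed=True)``.
    """
    rows = []
    for arc in g.arcs:
        row = {"source": arc[0], "target": arc[1]}
        if g.confidences is not None:
            row["confidence"] = g.confidences.get(arc, np.nan)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Graph surgery
# ---------------------------------------------------------------------------


def mutilate(g: ProxyCausalGraph, u: InterventionSet | Iterable[str]) -> ProxyCausalGraph:
    """Apply the do-operator graph surgery for intervention set ``u``.

    All arcs *into* intervened nodes are deleted (their values are set
    exogenously, so they no longer listen to their parents); arcs *out of*
    intervened nodes are kept so the intervention's effects propagate.
    Returns a new graph; ``g`` is unchanged.
    """
    members = set(u.members if isinstance(u, InterventionSet) else u)
    if not members:
        raise ValidationError("intervention set must be non-empty")
    for node in members:
        g.node_index(node)  # raises ValidationError on unknown node
    kept = tuple(arc for arc in g.arcs if arc[1] not in members)
    conf = None
    if g.confidences is not None:
        conf = {arc: c for arc, c in g.confidences.items() if arc[1] not in members}
    return replace(g, arcs=kept, confidences=conf)


def filter_by_confidence(g: ProxyCausalGraph, quantile: float) -> ProxyCausalGraph:
    """Drop arcs whose confidence falls below the q-th quantile of the
    confidence distribution.

    Convention (the choice matters for absolute edge counts): the cutoff is
    the linear-interpolation quantile of all arc confidences, and arcs with
    confidence strictly below the cutoff are removed — so ``quantile=0``
    keeps everything and ``quantile=1`` keeps only maximum-confidence arcs.
    The node set is unchanged.
    """
    if g.confidences is None:
        raise ValidationError("graph has no confidences to filter on")
    if not (0.0 <= quantile <= 1.0):
        raise ValidationError(f"quantile {quantile} outside [0, 1]")
    values = np.array([g.confidences[a] for a in g.arcs])
    cut = float(np.quantile(values, quantile))
    kept = tuple(a for a in g.arcs if g.confidences[a] >= cut)
    conf = {a: g.confidences[a] for a in kept}
    return replace(g, arcs=kept, confidences=conf)


def find_bridges(g: ProxyCausalGraph) -> set[frozenset[str]]:
    """Bridge edges of the undirected view: edges whose removal increases
    the number of connected components."""
    ug = g.to_networkx(directed=False)
    return {frozenset(e) for e in nx.bridges(ug)}


def _remove_undirected(
    g: ProxyCausalGraph, edges: Sequence[frozenset[str]], fraction: float, seed: int,
    stream: str,
) -> ProxyCausalGraph:
    if not (0.0 <= fraction <= 1.0):
        raise ValidationError(f"fraction {fraction} outside [0, 1]")
    k = math.floor(fraction * len(edges))
    if k == 0:
        return g
    order = sorted(edges, key=lambda e: tuple(sorted(e)))
    rng = rng_for(seed, stream)
    chosen = {order[i] for i in rng.choice(len(order), size=k, replace=False)}
    kept = tuple(a for a in g.arcs if frozenset(a) not in chosen)
    conf = None
    if g.confidences is not None:
        conf = {a: c for a, c in g.confidences.items() if frozenset(a) not in chosen}
    return replace(g, arcs=kept, confidences=conf)


def remove_bridge_edges(g: ProxyCausalGraph, fraction: float, seed: int) -> ProxyCausalGraph:
    """Remove a seeded uniform sample of floor(fraction * #bridges) bridge
    edges (both arcs when doubled). Bridges are computed on the input graph
    once, not recomputed as edges fall away."""
    return _remove_undirected(g, sorted(find_bridges(g), key=lambda e: tuple(sorted(e))),
                              fraction, seed, "bridge-removal")


def remove_random_edges(g: ProxyCausalGraph, fraction: float, seed: int) -> ProxyCausalGraph:
    """Remove a seeded uniform sample of floor(fraction * #edges) undirected
    edges (both arcs when doubled)."""
    return _remove_undirected(g, sorted(g.undirected_edges(), key=lambda e: tuple(sorted(e))),
                              fraction, seed, "random-removal")


def shortest_path_distance(g: ProxyCausalGraph, a: str, b: str) -> float:
    """Hop count of the shortest path between ``a`` and ``b`` on the
    undirected view; 0 iff a == b; ``math.inf`` when disconnected."""
    g.node_index(a)
    g.node_index(b)
    if a == b:
        return 0.0
    ug = g.to_networkx(directed=False)
    try:
        return float(nx.shortest_path_length(ug, a, b))
    except nx.NetworkXNoPath:
        return math.inf
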