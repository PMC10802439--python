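"""Structural-causal-model simulator for intervention datasets.

Generates the two dataset kinds the method trains on, with known ground
truth: disease intervention triplets (healthy state, disease-gene set,
diseased state) and treatment intervention triplets (diseased state,
perturbagen gene set, treated state). States follow logistic-linear
structural equations with additive Gaussian exogenous noise,

    x_i = logistic( sum_{j in Pa(i)} w_ij x_j + b_i + eps_i ),

evaluated in topological order on a random DAG; intervened nodes are
clamped to exogenous values (do-semantics), so their parents are ignored.
The logistic keeps every state in [0, 1], matching normalized expression.
Also implements the latent-confounder corruption used in robustness
studies: grouped Gaussian offsets added to expression and clamped to [0, 1].
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from ._seeds import derive_seed, rng_for
from .errors import FormatError, ValidationError
from .graphs import ORIGIN_DIRECTED, InterventionSet, ProxyCausalGraph


def _logistic(z: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class SCMParameters:
    """Ground truth of the simulator: an acyclic proxy causal graph with
    arc weights, node biases, and an exogenous noise scale."""

    graph: ProxyCausalGraph
    weights: Mapping[tuple[str, str], float]
    biases: Mapping[str, float]
    noise_sd: float = 0.05
    activation: str = "logistic"
    topo_order: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.activation != "logistic":
            raise ValidationError(f"unsupported activation {self.activation!r}")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        if set(self.weights) != set(self.graph.arcs):
            raise ValidationError("weights must be defined exactly on arcs")
        order = self.topo_order or tuple(self.graph.node_ids)
        if sorted(order) != sorted(self.graph.node_ids):
            raise ValidationError("topo_order must permute the graph nodes")
        pos = {n: i for i, n in enumerate(order)}
        for a, b in self.graph.arcs:
            if pos[a] >= pos[b]:
                raise ValidationError(
                    f"topo_order violated by arc ({a!r}, {b!r}); graph must be acyclic"
                )
        object.__setattr__(self, "topo_order", order)

    def content_hash(self) -> str:
        """Stable hash of the SCM for provenance manifests."""
        h = hashlib.sha256()
        for n in self.graph.node_ids:
            h.update(f"{n}:{self.biases[n]:.17g};".encode())
        for arc in sorted(self.weights):
            h.update(f"{arc}:{self.weights[arc]:.17g};".encode())
        h.update(f"sd={self.noise_sd:.17g}".encode())
        return h.hexdigest()[:16]


@dataclass(frozen=True)
class InterventionTriplet:
    """One paired sample: initial state, intervened gene set, outcome state."""

    x_initial: np.ndarray
    u: InterventionSet
    x_outcome: np.ndarray
    context: str = "sim"
    perturbagen_id: Optional[str] = None

    def __post_init__(self):
        xi = np.asarray(self.x_initial, dtype=float)
        xo = np.asarray(self.x_outcome, dtype=float)
        if xi.shape != xo.shape or xi.ndim != 1:
            raise ValidationError("state vectors must be 1-D and equal length")
        for name, v in (("x_initial", xi), ("x_outcome", xo)):
            if np.any(v < 0) or np.any(v > 1) or not np.all(np.isfinite(v)):
                raise ValidationError(f"{name} values must lie in [0, 1]")
        object.__setattr__(self, "x_initial", xi)
        object.__setattr__(self, "x_outcome", xo)


@dataclass(frozen=True)
class ConfounderSpec:
    """Latent-confounder corruption: genes partitioned into groups, each
    group assigned a Gaussian offset distribution; a random fraction of
    groups is perturbed."""

    fraction_perturbed: float
    n_groups: int = 50
    mean_range: tuple[float, float] = (-0.5, 0.5)
    sd_range: tuple[float, float] = (0.1, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fraction_perturbed <= 1.0):
            raise ValidationError("fraction_perturbed must be in (0, 1]")
        if self.n_groups < 1:
            raise ValidationError("n_groups must be >= 1")
        if self.sd_range[0] < 0 or self.sd_range[1] < self.sd_range[0]:
            raise ValidationError("sd_range must be ordered and non-negative")


# ---------------------------------------------------------------------------
# SCM sampling and simulation
# ---------------------------------------------------------------------------


def sample_scm(
    n_nodes: int,
    arc_density: float,
    seed: int,
    noise_sd: float = 0.05,
) -> SCMParameters:
    """Sample a random DAG-based SCM.

    Nodes are ordered randomly; each forward pair (i, j), i before j, keeps
    an arc with probability ``arc_density``, which guarantees acyclicity.
    Weights are uniform on +/-[0.5, 2] (random sign), biases uniform[-1, 1].
    """
    if n_nodes < 2:
        raise ValidationError("n_nodes must be >= 2")
    if not (0.0 <= arc_density <= 1.0):
        raise ValidationError("arc_density must be in [0, 1]")
    rng = rng_for(seed, "scm")
    width = len(str(n_nodes - 1))
    node_ids = tuple(f"g{i:0{width}d}" for i in range(n_nodes))
    order = tuple(np.array(node_ids)[rng.permutation(n_nodes)])
    arcs = []
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < arc_density:
                arcs.append((order[i], order[j]))
    weights = {}
    for arc in arcs:
        mag = rng.uniform(0.5, 2.0)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        weights[arc] = sign * mag
    biases = {n: float(rng.uniform(-1.0, 1.0)) for n in node_ids}
    graph = ProxyCausalGraph(
        node_ids=node_ids, arcs=tuple(arcs), origin=ORIGIN_DIRECTED
    )
    return SCMParameters(
        graph=graph, weights=weights, biases=biases, noise_sd=noise_sd,
        topo_order=order, seed=seed,
    )


def simulate_state(
    scm: SCMParameters,
    u: Optional[InterventionSet] = None,
    clamp_values: Optional[Mapping[str, float]] = None,
    noise_seed: int = 0,
) -> np.ndarray:
    """Evaluate the structural equations once, optionally under do(u).

    Intervened nodes take their clamp value and ignore their parents
    (equivalent to mutilating the graph before evaluation); all other
    nodes get logistic(sum_j w_ij x_j + b_i + eps_i) with eps_i ~
    Normal(0, noise_sd). The full exogenous vector eps is drawn from
    ``noise_seed`` up front, so two calls with the same seed but different
    interventions share their exogenous variation.
    """
    members = set(u.members) if u is not None else set()
    clamp_values = dict(clamp_values or {})
    if set(clamp_values) != members:
        raise ValidationError("clamp_values keys must equal the intervened set")
    for node in members:
        scm.graph.node_index(node)
        if not (0.0 <= clamp_values[node] <= 1.0):
            raise ValidationError("clamp values must lie in [0, 1]")
    rng = np.random.default_rng(noise_seed)
    eps = rng.normal(0.0, scm.noise_sd, size=scm.graph.n_nodes) if scm.noise_sd > 0 \
        else np.zeros(scm.graph.n_nodes)
    parents: dict[str, list[tuple[str, float]]] = {n: [] for n in scm.graph.node_ids}
    for (a, b), w in scm.weights.items():
        parents[b].append((a, w))
    x: dict[str, float] = {}
    for node in scm.topo_order:
        if node in members:
            x[node] = float(clamp_values[node])
        else:
            z = scm.biases[node] + eps[scm.graph.node_index(node)]
            for p, w in parents[node]:
                z += w * x[p]
            x[node] = float(_logistic(z))
    return np.array([x[n] for n in scm.graph.node_ids])


# ---------------------------------------------------------------------------
# Intervention clamp draws
# ---------------------------------------------------------------------------

# Clamps emulate strong knock-down / activation: per intervened gene a fixed
# direction (down or up), with per-sample values drawn from Beta(0.5, 5)
# (mass near 0) or Beta(5, 0.5) (mass near 1) respectively.
_BETA_DOWN = (0.5, 5.0)
_BETA_UP = (5.0, 0.5)


def _clamp_directions(genes: Sequence[str], seed: int, stream: str) -> dict[str, bool]:
    rng = rng_for(seed, stream)
    return {g: bool(rng.random() < 0.5) for g in sorted(genes)}


def _draw_clamps(
    genes: Sequence[str], up: Mapping[str, bool], rng: np.random.Generator
) -> dict[str, float]:
    out = {}
    for g in sorted(genes):
        a, b = _BETA_UP if up[g] else _BETA_DOWN
        out[g] = float(rng.beta(a, b))
    return out


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------


def generate_disease_dataset(
    scm: SCMParameters,
    disease_genes: InterventionSet,
    m: int,
    seed: int,
    context: str = "sim",
    shared_noise: bool = True,
    clamp_values: Optional[Mapping[str, float]] = None,
) -> list[InterventionTriplet]:
    """m disease intervention triplets (x_healthy, disease genes, x_diseased).

    Per sample, the healthy state is an unintervened simulation and the
    diseased state applies do(disease_genes) with strong up/down clamps
    (direction fixed per gene for the whole dataset, value redrawn per
    sample). With ``shared_noise`` the two states share their exogenous
    draw, emulating paired profiling of the same biological background;
    ``clamp_values`` overrides the clamp draw with fixed values.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    for gene in disease_genes:
        scm.graph.node_index(gene)
    up = _clamp_directions(sorted(disease_genes), seed, "disease-direction")
    clamp_rng = rng_for(seed, "disease-clamps")
    out = []
    for s in range(m):
        noise_h = derive_seed(seed, "disease-noise", s, "h")
        noise_d = noise_h if shared_noise else derive_seed(seed, "disease-noise", s, "d")
        clamps = dict(clamp_values) if clamp_values is not None else \
            _draw_clamps(sorted(disease_genes), up, clamp_rng)
        x_h = simulate_state(scm, None, None, noise_seed=noise_h)
        x_d = simulate_state(scm, disease_genes, clamps, noise_seed=noise_d)
        out.append(InterventionTriplet(x_h, disease_genes, x_d, context=context))
    return out


def generate_treatment_dataset(
    scm: SCMParameters,
    library: Sequence[InterventionSet],
    m_per_perturbagen: int,
    seed: int,
    disease_genes: InterventionSet,
    context: str = "sim",
    shared_noise: bool = True,
    clamp_overrides: Optional[Mapping[int, Mapping[str, float]]] = None,
    keep_disease_intervention: bool = False,
) -> list[InterventionTriplet]:
    """Treatment intervention triplets (x_diseased, perturbagen, x_treated).

    For each perturbagen in the library and each of ``m_per_perturbagen``
    samples: the diseased state applies do(disease_genes); the treated
    state applies do(perturbagen) to the same exogenous draw (plus the
    disease clamps too when ``keep_disease_intervention``). Each triplet
    records its library entry in ``perturbagen_id`` so held-out-perturbagen
    splits can be built.
    """
    if len(library) == 0:
        raise ValidationError("perturbagen library must be non-empty")
    if m_per_perturbagen < 1:
        raise ValidationError("m_per_perturbagen must be >= 1")
    for p in library:
        for gene in p:
            scm.graph.node_index(gene)
    dis_up = _clamp_directions(sorted(disease_genes), seed, "disease-direction")
    out = []
    for pi, pert in enumerate(library):
        pert_up = _clamp_directions(sorted(pert), seed, f"pert-direction/{pi}")
        clamp_rng = rng_for(seed, "treatment-clamps", pi)
        for s in range(m_per_perturbagen):
            noise_d = derive_seed(seed, "treatment-noise", pi, s, "d")
            noise_t = noise_d if shared_noise else derive_seed(seed, "treatment-noise", pi, s, "t")
            dis_clamps = _draw_clamps(sorted(disease_genes), dis_up, clamp_rng)
            if clamp_overrides is not None and pi in clamp_overrides:
                pert_clamps = dict(clamp_overrides[pi])
            else:
                pert_clamps = _draw_clamps(sorted(pert), pert_up, clamp_rng)
            x_d = simulate_state(scm, disease_genes, dis_clamps, noise_seed=noise_d)
            if keep_disease_intervention:
                u_treat = InterventionSet(disease_genes.members | pert.members, "perturbagen")
                clamps = {**dis_clamps, **pert_clamps}
            else:
                u_treat, clamps = pert, pert_clamps
            x_t = simulate_state(scm, u_treat, clamps, noise_seed=noise_t)
            out.append(
                InterventionTriplet(x_d, pert, x_t, context=context,
                                    perturbagen_id=f"p{pi:03d}")
            )
    return out


def inject_confounders(
    dataset: Sequence[InterventionTriplet], spec: ConfounderSpec
) -> list[InterventionTriplet]:
    """Add grouped Gaussian confounder noise to every expression value.

    Genes are partitioned into ``n_groups`` contiguous, near-equal index
    blocks; each group g gets mu_g ~ U(mean_range) and sd_g ~ U(sd_range);
    a seeded random fraction of groups is selected; every expression value
    of a gene in a selected group is incremented by a fresh
    Normal(mu_g, sd_g) draw and clamped to [0, 1]. Intervention sets and
    labels are untouched.
    """
    if len(dataset) == 0:
        return []
    n = dataset[0].x_initial.shape[0]
    groups = np.array_split(np.arange(n), spec.n_groups)
    rng = rng_for(spec.seed, "confounders")
    mus = rng.uniform(spec.mean_range[0], spec.mean_range[1], size=spec.n_groups)
    sds = rng.uniform(spec.sd_range[0], spec.sd_range[1], size=spec.n_groups)
    n_sel = int(spec.fraction_perturbed * spec.n_groups + 0.5)
    selected = rng.choice(spec.n_groups, size=n_sel, replace=False)
    out = []
    for t in dataset:
        xi, xo = t.x_initial.copy(), t.x_outcome.copy()
        for gidx in selected:
            idx = groups[gidx]
            if len(idx) == 0:
                continue
            xi[idx] += rng.normal(mus[gidx], sds[gidx], size=len(idx))
            xo[idx] += rng.normal(mus[gidx], sds[gidx], size=len(idx))
        np.clip(xi, 0.0, 1.0, out=xi)
        np.clip(xo, 0.0, 1.0, out=xo)
        out.append(InterventionTriplet(xi, t.u, xo, t.context, t.perturbagen_id))
    return out


# ---------------------------------------------------------------------------
# Dataset directory I/O
# ---------------------------------------------------------------------------

_INITIAL = "expression_initial.tsv"
_OUTCOME = "expression_outcome.tsv"
_INTERV = "interventions.tsv"
_MANIFEST = "manifest.yaml"


def write_dataset(
    dataset: Sequence[InterventionTriplet],
    directory: str | Path,
    node_ids: Sequence[str],
    manifest_extra: Optional[Mapping] = None,
) -> None:
    """Serialize a dataset to TSV matrices + intervention table + manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    sample_ids = [f"s{i:05d}" for i in range(len(dataset))]
    xi = np.column_stack([t.x_initial for t in dataset]) if dataset else \
        np.zeros((len(node_ids), 0))
    xo = np.column_stack([t.x_outcome for t in dataset]) if dataset else \
        np.zeros((len(node_ids), 0))
    for fname, mat in ((_INITIAL, xi), (_OUTCOME, xo)):
        pd.DataFrame(mat, index=list(node_ids), columns=sample_ids).to_csv(
            directory / fname, sep="\t", float_format="%.17g", index_label="gene"
        )
    rows = [
        {
            "sample_id": sid,
            "kind": t.u.kind,
            "genes": ",".join(sorted(t.u.members)),
            "context": t.context,
            "perturbagen_id": t.perturbagen_id or "",
        }
        for sid, t in zip(sample_ids, dataset)
    ]
    pd.DataFrame(rows).to_csv(directory / _INTERV, sep="\t", index=False)
    manifest = {"n_samples": len(dataset), "n_genes": len(node_ids)}
    if manifest_extra:
        manifest.update(dict(manifest_extra))
    with open(directory / _MANIFEST, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)


def read_dataset(directory: str | Path) -> tuple[list[InterventionTriplet], dict]:
    """Inverse of :func:`write_dataset`; validates schema and [0, 1] bounds."""
    directory = Path(directory)
    if not (directory / _MANIFEST).exists():
        raise FormatError(f"missing manifest in {directory}")
    with open(directory / _MANIFEST) as fh:
        manifest = yaml.safe_load(fh)
    try:
        xi = pd.read_csv(directory / _INITIAL, sep="\t", index_col=0,
                         float_precision="round_trip")
        xo = pd.read_csv(directory / _OUTCOME, sep="\t", index_col=0,
                         float_precision="round_trip")
        iv = pd.read_csv(directory / _INTERV, sep="\t", keep_default_na=False)
    except FileNotFoundError as e:
        raise FormatError(f"incomplete dataset directory: {e}") from None
    if list(xi.columns) != list(xo.columns) or len(iv) != xi.shape[1]:
        raise FormatError("expression matrices and intervention table disagree")
    manifest = dict(manifest or {})
    manifest.setdefault("genes", [str(g) for g in xi.index])
    out = []
    for k, row in enumerate(iv.itertuples(index=False)):
        u = InterventionSet(frozenset(str(row.genes).split(",")), str(row.kind))
        out.append(
            InterventionTriplet(
                xi.iloc[:, k].to_numpy(), u, xo.iloc[:, k].to_numpy(),
                context=str(row.context),
                perturbagen_id=(str(row.perturbagen_id) or None),
            )
        )
    return out, manifest
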