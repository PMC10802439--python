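"""Losses, data splits, and the dual training loop.

The response module f_r minimizes cross-entropy between predicted and
observed post-intervention states over known triplets (disease and/or
treatment). The discovery module f_p minimizes, depending on ``loss_mode``:

* ``super`` — per-node binary cross-entropy between its scores and the
  indicator of the true target set (positive class weighted n/|U'| to
  counter the extreme class imbalance);
* ``cycle`` — cross-entropy between the true treated state and the frozen
  f_r's response to f_p's (soft) predicted perturbagen;
* ``supercycle`` — the unweighted sum of both.

The two modules are trained in parallel in the ordering sense: each epoch
runs an f_r update, then an f_p update with f_r frozen. Each module early
stops independently when its validation loss has not improved by at least
``min_delta`` for ``patience`` consecutive epochs, and the reported model
is its best-validation snapshot.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from . import autodiff as ad
from ._seeds import derive_seed, rng_for
from .autodiff import Adam, Tensor
from .errors import TrainingDivergedError, ValidationError
from .graphs import ProxyCausalGraph, mutilate
from .model import (PerturbagenModel, ResponseModel, aggregation_matrix,
                    fit_bins)
from .synthdata import InterventionTriplet

LOSS_MODES = ("super", "cycle", "supercycle")


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of one training run."""

    loss_mode: str = "supercycle"
    max_epochs: int = 200
    patience: int = 15
    min_delta: float = 1e-5
    learning_rate: float = 1e-3
    batch_size: Optional[int] = None  # None = full batch
    K: int = 2
    K_grid: tuple[int, ...] = (1, 2, 3)
    d: int = 16
    B: int = 5
    aggregator: str = "mean"
    dtype: str = "float64"  # "float32" roughly halves training time
    use_disease_data: bool = True
    disease_loss_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.loss_mode not in LOSS_MODES:
            raise ValidationError(f"loss_mode must be one of {LOSS_MODES}")
        if self.patience < 1 or self.min_delta < 0:
            raise ValidationError("patience >= 1 and min_delta >= 0 required")


@dataclass(frozen=True)
class FoldSplit:
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray


@dataclass(frozen=True)
class SampleSplit:
    """A cross-validation split: per-fold disjoint train/val/test indices."""

    folds: tuple[FoldSplit, ...]

    def __len__(self) -> int:
        return len(self.folds)


class EarlyStopper:
    """Patience-based early stopping on a validation-loss trace.

    The counter resets exactly when the loss improves on the best seen so
    far by at least ``min_delta``; after ``patience`` consecutive
    non-improving epochs, :meth:`update` returns True (stop).
    """

    def __init__(self, patience: int = 15, min_delta: float = 1e-5):
        self.patience = patience
        self.min_delta = min_delta
        self.best = math.inf
        self.best_epoch = -1
        self.counter = 0
        self.epoch = -1

    def update(self, loss: float) -> bool:
        self.epoch += 1
        if self.best - loss >= self.min_delta:
            self.best = loss
            self.best_epoch = self.epoch
            self.counter = 0
        else:
            self.counter += 1
        return self.counter >= self.patience


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

_EPS = 1e-7


def loss_response(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean continuous-target cross-entropy -[t log p + (1-t) log(1-p)].

    Both arguments lie in [0, 1]; predictions are clipped to
    (1e-7, 1 - 1e-7). The minimum over p for fixed t is the entropy of t,
    so the loss is zero only for binary targets.
    """
    pred = np.asarray(pred, float)
    target = np.asarray(target, float)
    if pred.shape != target.shape:
        raise ValidationError("pred and target must have the same shape")
    if np.any(target < 0) or np.any(target > 1):
        raise ValidationError("targets must lie in [0, 1]")
    p = np.clip(pred, _EPS, 1 - _EPS)
    return float(np.mean(-(target * np.log(p) + (1 - target) * np.log1p(-p))))


def supervision_loss(scores: Tensor, u_mask: np.ndarray) -> Tensor:
    """Class-weighted BCE between f_p scores and the target indicator.

    Positive nodes (true targets) are weighted n / |U'| per sample so the
    handful of targets is not drowned by the ~n negatives.
    """
    u_mask = np.asarray(u_mask, float)
    if not np.any(u_mask):
        raise ValidationError("u_true must be non-empty")
    n = u_mask.shape[-1]
    k = u_mask.sum(axis=-1, keepdims=True)
    weights = np.where(u_mask > 0, n / k, 1.0)
    return ad.bce_with_logits(scores, u_mask, weights)


def cycle_loss(scores: Tensor, fr: ResponseModel, A_unmut: np.ndarray,
               x_d: np.ndarray, x_t: np.ndarray) -> Tensor:
    """CE(x_t, f_r(x_d, sigma(f_p scores))) with f_r frozen.

    The discovery module's scores are squashed to soft perturbation flags
    and fed to f_r through embedding interpolation on the unmutilated
    graph, keeping the whole pipeline differentiable in f_p's parameters.
    """
    soft_flags = ad.sigmoid(scores)
    frozen = [p.requires_grad for p in fr.parameters()]
    fr.set_requires_grad(False)
    try:
        logits = fr.forward_logits(A_unmut, x_d, soft_flags)
    finally:
        for p, f in zip(fr.parameters(), frozen):
            p.requires_grad = f
    return ad.bce_with_logits(logits, np.asarray(x_t, float))


def loss_perturbagen(scores: Tensor, fr: ResponseModel, A_unmut: np.ndarray,
                     x_d: np.ndarray, x_t: np.ndarray, u_mask: np.ndarray,
                     mode: str = "supercycle") -> Tensor:
    """The discovery-module loss for the requested ablation mode.

    ``supercycle`` is the exact (unit-weight) sum of the ``cycle`` and
    ``super`` terms.
    """
    if mode not in LOSS_MODES:
        raise ValidationError(f"unknown loss mode {mode!r}")
    if mode == "super":
        return supervision_loss(scores, u_mask)
    if mode == "cycle":
        return cycle_loss(scores, fr, A_unmut, x_d, x_t)
    return cycle_loss(scores, fr, A_unmut, x_d, x_t) + supervision_loss(scores, u_mask)


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _train_val(indices: np.ndarray, rng: np.random.Generator,
               val_fraction: float = 0.2) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(indices)
    n_val = max(1, int(round(val_fraction * len(perm))))
    return np.sort(perm[n_val:]), np.sort(perm[:n_val])


def make_random_splits(n_samples: int, n_folds: int = 5, seed: int = 0) -> SampleSplit:
    """Seeded k-fold split with an 8:2 train/validation split inside each
    fold's training portion. Fold sizes differ by at most one."""
    if n_samples < n_folds:
        raise ValidationError(f"need >= {n_folds} samples, got {n_samples}")
    rng = rng_for(seed, "random-split")
    perm = rng.permutation(n_samples)
    fold_tests = np.array_split(perm, n_folds)
    folds = []
    for k, test in enumerate(fold_tests):
        rest = np.setdiff1d(perm, test)
        train, val = _train_val(rest, rng_for(seed, "random-split-val", k))
        folds.append(FoldSplit(train, val, np.sort(test)))
    return SampleSplit(tuple(folds))


def make_leave_cell_out(
    datasets: Mapping[str, Sequence[InterventionTriplet]],
    train_context: str,
    n_folds: int = 5,
    seed: int = 0,
) -> tuple[list[InterventionTriplet], SampleSplit]:
    """Leave-cell-out split: train/val from one cellular context, test on
    every other context.

    Returns the concatenated dataset (train context first) and a split
    whose every fold tests on the full union of held-out contexts while
    train/val rotate within the training context.
    """
    if train_context not in datasets:
        raise ValidationError(f"unknown context {train_context!r}")
    if len(datasets) < 2:
        raise ValidationError("leave-cell-out needs >= 2 contexts")
    train_data = list(datasets[train_context])
    other = [t for ctx in sorted(datasets) if ctx != train_context
             for t in datasets[ctx]]
    combined = train_data + other
    test_idx = np.arange(len(train_data), len(combined))
    inner = make_random_splits(len(train_data), n_folds=n_folds, seed=seed)
    # the inner fold's held-out portion is not tested here, so it joins the
    # training pool; only the other contexts are tested
    folds = tuple(
        FoldSplit(np.sort(np.concatenate([f.train_idx, f.test_idx])),
                  f.val_idx, test_idx)
        for f in inner.folds
    )
    return combined, SampleSplit(folds)


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _stack_states(dataset: Sequence[InterventionTriplet], node_index: Mapping[str, int],
                  n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    S = len(dataset)
    X_in = np.stack([t.x_initial for t in dataset])
    X_out = np.stack([t.x_outcome for t in dataset])
    U = np.zeros((S, n))
    for s, t in enumerate(dataset):
        for gene in t.u.members:
            U[s, node_index[gene]] = 1.0
    return X_in, X_out, U


def _grouped_adjacency(
    g: ProxyCausalGraph, dataset: Sequence[InterventionTriplet], aggregator: str
) -> tuple[np.ndarray, list[slice], np.ndarray, np.ndarray]:
    """Mutilated aggregation matrices grouped by intervention set.

    Returns (A_stack, slices, group_ids, order): ``order`` permutes the
    dataset so samples sharing an intervention set are contiguous, after
    which samples in ``slices[k]`` use ``A_stack[k]`` and ``group_ids``
    maps each (reordered) sample to its matrix.
    """
    key_to_gid: dict[frozenset, int] = {}
    mats: list[np.ndarray] = []
    gids = np.empty(len(dataset), int)
    for s, t in enumerate(dataset):
        key = t.u.members
        if key not in key_to_gid:
            key_to_gid[key] = len(mats)
            mats.append(aggregation_matrix(mutilate(g, t.u), aggregator))
        gids[s] = key_to_gid[key]
    order = np.argsort(gids, kind="stable")
    gids = gids[order]
    bounds = np.flatnonzero(np.diff(gids)) + 1
    starts = np.concatenate([[0], bounds])
    ends = np.concatenate([bounds, [len(dataset)]])
    slices = [slice(int(a), int(b)) for a, b in zip(starts, ends)]
    # slices index groups in sorted-gid order; align the stack with them
    stack = np.stack([mats[gids[s.start]] for s in slices])
    slice_gid = {int(gids[s.start]): k for k, s in enumerate(slices)}
    gids = np.array([slice_gid[int(gg)] for gg in gids])
    return stack, slices, gids, order


@dataclass
class TrainingHistory:
    train_fr: list[float] = field(default_factory=list)
    val_fr: list[float] = field(default_factory=list)
    train_fp: list[float] = field(default_factory=list)
    val_fp: list[float] = field(default_factory=list)
    stopped_fr: Optional[int] = None
    stopped_fp: Optional[int] = None
    best_epoch_fr: Optional[int] = None
    best_epoch_fp: Optional[int] = None


def train(
    treatment_dataset: Sequence[InterventionTriplet],
    g: ProxyCausalGraph,
    cfg: TrainConfig,
    fold: FoldSplit,
    disease_dataset: Optional[Sequence[InterventionTriplet]] = None,
    thresholds: Optional[np.ndarray] = None,
    pretrained_fr: Optional[ResponseModel] = None,
) -> tuple[ResponseModel, PerturbagenModel, TrainingHistory]:
    """Train f_r and f_p on one fold.

    ``fold`` indexes ``treatment_dataset``; the disease dataset, when used,
    joins f_r's training objective in full (it has no held-out role).
    Expression-bin thresholds are fitted on the fold's training expression
    unless supplied. ``pretrained_fr`` skips response-module training and
    uses the given module as-is; because f_r's updates never depend on
    f_p, a response module trained under the same config is identical to
    the one this run would produce, so this is a pure caching device for
    loss modes that do not feed f_p's gradients through f_r.
    """
    n = g.n_nodes
    node_index = {nd: i for i, nd in enumerate(g.node_ids)}
    train_set = [treatment_dataset[i] for i in fold.train_idx]
    val_set = [treatment_dataset[i] for i in fold.val_idx]
    if not train_set or not val_set:
        raise ValidationError("fold must have non-empty train and val sets")

    # group samples by intervention set so mutilated-graph message passing
    # runs one GEMM per unique perturbagen
    A_tr = _grouped_adjacency(g, train_set, cfg.aggregator)
    train_set = [train_set[i] for i in A_tr[3]]
    A_va = _grouped_adjacency(g, val_set, cfg.aggregator)
    val_set = [val_set[i] for i in A_va[3]]

    Xd_tr, Xt_tr, U_tr = _stack_states(train_set, node_index, n)
    Xd_va, Xt_va, U_va = _stack_states(val_set, node_index, n)
    if thresholds is None:
        expr = np.concatenate([Xd_tr, Xt_tr]).T  # genes x samples
        thresholds = fit_bins(expr, cfg.B)

    A_un = aggregation_matrix(g, cfg.aggregator)

    use_disease = cfg.use_disease_data and disease_dataset is not None \
        and len(disease_dataset) > 0
    if use_disease:
        A_di = _grouped_adjacency(g, disease_dataset, cfg.aggregator)
        disease_sorted = [disease_dataset[i] for i in A_di[3]]
        Xh_di, Xd_di, U_di = _stack_states(disease_sorted, node_index, n)

    if pretrained_fr is not None:
        fr = pretrained_fr
    else:
        fr = ResponseModel(thresholds, d=cfg.d, K=cfg.K,
                           seed=derive_seed(cfg.seed, "fr"),
                           aggregator=cfg.aggregator, dtype=cfg.dtype)
    fp = PerturbagenModel(thresholds, d=cfg.d, K=cfg.K,
                          seed=derive_seed(cfg.seed, "fp"), aggregator=cfg.aggregator,
                          dtype=cfg.dtype)
    opt_fr = Adam(fr.parameters(), lr=cfg.learning_rate)
    opt_fp = Adam(fp.parameters(), lr=cfg.learning_rate)
    stop_fr = EarlyStopper(cfg.patience, cfg.min_delta)
    stop_fp = EarlyStopper(cfg.patience, cfg.min_delta)
    hist = TrainingHistory()
    best_fr = fr.snapshot()
    best_fp = fp.snapshot()
    batch_rng = rng_for(cfg.seed, "batches")

    def _batches(S: int):
        if cfg.batch_size is None or cfg.batch_size >= S:
            yield np.arange(S)
            return
        perm = batch_rng.permutation(S)
        for start in range(0, S, cfg.batch_size):
            yield perm[start:start + cfg.batch_size]

    def _fr_loss(Agrp, X_in, X_out, U, grad: bool) -> float:
        A_stack, slices, gids, _ = Agrp
        total, count = 0.0, 0
        for idx in _batches(len(X_in)):
            A = (A_stack, slices) if len(idx) == len(X_in) else A_stack[gids[idx]]
            logits = fr.forward_logits(A, X_in[idx], U[idx])
            loss = ad.bce_with_logits(logits, X_out[idx])
            if grad:
                opt_fr.zero_grad()
                loss.backward()
                opt_fr.step()
            total += loss.item() * len(idx)
            count += len(idx)
        return total / count

    def _fp_loss(X_d, X_t, U, grad: bool) -> float:
        total, count = 0.0, 0
        for idx in _batches(len(X_d)):
            scores = fp.forward_scores(A_un, X_d[idx], X_t[idx])
            loss = loss_perturbagen(scores, fr, A_un, X_d[idx], X_t[idx],
                                    U[idx], cfg.loss_mode)
            if grad:
                opt_fp.zero_grad()
                loss.backward()
                opt_fp.step()
            total += loss.item() * len(idx)
            count += len(idx)
        return total / count

    done_fr = pretrained_fr is not None
    done_fp = False
    if done_fr:
        best_fr = fr.snapshot()
    for epoch in range(cfg.max_epochs):
        if not done_fr:
            tr_loss = _fr_loss(A_tr, Xd_tr, Xt_tr, U_tr, grad=True)
            if use_disease and cfg.disease_loss_weight > 0:
                # disease triplets enter f_r's objective as extra batches
                tr_loss += cfg.disease_loss_weight * _fr_loss(
                    A_di, Xh_di, Xd_di, U_di, grad=True)
            va_loss = _fr_loss(A_va, Xd_va, Xt_va, U_va, grad=False)
            if not (math.isfinite(tr_loss) and math.isfinite(va_loss)):
                raise TrainingDivergedError("fr", epoch)
            hist.train_fr.append(tr_loss)
            hist.val_fr.append(va_loss)
            improved = stop_fr.best - va_loss >= stop_fr.min_delta
            if stop_fr.update(va_loss):
                done_fr = True
                hist.stopped_fr = epoch
            if improved:
                best_fr = fr.snapshot()
        if not done_fp:
            tr_loss = _fp_loss(Xd_tr, Xt_tr, U_tr, grad=True)
            va_loss = _fp_loss(Xd_va, Xt_va, U_va, grad=False)
            if not (math.isfinite(tr_loss) and math.isfinite(va_loss)):
                raise TrainingDivergedError("fp", epoch)
            hist.train_fp.append(tr_loss)
            hist.val_fp.append(va_loss)
            improved = stop_fp.best - va_loss >= stop_fp.min_delta
            if stop_fp.update(va_loss):
                done_fp = True
                hist.stopped_fp = epoch
            if improved:
                best_fp = fp.snapshot()
        if done_fr and done_fp:
            break

    fr.load_state_arrays(best_fr)
    fp.load_state_arrays(best_fp)
    hist.best_epoch_fr = stop_fr.best_epoch
    hist.best_epoch_fp = stop_fp.best_epoch
    return fr, fp, hist


def grid_search_K(
    treatment_dataset: Sequence[InterventionTriplet],
    g: ProxyCausalGraph,
    cfg: TrainConfig,
    fold: FoldSplit,
    disease_dataset: Optional[Sequence[InterventionTriplet]] = None,
) -> tuple[int, ResponseModel, PerturbagenModel, dict[int, TrainingHistory]]:
    """Fit one model per K in ``cfg.K_grid`` and keep the best by
    validation nDCG of the discovery module (ties favor smaller K)."""
    from .evaluation import ndcg  # local import to avoid a cycle

    if not cfg.K_grid:
        raise ValidationError("K_grid must be non-empty")
    node_index = {nd: i for i, nd in enumerate(g.node_ids)}
    val_set = [treatment_dataset[i] for i in fold.val_idx]
    best = None
    histories: dict[int, TrainingHistory] = {}
    for K in sorted(cfg.K_grid):
        fr, fp, hist = train(treatment_dataset, g, replace(cfg, K=K), fold,
                             disease_dataset)
        histories[K] = hist
        A_un = aggregation_matrix(g, cfg.aggregator)
        Xd, Xt, _ = _stack_states(val_set, node_index, g.n_nodes)
        rankings = fp.forward(A_un, Xd, Xt)
        vals = [ndcg(r, {node_index[m] for m in t.u.members}, g.n_nodes)
                for r, t in zip(rankings, val_set)]
        score = float(np.mean(vals))
        if best is None or score > best[0] + 1e-12:
            best = (score, K, fr, fp)
    _, K, fr, fp = best
    return K, fr, fp, histories
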