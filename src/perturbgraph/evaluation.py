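"""Ranking metrics, baselines, network proximity, and statistical tests.

Ranking quality of predicted therapeutic targets uses nDCG with the gain
function 1 - rank/n and the standard logarithmic discount 1/log2(rank+1)
(the discount choice changes absolute nDCG values and is documented here
prominently for that reason), recall@k, and the percentage of accurately
predicted samples — samples whose top-N predictions (N = true target-set
size) intersect the true targets. Response-prediction quality uses squared
Pearson correlations (sample-wise and perturbagen-wise). Network proximity
between predicted and true target sets is the mean shortest-path distance
over all cross pairs, compared against a random reference with a one-sided
Mann-Whitney U test, rank-biserial effect size, and a percentile bootstrap
confidence interval.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from ._seeds import rng_for
from .errors import ValidationError
from .graphs import ProxyCausalGraph
from .model import PerturbagenRanking, rank_nodes

logger = logging.getLogger(__name__)


def _truth_set(truth: Iterable[int]) -> set[int]:
    t = set(int(i) for i in truth)
    if not t:
        raise ValidationError("truth set must be non-empty")
    return t


def _order_of(ranking: PerturbagenRanking | np.ndarray) -> np.ndarray:
    return ranking.order if isinstance(ranking, PerturbagenRanking) else \
        np.asarray(ranking, int)


# ---------------------------------------------------------------------------
# Ranking metrics
# ---------------------------------------------------------------------------


def ndcg(ranking: PerturbagenRanking | np.ndarray, truth: Iterable[int],
         n: int) -> float:
    """Normalized DCG of true targets in a predicted node ranking.

    DCG sums, over true targets, gain (1 - rank/n) discounted by
    1/log2(rank + 1) with 1-based ranks; IDCG places the |truth| targets
    at ranks 1..|truth|. Equals 1 iff all true targets occupy the top
    |truth| positions.
    """
    truth = _truth_set(truth)
    order = _order_of(ranking)
    pos = {int(node): r + 1 for r, node in enumerate(order)}
    dcg = sum((1 - pos[t] / n) / math.log2(pos[t] + 1) for t in truth)
    idcg = sum((1 - r / n) / math.log2(r + 1) for r in range(1, len(truth) + 1))
    return dcg / idcg


def recall_at_k(ranking: PerturbagenRanking | np.ndarray, truth: Iterable[int],
                k: int) -> float:
    """|top-k intersect truth| / |truth|."""
    truth = _truth_set(truth)
    order = _order_of(ranking)
    if not (1 <= k <= len(order)):
        raise ValidationError(f"k must be in [1, {len(order)}], got {k}")
    return len(set(order[:k].tolist()) & truth) / len(truth)


def accurately_predicted(ranking: PerturbagenRanking | np.ndarray,
                         truth: Iterable[int]) -> bool:
    """True iff the top-|truth| prefix intersects the truth set."""
    truth = _truth_set(truth)
    order = _order_of(ranking)
    return len(set(order[:len(truth)].tolist()) & truth) > 0


def pct_accurately_predicted(
    rankings: Sequence[PerturbagenRanking | np.ndarray],
    truths: Sequence[Iterable[int]],
) -> float:
    """100 x fraction of samples accurately predicted."""
    if len(rankings) != len(truths):
        raise ValidationError("rankings and truths must align")
    hits = [accurately_predicted(r, t) for r, t in zip(rankings, truths)]
    return 100.0 * float(np.mean(hits))


# ---------------------------------------------------------------------------
# R2 metrics
# ---------------------------------------------------------------------------


def samplewise_r2(pred: np.ndarray, truth: np.ndarray) -> float:
    """Squared Pearson correlation between one predicted and one observed
    expression vector; NaN (missing) when either vector is constant."""
    pred = np.asarray(pred, float)
    truth = np.asarray(truth, float)
    if pred.shape != truth.shape or pred.ndim != 1:
        raise ValidationError("vectors must be 1-D and aligned")
    if len(pred) < 3:
        raise ValidationError("need length >= 3")
    if np.ptp(pred) == 0 or np.ptp(truth) == 0:
        return float("nan")
    r = stats.pearsonr(pred, truth).statistic
    return float(r * r)


def perturbagenwise_r2(pred_set: np.ndarray, truth_set: np.ndarray) -> float:
    """Squared Pearson r of the least-squares fit between per-gene mean
    predicted and mean observed treated profiles for one perturbagen.

    Inputs are genes x samples matrices over samples sharing the
    perturbagen; column order does not matter.
    """
    pred_set = np.atleast_2d(np.asarray(pred_set, float))
    truth_set = np.atleast_2d(np.asarray(truth_set, float))
    if pred_set.shape[0] != truth_set.shape[0]:
        raise ValidationError("gene dimensions must agree")
    return samplewise_r2(pred_set.mean(axis=1), truth_set.mean(axis=1))


# ---------------------------------------------------------------------------
# Network proximity
# ---------------------------------------------------------------------------


def proximity(g: ProxyCausalGraph, predicted: Iterable[str], truth: Iterable[str],
              variant: str = "mean") -> float:
    """Mean undirected shortest-path distance over all (predicted, truth)
    node pairs.

    Disconnected pairs are excluded from the average and their count
    logged. ``variant="closest"`` instead averages, over truth nodes, the
    distance to the nearest predicted node (off by default; the mean
    variant is the primary definition).
    """
    P = sorted(set(predicted))
    R = sorted(set(truth))
    if not P or not R:
        raise ValidationError("both node sets must be non-empty")
    for node in (*P, *R):
        g.node_index(node)
    ug = g.to_networkx(directed=False)
    dropped = 0
    per_truth: list[list[float]] = []
    for r in R:
        dist = nx.single_source_shortest_path_length(ug, r)
        row = []
        for p in P:
            if p in dist:
                row.append(float(dist[p]))
            else:
                dropped += 1
        per_truth.append(row)
    if dropped:
        logger.info("proximity: excluded %d disconnected pair(s)", dropped)
    if variant == "mean":
        flat = [d for row in per_truth for d in row]
        return float(np.mean(flat)) if flat else float("nan")
    if variant == "closest":
        mins = [min(row) for row in per_truth if row]
        return float(np.mean(mins)) if mins else float("nan")
    raise ValidationError(f"unknown proximity variant {variant!r}")


@dataclass(frozen=True)
class ProximityTestResult:
    """Mann-Whitney comparison of proximity distributions.

    Sign convention: the U statistic counts method-vs-random pairs where
    the method distance is larger, so rank-biserial r = 2U/(n1 n2) - 1 is
    *negative* when the method's predictions are closer to the truth than
    random, and the one-sided p tests exactly that direction.
    """

    u_statistic: float
    p_value: float
    rank_biserial: float
    ci_low: float
    ci_high: float
    n_method: int
    n_random: int
    values_method: tuple[float, ...] = ()
    values_random: tuple[float, ...] = ()


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U of x relative to y: #(x > y) + 0.5 #(x == y), via pooled ranks."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2)


def proximity_test(values_method: Sequence[float], values_random: Sequence[float],
                   n_boot: int = 1000, seed: int = 0) -> ProximityTestResult:
    """One-sided Mann-Whitney U test (alternative: method distances are
    smaller than random) with rank-biserial effect size and a percentile
    bootstrap 95% CI over ``n_boot`` resamples."""
    x = np.asarray(values_method, float)
    y = np.asarray(values_random, float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("both samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="less")
    u = float(res.statistic)
    r = 2 * u / (len(x) * len(y)) - 1
    rng = rng_for(seed, "proximity-bootstrap")
    boots = np.empty(n_boot)
    for i in range(n_boot):
        xb = x[rng.integers(0, len(x), len(x))]
        yb = y[rng.integers(0, len(y), len(y))]
        boots[i] = 2 * _u_statistic(xb, yb) / (len(x) * len(y)) - 1
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return ProximityTestResult(
        u_statistic=u, p_value=float(res.pvalue), rank_biserial=float(r),
        ci_low=float(lo), ci_high=float(hi), n_method=len(x), n_random=len(y),
        values_method=tuple(x), values_random=tuple(y),
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------


def baseline_rank(kind: str, prior: Optional[Sequence[int]], n: int,
                  seed: int) -> PerturbagenRanking:
    """Non-learned reference rankings.

    ``random``: a seeded permutation of all nodes. ``prior_list``: the
    prior genes occupy the top ranks in their given order and all other
    nodes follow in seeded random order (cancer genes / drug targets /
    perturbed-genes baselines are all instances with different priors).
    """
    if kind not in ("random", "prior_list"):
        raise ValidationError(f"unknown baseline kind {kind!r}")
    rng = rng_for(seed, "baseline", kind)
    if kind == "random" or not prior:
        order = rng.permutation(n)
    else:
        prior = [int(p) for p in prior]
        if len(set(prior)) != len(prior):
            raise ValidationError("duplicate genes in prior list")
        if any(p < 0 or p >= n for p in prior):
            raise ValidationError("prior gene index out of range")
        rest = np.setdiff1d(np.arange(n), prior)
        order = np.concatenate([np.asarray(prior, int), rng.permutation(rest)])
    scores = np.empty(n)
    scores[order] = np.arange(n, 0, -1)
    return PerturbagenRanking(scores=scores, order=order, tie_rule="baseline")


def indirect_rank(r2_per_perturbagen: Mapping[str, float],
                  drug_targets: Mapping[str, Iterable[int]], n: int,
                  seed: int) -> PerturbagenRanking:
    """Gene ranking derived from a response-prediction method's per-drug
    R2 scores (the indirect-baseline wrapper).

    Drugs are sorted by descending R2 (ties broken lexicographically by
    drug id); each drug expands to its target genes in seeded random
    internal order, keeping first occurrences; genes absent from every
    ranked drug are appended in seeded shuffled order to complete the
    rank.
    """
    rng = rng_for(seed, "indirect-rank")
    drugs = sorted(r2_per_perturbagen, key=lambda d: (-r2_per_perturbagen[d], d))
    order: list[int] = []
    seen: set[int] = set()
    for d in drugs:
        targets = [int(t) for t in drug_targets.get(d, ())]
        rng.shuffle(targets)
        for t in targets:
            if t not in seen:
                seen.add(t)
                order.append(t)
    missing = np.setdiff1d(np.arange(n), list(seen))
    order = np.concatenate([np.asarray(order, int), rng.permutation(missing)]) \
        if len(missing) else np.asarray(order, int)
    scores = np.empty(n)
    scores[order] = np.arange(n, 0, -1)
    return PerturbagenRanking(scores=scores, order=order, tie_rule="indirect")


# ---------------------------------------------------------------------------
# Reports and aggregation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MetricsReport:
    """Per-evaluation-run summary. Recall cutoffs above n are evaluated at
    n (every gene), where recall is 1 by construction."""

    ndcg: float
    recall_at_1: float
    recall_at_10: float
    recall_at_100: float
    pct_accurately_predicted: float
    samplewise_r2: float = float("nan")
    perturbagenwise_r2: float = float("nan")

    def aggregated_score(self) -> float:
        """Mean of the available (non-NaN) metric values, with the
        percentage rescaled to [0, 1]."""
        vals = [self.ndcg, self.recall_at_1, self.recall_at_10,
                self.recall_at_100, self.pct_accurately_predicted / 100.0,
                self.samplewise_r2, self.perturbagenwise_r2]
        vals = [v for v in vals if not math.isnan(v)]
        return float(np.mean(vals))


def summarize_rankings(
    rankings: Sequence[PerturbagenRanking | np.ndarray],
    truths: Sequence[Iterable[int]],
    n: int,
    samplewise: Sequence[float] = (),
    perturbagenwise: Sequence[float] = (),
) -> MetricsReport:
    """Average the ranking metrics over a test set."""
    if len(rankings) != len(truths):
        raise ValidationError("rankings and truths must align")
    nd, r1, r10, r100 = [], [], [], []
    for r, t in zip(rankings, truths):
        nd.append(ndcg(r, t, n))
        r1.append(recall_at_k(r, t, 1))
        r10.append(recall_at_k(r, t, min(10, n)))
        r100.append(recall_at_k(r, t, min(100, n)))
    return MetricsReport(
        ndcg=float(np.mean(nd)),
        recall_at_1=float(np.mean(r1)),
        recall_at_10=float(np.mean(r10)),
        recall_at_100=float(np.mean(r100)),
        pct_accurately_predicted=pct_accurately_predicted(rankings, truths),
        samplewise_r2=float(np.mean(samplewise)) if len(samplewise) else float("nan"),
        perturbagenwise_r2=float(np.mean(perturbagenwise)) if len(perturbagenwise)
        else float("nan"),
    )


def aggregate_and_test(
    per_method: Mapping[str, Mapping[str, Sequence[float]]],
    focal: str,
    alternative: str = "greater",
) -> tuple[dict[str, float], dict[str, float]]:
    """Aggregate per-fold metric values and test the focal method.

    ``per_method[method][metric]`` is a sequence of per-fold values, folds
    aligned across methods. Returns (aggregated mean per method, p-value
    of a paired t-test of focal vs each competitor). ``alternative``
    "greater" gives the one-tailed benchmark test; "two-sided" the
    ablation variant.
    """
    if focal not in per_method:
        raise ValidationError(f"unknown focal method {focal!r}")
    fold_counts = {
        len(vals) for metrics in per_method.values() for vals in metrics.values()
    }
    if len(fold_counts) != 1:
        raise ValidationError("misaligned folds across methods/metrics")
    per_fold: dict[str, np.ndarray] = {}
    for method, metrics in per_method.items():
        mat = np.array([list(v) for v in metrics.values()], float)
        per_fold[method] = mat.mean(axis=0)  # aggregated metric per fold
    aggregated = {m: float(v.mean()) for m, v in per_fold.items()}
    pvals: dict[str, float] = {}
    for method in per_method:
        if method == focal:
            continue
        diffs = per_fold[focal] - per_fold[method]
        if np.ptp(diffs) == 0:
            # zero-variance differences: the t statistic is undefined, so
            # report the limiting convention (no evidence -> 1, constant
            # advantage in the tested direction -> 0)
            mean = float(diffs.mean())
            if alternative == "greater":
                pvals[method] = 0.0 if mean > 0 else 1.0
            elif alternative == "less":
                pvals[method] = 0.0 if mean < 0 else 1.0
            else:
                pvals[method] = 1.0 if mean == 0 else 0.0
            continue
        res = stats.ttest_rel(per_fold[focal], per_fold[method],
                              alternative=alternative)
        pvals[method] = float(res.pvalue)
    return aggregated, pvals
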