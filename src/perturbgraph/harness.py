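"""End-to-end study harness: simulate, train, evaluate, compare.

Builds the desk-scale study the package validates itself on: an SCM over
60 genes, a 20-perturbagen library of 1-3-gene target sets, 40 paired
samples per perturbagen, 5-fold cross-validation with a {1, 2} layer grid.
Provides three entry points — the supercycle target-recovery run, the
objective-function ablation (super / cycle / supercycle), and the
latent-confounder robustness sweep — each returning plain dictionaries of
per-fold metrics plus Monte-Carlo random-baseline references. All
randomness derives from one root seed.

Model width (d=8) and the fixed epoch budget (minibatch 128, Adam lr
2e-3, at most 80 epochs under patience-15 early stopping) are the
package's desk-scale defaults for this study; both are ordinary
TrainConfig fields for anyone who wants to run larger.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from ._seeds import derive_seed, rng_for
from .evaluation import (baseline_rank, ndcg, pct_accurately_predicted,
                         samplewise_r2, summarize_rankings)
from .graphs import InterventionSet, ProxyCausalGraph, mutilate
from .model import PerturbagenModel, ResponseModel, aggregation_matrix
from .synthdata import (ConfounderSpec, InterventionTriplet,
                        generate_treatment_dataset, inject_confounders,
                        sample_scm)
from .training import (FoldSplit, SampleSplit, TrainConfig, grid_search_K,
                       make_random_splits, train)

#: Study conditions of the desk-scale validation experiment.
N_NODES = 60
ARC_DENSITY = 0.07
N_DISEASE_GENES = 3
N_PERTURBAGENS = 20
PERTURBAGEN_SIZES = (1, 3)  # inclusive range
SAMPLES_PER_PERTURBAGEN = 40
NOISE_SD = 0.05
N_FOLDS = 5
RANDOM_BASELINE_DRAWS = 200

DEFAULT_TRAIN = TrainConfig(
    loss_mode="supercycle", max_epochs=80, patience=15, min_delta=1e-5,
    learning_rate=2e-3, batch_size=128, K_grid=(1, 2), d=8, B=5,
    use_disease_data=False,
)


@dataclass
class Scenario:
    """One simulated study: graph, ground truth, and the treatment data."""

    scm: object
    graph: ProxyCausalGraph
    disease_genes: InterventionSet
    library: list[InterventionSet]
    dataset: list[InterventionTriplet]
    node_index: dict[str, int]
    seed: int


def build_scenario(seed: int, dataset: Optional[Sequence[InterventionTriplet]] = None
                   ) -> Scenario:
    """Simulate the study conditions from one root seed."""
    scm = sample_scm(N_NODES, ARC_DENSITY, seed=derive_seed(seed, "scm"),
                     noise_sd=NOISE_SD)
    nodes = list(scm.graph.node_ids)
    rng = rng_for(seed, "scenario")
    disease = InterventionSet(
        frozenset(rng.choice(nodes, N_DISEASE_GENES, replace=False)), "disease")
    library = []
    for _ in range(N_PERTURBAGENS):
        k = int(rng.integers(PERTURBAGEN_SIZES[0], PERTURBAGEN_SIZES[1] + 1))
        library.append(InterventionSet(frozenset(rng.choice(nodes, k, replace=False))))
    if dataset is None:
        dataset = generate_treatment_dataset(
            scm, library, SAMPLES_PER_PERTURBAGEN,
            seed=derive_seed(seed, "treatment"), disease_genes=disease)
    return Scenario(scm=scm, graph=scm.graph, disease_genes=disease,
                    library=library, dataset=list(dataset),
                    node_index={n: i for i, n in enumerate(nodes)}, seed=seed)


# ---------------------------------------------------------------------------
# Evaluation helpers
# ---------------------------------------------------------------------------


def _truths(sc: Scenario, samples: Sequence[InterventionTriplet]) -> list[set[int]]:
    return [{sc.node_index[m] for m in t.u.members} for t in samples]


def evaluate_fold(sc: Scenario, fr: ResponseModel, fp: PerturbagenModel,
                  test: Sequence[InterventionTriplet]) -> dict:
    """Test-fold metrics: ranking quality of f_p plus reconstruction R2 of
    f_r driven by f_p's top-N predictions (hard flags, mutilated graph)."""
    n = sc.graph.n_nodes
    A = aggregation_matrix(sc.graph, fp.aggregator)
    Xd = np.stack([t.x_initial for t in test])
    Xt = np.stack([t.x_outcome for t in test])
    truths = _truths(sc, test)
    rankings = fp.forward(A, Xd, Xt)
    r2 = []
    mut_cache: dict[tuple, np.ndarray] = {}
    for i, (r, t) in enumerate(zip(rankings, truths)):
        top = tuple(sorted(int(j) for j in r.top(len(t))))
        if top not in mut_cache:
            genes = {sc.graph.node_ids[j] for j in top}
            mut_cache[top] = aggregation_matrix(mutilate(sc.graph, genes),
                                                fr.aggregator)
        flags = np.zeros(n)
        flags[list(top)] = 1.0
        pred = fr.forward(mut_cache[top], Xd[i:i + 1], flags[None])[0]
        r2.append(samplewise_r2(np.asarray(pred, float), Xt[i]))
    report = summarize_rankings(rankings, truths, n, samplewise=[
        v for v in r2 if not np.isnan(v)])
    return {
        "ndcg": report.ndcg,
        "recall_at_1": report.recall_at_1,
        "recall_at_10": report.recall_at_10,
        "pct_accurately_predicted": report.pct_accurately_predicted,
        "reconstruction_r2": float(np.nanmean(r2)),
    }


def random_baseline_mc(sc: Scenario, samples: Sequence[InterventionTriplet],
                       seed: int, n_draws: int = RANDOM_BASELINE_DRAWS) -> dict:
    """Monte-Carlo distribution of the random baseline on a sample set:
    per-draw pct-accurately-predicted and nDCG over fresh random ranks."""
    n = sc.graph.n_nodes
    truths = _truths(sc, samples)
    pcts, ndcgs = [], []
    for d in range(n_draws):
        ranks = [baseline_rank("random", None, n, seed=derive_seed(seed, "rb", d, i))
                 for i in range(len(samples))]
        pcts.append(pct_accurately_predicted(ranks, truths))
        ndcgs.append(float(np.mean([ndcg(r, t, n) for r, t in zip(ranks, truths)])))
    return {
        "pct_mean": float(np.mean(pcts)), "pct_sd": float(np.std(pcts, ddof=1)),
        "ndcg_mean": float(np.mean(ndcgs)), "ndcg_sd": float(np.std(ndcgs, ddof=1)),
        "n_draws": n_draws,
    }


# ---------------------------------------------------------------------------
# Experiment entry points
# ---------------------------------------------------------------------------


def run_target_recovery(seed: int, cfg: TrainConfig = DEFAULT_TRAIN,
                        sc: Optional[Scenario] = None,
                        split: Optional[SampleSplit] = None) -> dict:
    """Supercycle training with per-fold layer-grid selection.

    Returns per-fold metrics, per-fold selected K, the trained models, and
    the random baseline's Monte-Carlo reference on the full dataset.
    """
    sc = sc or build_scenario(seed)
    split = split or make_random_splits(len(sc.dataset), N_FOLDS,
                                        seed=derive_seed(seed, "split"))
    folds = []
    for k, fold in enumerate(split.folds):
        fold_cfg = replace(cfg, loss_mode="supercycle",
                           seed=derive_seed(seed, "fit", k))
        best_K, fr, fp, _ = grid_search_K(sc.dataset, sc.graph, fold_cfg, fold)
        test = [sc.dataset[i] for i in fold.test_idx]
        metrics = evaluate_fold(sc, fr, fp, test)
        folds.append({"fold": k, "best_K": best_K, "metrics": metrics,
                      "models": (fr, fp)})
    baseline = random_baseline_mc(sc, sc.dataset, seed=derive_seed(seed, "mc"))
    return {"scenario": sc, "split": split, "folds": folds,
            "random_baseline": baseline,
            "mean_pct": float(np.mean(
                [f["metrics"]["pct_accurately_predicted"] for f in folds])),
            "mean_ndcg": float(np.mean([f["metrics"]["ndcg"] for f in folds]))}


def run_ablation(seed: int, recovery: Optional[dict] = None,
                 cfg: TrainConfig = DEFAULT_TRAIN) -> dict:
    """Objective-function ablation at each fold's supercycle-selected K.

    Reuses the supercycle run's models; trains super- and cycle-only
    discovery modules per fold. The supervision-only fit reuses the
    supercycle f_r (f_r updates are independent of the discovery loss, so
    retraining it would reproduce the same module); the cycle-only fit
    retrains f_r in parallel because its gradients pass through f_r's
    evolving parameters.
    """
    recovery = recovery or run_target_recovery(seed, cfg)
    sc: Scenario = recovery["scenario"]
    split: SampleSplit = recovery["split"]
    out = {"supercycle": [], "super": [], "cycle": []}
    for k, fold in enumerate(split.folds):
        rec_fold = recovery["folds"][k]
        best_K = rec_fold["best_K"]
        fr_sc, _ = rec_fold["models"]
        test = [sc.dataset[i] for i in fold.test_idx]
        out["supercycle"].append(rec_fold["metrics"])
        for mode in ("super", "cycle"):
            fold_cfg = replace(cfg, loss_mode=mode, K=best_K,
                               seed=derive_seed(seed, "fit", k))
            fr, fp, _ = train(sc.dataset, sc.graph, fold_cfg, fold,
                              pretrained_fr=fr_sc if mode == "super" else None)
            out[mode].append(evaluate_fold(sc, fr, fp, test))
    summary = {
        mode: {key: float(np.mean([m[key] for m in vals]))
               for key in vals[0]}
        for mode, vals in out.items()
    }
    return {"per_fold": out, "summary": summary, "scenario": sc}


def run_confounder_sweep(seed: int, recovery: Optional[dict] = None,
                         fractions: Sequence[float] = (0.2, 0.6, 1.0),
                         cfg: TrainConfig = DEFAULT_TRAIN) -> dict:
    """Latent-confounder robustness sweep.

    For each confounder fraction, corrupts the expression data (50 gene
    groups, group means uniform on [-0.5, 0.5], group SDs on [0.1, 0.5]),
    retrains supercycle at each fold's clean-data-selected K, and reports
    per-fold metrics plus the random baseline on the corrupted data.
    """
    recovery = recovery or run_target_recovery(seed, cfg)
    sc: Scenario = recovery["scenario"]
    split: SampleSplit = recovery["split"]
    rows = []
    for frac in fractions:
        spec = ConfounderSpec(fraction_perturbed=frac,
                              seed=derive_seed(seed, "confounder", frac))
        corrupted = inject_confounders(sc.dataset, spec)
        sc_c = Scenario(scm=sc.scm, graph=sc.graph,
                        disease_genes=sc.disease_genes, library=sc.library,
                        dataset=corrupted, node_index=sc.node_index, seed=seed)
        for k, fold in enumerate(split.folds):
            best_K = recovery["folds"][k]["best_K"]
            fold_cfg = replace(cfg, loss_mode="supercycle", K=best_K,
                               seed=derive_seed(seed, "fit", k))
            fr, fp, _ = train(corrupted, sc.graph, fold_cfg, fold)
            test = [corrupted[i] for i in fold.test_idx]
            metrics = evaluate_fold(sc_c, fr, fp, test)
            rows.append({"fraction": frac, "fold": k, **metrics})
        mc = random_baseline_mc(sc_c, corrupted, seed=derive_seed(seed, "mc", frac))
        rows.append({"fraction": frac, "fold": "random_baseline",
                     "pct_accurately_predicted": mc["pct_mean"],
                     "ndcg": mc["ndcg_mean"]})
    return {"rows": rows, "fractions": list(fractions)}
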