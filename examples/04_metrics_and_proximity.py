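"""The evaluation stack on worked toy inputs.

Walks through the ranking metrics (nDCG with gain 1 - rank/n, recall@k,
percent accurately predicted), the two R2 variants for response
prediction, and the network-proximity comparison with its one-sided
Mann-Whitney test and rank-biserial effect size. Numbers are small enough
to verify by hand.
"""

import numpy as np

from perturbgraph import (baseline_rank, indirect_rank, ndcg,
                          pct_accurately_predicted, proximity,
                          proximity_test, recall_at_k, samplewise_r2)
from perturbgraph.graphs import ProxyCausalGraph

# a ranking over 5 genes with one true target sitting at rank 3
order = np.array([0, 1, 4, 2, 3])
truth = {4}
print(f"single target at rank 3 of 5: nDCG = {ndcg(order, truth, 5):.2f} "
      "(gain (1-3/5)/log2(4) over ideal (1-1/5)/log2(2))")
print(f"recall@1 = {recall_at_k(order, truth, 1):.0f}, "
      f"recall@3 = {recall_at_k(order, truth, 3):.2f}")
print(f"pct accurately predicted over two samples = "
      f"{pct_accurately_predicted([order, order], [{0}, {4}]):.0f}%")

pred = np.array([0.1, 0.4, 0.35, 0.8, 0.95])
obs = np.array([0.2, 0.3, 0.5, 0.7, 0.9])
print(f"\nsample-wise R2 (squared Pearson) = {samplewise_r2(pred, obs):.3f}")

# proximity on a path graph a-b-c-d: predicted {a,b} vs true {d}
nodes = ("a", "b", "c", "d")
arcs = []
for x, y in zip(nodes, nodes[1:]):
    arcs += [(x, y), (y, x)]
g = ProxyCausalGraph(nodes, tuple(arcs), origin="undirected-doubled")
d = proximity(g, {"a", "b"}, {"d"})
print(f"\nproximity d({{a,b}}, {{d}}) on the path a-b-c-d = {d} "
      "(mean of 3 and 2 hops)")

rng = np.random.default_rng(0)
method = rng.choice([1.0, 2.0, 3.0], 60, p=[0.5, 0.3, 0.2])
random_ref = rng.choice([2.0, 3.0, 4.0], 60)
res = proximity_test(method, random_ref, n_boot=1000, seed=1)
print(f"method vs random distances: U = {res.u_statistic:.0f}, one-sided "
      f"p = {res.p_value:.2e}, rank-biserial r = {res.rank_biserial:.3f} "
      f"(95% CI [{res.ci_low:.3f}, {res.ci_high:.3f}])")
print("negative r: the method's predictions sit closer to the true targets "
      "than chance")

# the indirect wrapper turns per-drug response-R2 scores into a gene rank
r = indirect_rank({"drugA": 0.9, "drugB": 0.4}, {"drugA": {0, 1}, "drugB": {2}},
                  n=6, seed=2)
print(f"\nindirect baseline gene rank from drug R2 scores: {r.order.tolist()} "
      "(drugA's targets first, then drugB's, missing genes shuffled last)")
print(f"plain random baseline: "
      f"{baseline_rank('random', None, 6, seed=3).order.tolist()}")
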