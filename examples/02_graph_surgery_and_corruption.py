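"""Do-operator graph surgery and the network-corruption procedures.

Interventions delete the arcs *into* intervened genes (they stop
listening to their parents) while outgoing arcs keep propagating the
effect — the printed in/out degrees make that asymmetry visible. The
second half shows the robustness-study corruptions: bridge-edge removal,
random-edge removal, and confidence-quantile filtering.
"""

import numpy as np

from perturbgraph import (filter_by_confidence, find_bridges, mutilate,
                          remove_bridge_edges, remove_random_edges,
                          shortest_path_distance)
from perturbgraph.graphs import ProxyCausalGraph

rng = np.random.default_rng(0)
nodes = tuple(f"g{i}" for i in range(12))
arcs, conf = [], {}
for i in range(12):
    for j in range(i + 1, 12):
        if rng.random() < 0.2:
            c = float(rng.uniform(0.1, 1.0))
            arcs += [(nodes[i], nodes[j]), (nodes[j], nodes[i])]
            conf[(nodes[i], nodes[j])] = conf[(nodes[j], nodes[i])] = c
g = ProxyCausalGraph(nodes, tuple(arcs), confidences=conf,
                     origin="undirected-doubled")
print(f"graph: {g.n_nodes} genes, {len(g.undirected_edges())} undirected edges")

target = nodes[4]
gm = mutilate(g, {target})
print(f"\ndo({target}): in-degree {len(g.in_neighbors(target))} -> "
      f"{len(gm.in_neighbors(target))}; "
      f"arcs {g.n_arcs} -> {gm.n_arcs} (outgoing arcs kept)")

bridges = find_bridges(g)
print(f"\nbridges: {len(bridges)} edge(s) whose removal disconnects the graph")
g_b = remove_bridge_edges(g, fraction=1.0, seed=1)
g_r = remove_random_edges(g, fraction=0.3, seed=1)
print(f"after removing all bridges: {len(g_b.undirected_edges())} edges; "
      f"after removing 30% random edges: {len(g_r.undirected_edges())} edges")

g_f = filter_by_confidence(g, quantile=0.5)
print(f"confidence filter at the 0.5 quantile keeps "
      f"{len(g_f.undirected_edges())} of {len(g.undirected_edges())} edges")
print(f"shortest path {nodes[0]} to {nodes[11]}: "
      f"{shortest_path_distance(g, nodes[0], nodes[11])} hops")
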