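"""Threshold a connectivity matrix and compute the three network metrics.

Builds a 148-parcel (Destrieux) random-plus-structure PLV matrix, retains
the 20% strongest connections, and computes modularity, global efficiency
and the core-extended routing efficiency of the face-processing network.
"""

import numpy as np

from plvnet import (
    ConnectivityMatrix,
    global_efficiency,
    modularity,
    proportional_threshold,
    routing_efficiency,
    routing_matrix,
)
from plvnet.atlas import default_face_network, destrieux_labels

rng = np.random.default_rng(7)
labels = destrieux_labels()
n = len(labels)

# synthetic whole-brain PLV matrix: smooth baseline + node strength gradient
strength = rng.uniform(0.4, 1.0, n)
plv = 0.5 * np.outer(strength, strength) + rng.uniform(0, 0.05, (n, n))
plv = np.clip((plv + plv.T) / 2, 0, 1)
np.fill_diagonal(plv, 1.0)
conn = ConnectivityMatrix(plv=plv, node_labels=labels)

graph = proportional_threshold(conn, density=0.2)
print(f"nodes: {graph.n_nodes}, retained edges: {graph.n_edges} "
      f"({100 * graph.density:.1f}% of possible)")

part = modularity(graph, n_restarts=50, seed=1)
ge = global_efficiency(graph)
sets = default_face_network()
reff = routing_efficiency(routing_matrix(graph), sets)

print(f"modularity Q          = {part.q:.4f}")
print(f"global efficiency     = {ge:.4f}")
print(f"routing efficiency    = {reff:.4f} "
      f"(core {len(sets.core)} parcels <-> extended {len(sets.extended)} parcels)")
print(
    "Q near 0 marks weak community structure (this matrix has none "
    "planted); global efficiency is the mean inverse shortest path length "
    "(1 = fully integrated); routing efficiency is the best such inverse "
    "path length between the face network's core and extended systems."
)
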