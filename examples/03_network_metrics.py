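"""Clustering coefficient and global efficiency of binary networks.

Coef = (1/M) sum_i 2 E_i / (k_i (k_i - 1)) with E_i the edges among node
i's neighbours; Eff = (1/M) sum_i [sum_j 1/d_ij] / (M - 1).  Both lie in
[0, 1] and attain the endpoints on the complete and star graphs.
"""

import itertools

import numpy as np

from hippoconn import BinaryNetwork, clustering_coefficient, global_efficiency


def net(m, edges):
    a = np.zeros((m, m), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return BinaryNetwork(adjacency=a)


examples = {
    "complete (16 nodes)": net(16, itertools.combinations(range(16), 2)),
    "star (hub + 15 leaves)": net(16, [(0, i) for i in range(1, 16)]),
    "triangle + pendant": net(4, [(0, 1), (0, 2), (1, 2), (0, 3)]),
    "3-node path": net(3, [(0, 1), (1, 2)]),
}
for name, network in examples.items():
    print(
        f"{name:<24} Coef = {clustering_coefficient(network):.4f}   "
        f"Eff = {global_efficiency(network):.4f}"
    )
# complete: both 1 (every pair adjacent); star: Coef 0 (triangle-free);
# triangle+pendant: Coef = 7/12; path: Eff = 5/6.
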