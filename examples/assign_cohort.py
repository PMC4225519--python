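"""Assign a simulated low-coverage cohort to fine-level haplogroups.

Builds a 20-leaf haplogroup tree with 3 markers per branch, simulates 40
haploid samples at 1.5x mean depth, and computes each sample's posterior
over the 20 leaf haplogroups (no EM pooling here; see em_pooling.py).
"""

import numpy as np

from yhap import (
    HaplogroupPrior,
    SimulationSpec,
    assign_cohort,
    augment,
    build_marker_matrix,
    restrict_nodes,
    simulate_dataset,
)

data = simulate_dataset(SimulationSpec(seed=1))
H = build_marker_matrix(data.tree, data.markers)
h_star, g = augment(H, data.likelihoods)
active = restrict_nodes(data.tree, "leaves")
results = assign_cohort(g, h_star, HaplogroupPrior.uniform(active), active)

print(f"{len(results)} samples, {g.n_sites} sites ({h_star.marker_rows.size} markers)")
print(f"{'sample':8s} {'truth':8s} {'MAP call':8s} {'P(MAP)':>8s}")
for r, truth in list(zip(results, data.truth.true_leaf))[:8]:
    print(f"{r.sample_id:8s} {truth:8s} {r.map_call:8s} {r.map_prob:8.4f}")

acc = np.mean([r.map_call == t for r, t in zip(results, data.truth.true_leaf)])
print(f"...\nMAP accuracy over the cohort: {acc:.3f}")
print("P(MAP) is the posterior probability of the called haplogroup; at 1.5x")
print("depth the known markers alone already identify most samples.")
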