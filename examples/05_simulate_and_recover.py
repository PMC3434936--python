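"""Simulate data on a known tree, then recover what generated it.

A parameter/topology-recovery loop: characters evolve under Mk with
gamma rate heterogeneity on a fixed 8-area tree, and the inference side
must find the topology and the shape parameter back.
"""

from paeml import (
    AreaTree, SearchConfig, SimulationConfig, fit, rf_distance, search,
    simulate_matrix,
)

truth = AreaTree.from_newick(
    "((((A:.15,B:.2):.1,(C:.25,D:.1):.15):.1,(E:.2,F:.15):.2):.1,"
    "(G:.3,H:.1):.15);"
)
sim = simulate_matrix(SimulationConfig(
    tree=truth, n_characters=2000, gamma_shape=0.5, seed=3,
))
print(f"simulated {sim.matrix.n_species} characters; "
      f"true per-branch change counts retained "
      f"(total {sim.branch_changes.sum()} changes)")

res = search(sim.matrix, SearchConfig(objective="likelihood", gamma=True,
                                      n_starts=1, swap="nni", seed=3))
print(f"recovered topology RF to truth: {rf_distance(res.trees[0], truth)}")
print(f"recovered gamma shape: {res.fit.gamma_shape:.3f} (simulated 0.5)")
# RF 0 and a shape estimate near 0.5 mean both the area relationships and
# the rate-heterogeneity signal are identifiable at this data size.
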