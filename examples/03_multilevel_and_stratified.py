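"""Multiple organizational levels and behavior-specific thresholds.

Part 1 simulates nested structure — tight subgroups (1 m member spread)
inside loose groups (60 m spread of subgroup centers) inside well-separated
supergroups — and shows that the pooled directional NN distance
distribution carries one cutoff per level boundary (subgroup vs group vs
supergroup).

Part 2 simulates a survey whose groups are either resting (1 m spread) or
foraging (25 m spread) with the same between-group spacing, stratifies the
distances by the source individual's behavioral state, and shows the
per-state thresholds come out ordered: resting groups warrant a tighter
chain rule than foraging ones.
"""

import numpy as np

from groupdelim import (
    SimulationConfig,
    SupergroupSpec,
    directional_nn_distances,
    estimate_thresholds,
    pool_distances,
    simulate_scene,
    stratified_thresholds,
)

# --- Part 1: nested scales -> multiple cutoffs ---
nested = SimulationConfig(
    window=(0, 0, 5000, 5000),
    n_groups=9,
    group_size_dist=("fixed", 6),
    spread_by_state={"rest": 1.0},
    state_probs={"rest": 1.0},
    supergroup=SupergroupSpec(n_supergroups=3, inter_group_sigma=60.0),
    min_center_separation=1500.0,
)
rng = np.random.default_rng(2)
recs = [
    directional_nn_distances(
        simulate_scene(nested, seed=int(rng.integers(0, 2**31 - 1))).scene
    )
    for _ in range(5)
]
est = estimate_thresholds(pool_distances(recs))
print("nested simulation:")
for name, cut in zip(est.level_names, est.cutoffs):
    print(f"  {name:10s} threshold: {cut:8.1f} m")

# --- Part 2: behavior-stratified thresholds ---
mixed = SimulationConfig(
    window=(0, 0, 2000, 2000),
    n_groups=6,
    group_size_dist=("fixed", 6),
    spread_by_state={"rest": 1.0, "forage": 25.0},
    state_probs={"rest": 0.5, "forage": 0.5},
    min_center_separation=300.0,
)
recs = [
    directional_nn_distances(
        simulate_scene(mixed, seed=int(rng.integers(0, 2**31 - 1))).scene
    )
    for _ in range(8)
]
strat = stratified_thresholds(pool_distances(recs, stratify_by_state=True))
print("\nbehavior-stratified thresholds:")
for state, sub in sorted(strat.per_stratum.items()):
    print(f"  {state:8s}: {sub.primary_cutoff:6.1f} m  (n = {sub.n})")
print("a tighter state (rest) earns a tighter chain-rule distance")
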