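"""Why one fixed chain-rule distance cannot fit all behaviors.

Builds the two canonical cohesion scenes — five resting animals about 1 m
apart with a sixth 20 m away, and five foraging animals about 25 m apart
with a sixth 20 m from the closest — and delimits both with a 10 m and a
50 m chain rule. Neither threshold gets both scenes right: the 10 m rule
correctly isolates the resting outsider but shatters the foraging group,
while the 50 m rule keeps the foraging group whole but absorbs the resting
outsider.
"""

from groupdelim import chain_rule_partition, classify_units, simulate_paired_cohesion_scenes

rest, forage = simulate_paired_cohesion_scenes()

for threshold in (10.0, 50.0):
    print(f"\nchain rule at {threshold:g} m")
    for sim in (rest, forage):
        part = chain_rule_partition(sim.scene, threshold)
        summary = classify_units(part)
        print(
            f"  {sim.scene.scene_id:16s}: {summary.n_groups} group(s) "
            f"{list(summary.group_sizes)}, {summary.n_singletons} singleton(s)"
        )
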