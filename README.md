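# groupdelim

Operational delimitation of animal **groups** from instantaneous positional
snapshots, and data-driven estimation of the threshold distances those
delimitations should use.

Field studies of social animals — the motivating case is delphinid boat and
aerial surveys — treat the *group* as their basic sampling unit, yet define
it with ad-hoc spatial rules ("within 10 m of any other member", "within
100 m of the boat") whose distances rarely have a biological justification.
`groupdelim` implements both halves of a principled alternative:

1. **Delimitation rules.** Given a *scene* (one snapshot: individuals with
   planar coordinates and optional behavioral states), partition it with
   the rules in field use:
   - **chain rule** at threshold *d*: connected components of the graph
     joining every pair with distance ≤ *d* (single-linkage clustering);
   - **focal-individual rule**: everyone within radius *d* of a focal
     animal, no chaining;
   - **fixed-point rule**: everyone within radius *d* of a location (e.g.
     the research vessel);
   - **adaptive chain rule**: a chain rule with a different threshold per
     behavioral state (tight when resting, loose when foraging).

   Components are classified into the standard unit taxonomy: *singleton*
   (1 individual), *group* (≥ 2), *sighting* (all units in the scene).

2. **Threshold estimation.** Measure, for each individual, the distance to
   its nearest neighbor lying strictly further along a constant compass
   bearing (north by convention). Pool these directional
   nearest-neighbor distances over many scenes, estimate their density
   f(d) with a Gaussian kernel (by default on log-distance, bandwidth by
   Silverman's rule), and take as cutoffs the prominent **antimodes** of
   the curve — interior minima where the numerical gradient df/dd changes
   sign from − to +, separating the within-group spacing mode from the
   between-group mode. Nested organization yields multiple cutoffs
   (subgroup / group / supergroup); stratifying by behavioral state yields
   one threshold per state. The estimated cutoff is then applied in the
   field as a chain rule.

A hierarchical scene simulator (Thomas-process-style Gaussian clusters with
behavior-dependent spread, optional supergroup nesting, observer detection
truncation) provides ground truth for validating the whole chain, and an
evaluation module scores threshold recovery with the adjusted Rand index.

## Worked example

`examples/02_estimate_threshold_from_survey.py` simulates ten survey
snapshots (5 groups of 6 animals, 2 m within-group spread, group centers
≥ 200 m apart), runs the full process, and delimits every scene with the
estimated threshold:

```
pooled directional NN distances: n = 290
modes (m):   [2.1, 322.1]
cutoffs (m): [41.1]
chain rule at 41.1 m: median truth agreement (ARI) = 1.000
```

The density of pooled distances is bimodal: a within-group mode at ~2 m and
a between-group mode at ~322 m. The single antimode at 41.1 m is the
data-derived chain-rule threshold, and delimiting with it reproduces the
generating partition exactly (adjusted Rand index 1.0).

The other examples show why no single fixed distance works across
behaviors (`01`), multi-level and behavior-stratified thresholds (`03`),
and how strongly rule choice alters measured sociality (`04`). Each is a
short script that prints what it computes.

## Command line

A thin CLI wraps the same functions:

```sh
groupdelim simulate --out survey/ --seed 1 --n-scenes 10
groupdelim nnd survey/scenes.csv --out nn.csv
groupdelim estimate-threshold nn.csv --out threshold.json --by-state
groupdelim delimit survey/scenes.csv --out units/ --rule chain --threshold-m 41
groupdelim pipeline --out run/ --seed 1 --fallback 10m-chain
```

Every pipeline run writes a machine-readable *definition statement*
(rule kind, threshold(s), provenance, seed, analysis settings) so the group
definition actually applied is always explicit. When no distance data are
available the pipeline falls back to a declared standard rule (10 m or
100 m chain).

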