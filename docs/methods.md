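# Methods

## The problem and the model

An instantaneous field observation (a *scene*) records a set of individuals
with planar coordinates in metres, optionally a behavioral state and a body
length each. Group delimitation is a partition of a scene. All rules here
are functions of interindividual Euclidean distance only: behavioral state
enters exclusively through its effect on the distance threshold, and
movement direction or shared activity are deliberately not membership
criteria — they are subjective in the field and a spatially cohesive
cluster can contain animals in different states.

Threshold comparisons are inclusive (distance ≤ d joins two individuals).
The chain rule at threshold d is exactly single-linkage clustering cut at
d: the connected components of the proximity graph. This makes two useful
properties automatic: the partition is invariant to which individual the
chain "starts" from, and partitions are nested in d (smaller thresholds
refine larger ones). In the adaptive chain rule the edge (i, j) uses the
shared state's threshold when states match and the **maximum** of the two
thresholds otherwise: the grouping-conservative choice, which never splits
a mixed-behavior cluster that either state's own threshold would have
joined. Component labels are assigned in ascending order of each
component's minimum member identifier, so output is reproducible
regardless of input ordering.

Units follow the singleton / group / sighting taxonomy: a group requires
at least two members; singletons are counted separately rather than
discarded, because lone individuals matter in ecological analyses.

## Directional nearest-neighbor distances

For threshold estimation, each individual contributes the Euclidean
distance to the nearest other individual lying strictly *further along a
constant bearing* (north by default). Unlike plain nearest-neighbor
distances, this measurement does not saturate at the within-group scale:
the along-bearing-last member of each group must reach across to the next
group, so the pooled distribution contains both the within-group and the
between-group spacing — exactly the two scales the threshold must
separate.

"Strictly further along the bearing" is made a strict total order —
greater along-bearing coordinate, ties broken by greater perpendicular
coordinate, then identifier — so generic scenes yield exactly n − 1
records, no individual is its own neighbor, and results are deterministic
under coordinate ties. The recorded distance is the full Euclidean
distance to that neighbor, not its along-bearing component. With
body-length normalization the distance is divided by the mean of the
pair's body lengths.

Geographic input (longitude/latitude) is projected to a local tangent
plane by equirectangular projection about a reference point on a spherical
Earth (R = 6371 km); scenes span at most a few kilometres, where the
first-order distance error is negligible. Ellipsoidal geodesics and
3-D (depth-aware) distances are out of scope.

## Density estimation and cutoff detection

Pooled distances are strictly positive and right-skewed, and grouping
scales are often separated by orders of magnitude, so the default analysis
scale is **logarithmic**; linear scale is available by flag and all
reported modes and cutoffs are back-transformed to metres. Density is a
Gaussian kernel sum on an even 512-point grid spanning the data ± 3
bandwidths, with bandwidth by Silverman's rule
h = 0.9 min(sd, IQR/1.34) n^(−1/5) on the analysis scale (a fixed
bandwidth and Scott's rule are also accepted; whatever is used is recorded
in the output). On the linear scale the grid is clipped at zero and the
curve renormalized. Samples under 30 distances are processed but flagged
unreliable. Zero distances are rejected as a data error (coincident
surfacing positions).

Cutoffs are the **antimodes** of the curve: grid points where the
numerical gradient changes sign from negative to positive. Three filters
make this robust:

* **Mode mass.** A mode whose basin (density mass between its adjacent
  valleys) holds under 2% of the sample is discarded and its valleys
  merged. Isolated tail bumps carrying a handful of observations are
  sampling noise, not spacing modes, yet the valley beside such a bump
  would otherwise score near-unit relative prominence.
* **Relative prominence.** A valley is kept only if
  (min flanking-mode height − valley height) / min flanking-mode height
  ≥ `min_prominence` (default 0.10). Failing valleys are merged away,
  shallowest first, so retained cutoffs always strictly interleave
  retained modes.
* **Level cap.** At most `max_levels` (default 3) cutoffs are kept, ranked
  by **absolute depth** (density drop from the lower flanking mode to the
  valley). Depth rather than relative prominence is used for ranking —
  and for `ThresholdEstimate.primary_cutoff`, the single threshold to use
  when one is needed — because relative prominence saturates near 1 for
  valleys beside small modes and therefore cannot discriminate a dominant
  valley from a minor one.

A unimodal curve returns an empty cutoff list: "no natural cutoff" is a
valid, explicitly reported outcome, not an error. Ascending cutoffs are
given the conventional nested-unit names subgroup / group / supergroup;
this is labelling only, with no analytic content.

Stratified estimation runs the same procedure per behavioral state
(strata under 30 distances are skipped and listed) and on the pooled
sample, reporting both. A nonparametric bootstrap (resampling distances,
matching replicate cutoffs to the original by nearest distance) provides
percentile stability intervals and the distribution of cutoff counts
across replicates.

## The scene simulator

Scenes are generated as a Thomas-style cluster process: group centers
uniform in a rectangular window subject to a minimum separation (rejection
sampling with bounded retries), each group drawing a size (zero-truncated
Poisson, or fixed) and a behavioral state, members placed as isotropic
Gaussian offsets with state-dependent σ. Defaults encode the canonical
contrast between behaviors: σ(rest) = 1 m and σ(forage) = 25 m, matching
nearest-neighbor spacings of about 1 m in tight resting groups and about
25 m in dispersed foraging groups; states are assigned per group (a
group's behavior is then well-defined in the truth labels), equiprobable
by default. With supergroups enabled, group centers are Gaussian offsets
around supergroup centers and the minimum separation applies at the
supergroup level. Members may fall outside the window — clipping would
bias nearest-neighbor distances — and the window is recorded for
border-aware analyses. Detection is modelled only as observer-centered
range truncation.

The deterministic paired cohesion scenes are fixed collinear constants:
five resting animals at x = 0…4 m with a sixth at 24 m, and five foraging
animals at x = 0, 25, …, 100 m with a sixth at 120 m. They instantiate the
scenario in which a 10 m chain rule handles the resting scene correctly
but shatters the foraging scene, while 50 m does the reverse — the core
argument for data-driven, behavior-aware thresholds.

What the simulator does **not** emulate: movement and surfacing asynchrony
(scenes are true instantaneous snapshots), per-individual behavioral
mixtures within a group, attraction/repulsion interactions, observer
position error, and fission–fusion dynamics over time. Passing tests
therefore demonstrate that the estimation machinery recovers known
structure from idealized snapshots, not that any particular field protocol
is unbiased.

## Evaluation

Partition agreement is the adjusted Rand index (chance-corrected
pair-counting; 1 iff identical, ≈ 0 at random). The recovery experiment
simulates scenes, estimates a threshold from their pooled directional NN
distances, delimits every scene with the estimated cutoff as a chain rule,
and scores against the generating truth; a replicate with no detected
cutoff counts against the detection rate and scores zero agreement.

The reference ("oracle") cutoff for a configuration is the antimode, found
by dense numerical scan, of an approximate analytic mixture: within-group
directional NN distances as the minimum of K iid Rayleigh(√2 σ) draws
(K the expected number of along-bearing-further groupmates, giving
Rayleigh(√2 σ/√K)), and between-group distances as the half-plane nearest
neighbor of a Poisson process of group centers, Rayleigh(1/√(π λ)),
weighted by the expected fraction of group-boundary records (1 / mean group
size). This captures the two spacing scales and their valley; it ignores
the minimum-separation constraint and window edge effects, so it is a
scale reference rather than an exact distribution, and is used only as an
independent check that recovered cutoffs sit between the within-group mode
and the center spacing.

## Problem sizes and numerical conventions

Default experiment sizes — e.g. 10 scenes of ~30 individuals per
replicate, 5,000-draw mixture samples, 50-replicate experiments, 200-scene
oracle sweeps — were chosen so the whole validation suite runs in well
under a minute while leaving the stochastic checks with wide margins; all
are parameters, not constants. Seeds are explicit arguments everywhere;
there is no hidden global random state, and identical configuration + seed
reproduces results bit-for-bit (artifact files included). Internally all
coordinates and thresholds are metres; identifiers are opaque strings;
outputs are sorted by (scene_id, individual_id).

## Known limitations

* The antimode of a kernel density is bandwidth-dependent; with strongly
  unbalanced mixture weights or heavy overlap the detected cutoff can
  shift materially from any population-level valley. The bootstrap
  interval is the diagnostic for this.
* Formal mixture modelling with model selection would be a statistically
  sharper alternative to density-gradient reading; it is intentionally not
  the default here, which follows the gradient-of-the-density-curve
  procedure, but the estimation surface would admit it.
* The focal and fixed-point rules return member sets, not partitions; for
  cross-rule comparison the remainder of the scene is treated as
  singletons, which is a convention, not an observation.
* In-situ threshold selection based on a tracked focal individual's
  nearest-neighbor distance is described in the literature only vaguely
  and is not implemented.
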