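"""Operational group-delimitation rules for positional snapshots.

Implements the field rules in common use for delphinid (and other
social-mammal) surveys:

* **chain rule** — individuals within a threshold distance of *any* current
  member belong to the group; equivalently, connected components of the
  proximity graph at that threshold (single-linkage clustering).
* **focal individual rule** — everyone within a radius of one designated
  focal animal, without chaining.
* **fixed-point rule** — everyone within a radius of a fixed location, e.g.
  the research vessel.
* **adaptive chain rule** — a chain rule whose threshold depends on
  behavioral state, reflecting that cohesion varies with behavior (tight
  resting groups, dispersed foraging groups).

Resulting units follow the singleton / group / sighting taxonomy: a
component of one individual is a *singleton*, two or more a *group*, and
the whole scene's collection of units a *sighting*. Behavior enters only
through per-state thresholds; directionality and shared-activity criteria
are deliberately not membership predicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .geometry import Scene, pairwise_distances

SINGLETON = "singleton"
GROUP = "group"


@dataclass(frozen=True)
class RuleSpec:
    """Declarative description of a delimitation rule, for batch comparison
    and serialization."""

    rule_kind: str  # chain | focal | fixed_point | adaptive_chain
    threshold: Optional[float] = None
    thresholds_by_state: Optional[dict[str, float]] = None
    default_threshold: Optional[float] = None
    focal_id: Optional[str] = None
    point: Optional[tuple[float, float]] = None
    name: Optional[str] = None

    def __post_init__(self) -> None:
        kinds = {"chain", "focal", "fixed_point", "adaptive_chain"}
        if self.rule_kind not in kinds:
            raise ValueError(f"rule_kind must be one of {sorted(kinds)}")
        if self.rule_kind in {"chain", "focal", "fixed_point"}:
            if self.threshold is None or self.threshold < 0:
                raise ValueError(f"{self.rule_kind} rule requires threshold >= 0")
        if self.rule_kind == "adaptive_chain" and not self.thresholds_by_state:
            raise ValueError("adaptive_chain requires thresholds_by_state")

    @property
    def label(self) -> str:
        if self.name:
            return self.name
        if self.rule_kind == "chain":
            return f"chain_{self.threshold:g}m"
        if self.rule_kind == "focal":
            return f"focal_{self.threshold:g}m"
        if self.rule_kind == "fixed_point":
            return f"fixed_point_{self.threshold:g}m"
        return "adaptive_chain"


@dataclass(frozen=True)
class GroupPartition:
    """A disjoint assignment of a scene's individuals to labelled components,
    each classified singleton (1 member) or group (>= 2 members)."""

    scene_id: str
    assignment: dict[str, str]  # individual_id -> component label
    unit_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes: dict[str, int] = {}
        for comp in self.assignment.values():
            sizes[comp] = sizes.get(comp, 0) + 1
        labels = {c: (SINGLETON if k == 1 else GROUP) for c, k in sizes.items()}
        if self.unit_labels:
            if self.unit_labels != labels:
                raise ValueError("unit_labels inconsistent with component sizes")
        else:
            object.__setattr__(self, "unit_labels", labels)

    def components(self) -> dict[str, list[str]]:
        """Component label -> sorted member ids."""
        out: dict[str, list[str]] = {}
        for ind, comp in self.assignment.items():
            out.setdefault(comp, []).append(ind)
        return {c: sorted(m) for c, m in out.items()}

    def component_sizes(self) -> dict[str, int]:
        return {c: len(m) for c, m in self.components().items()}


@dataclass(frozen=True)
class SightingSummary:
    """Counts for one sighting: the full set of units observed in a scene."""

    scene_id: str
    n_individuals: int
    n_units: int
    n_singletons: int
    n_groups: int
    group_sizes: tuple[int, ...]  # sizes of groups only (>= 2), descending


def _partition_from_adjacency(scene: Scene, adjacency: np.ndarray) -> GroupPartition:
    """Connected components of a boolean adjacency matrix, with component
    labels assigned in ascending order of the minimum member identifier."""
    n = len(scene)
    if n == 0:
        return GroupPartition(scene_id=scene.scene_id, assignment={})
    graph = csr_matrix(adjacency)
    _, comp_idx = connected_components(graph, directed=False)
    ids = scene.ids
    min_id: dict[int, str] = {}
    for i, c in enumerate(comp_idx):
        c = int(c)
        if c not in min_id or ids[i] < min_id[c]:
            min_id[c] = ids[i]
    order = sorted(min_id, key=lambda c: min_id[c])
    relabel = {c: f"c{rank + 1}" for rank, c in enumerate(order)}
    assignment = {ids[i]: relabel[int(comp_idx[i])] for i in range(n)}
    return GroupPartition(scene_id=scene.scene_id, assignment=assignment)


def chain_rule_partition(scene: Scene, threshold: float) -> GroupPartition:
    """Partition a scene by the chain rule at a single threshold (metres).

    Components are the connected components of the graph joining every pair
    at distance <= threshold (inclusive).
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if len(scene) == 0:
        return GroupPartition(scene_id=scene.scene_id, assignment={})
    dist = pairwise_distances(scene)
    adj = dist <= threshold
    np.fill_diagonal(adj, False)
    return _partition_from_adjacency(scene, adj)


def adaptive_chain_partition(
    scene: Scene,
    thresholds_by_state: dict[str, float],
    default_threshold: Optional[float] = None,
) -> GroupPartition:
    """Chain rule with a behavioral-state-dependent threshold.

    The edge (i, j) exists iff distance(i, j) <= T(i, j), where T is the
    shared state's threshold when states match and the maximum of the two
    states' thresholds otherwise (grouping-conservative: a mixed-behavior
    spatial cluster is not split by the stricter state). Individuals whose
    state has no entry use ``default_threshold``; a missing state with no
    default is an error.
    """
    if any(t < 0 for t in thresholds_by_state.values()):
        raise ValueError("thresholds must be >= 0")
    if len(scene) == 0:
        return GroupPartition(scene_id=scene.scene_id, assignment={})

    def state_threshold(state: Optional[str]) -> float:
        if state is not None and state in thresholds_by_state:
            return thresholds_by_state[state]
        if default_threshold is not None:
            return default_threshold
        raise ValueError(
            f"no threshold for state {state!r} and no default_threshold given"
        )

    t = np.array([state_threshold(r.state) for r in scene.records])
    dist = pairwise_distances(scene)
    pair_t = np.maximum.outer(t, t)
    adj = dist <= pair_t
    np.fill_diagonal(adj, False)
    return _partition_from_adjacency(scene, adj)


def focal_rule_group(scene: Scene, focal_id: str, radius: float) -> frozenset[str]:
    """All individuals within ``radius`` of the focal individual (inclusive),
    plus the focal itself; no chaining beyond the focal's radius."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    focal = scene.record(focal_id)  # KeyError if unknown
    xy = scene.coords
    d = np.hypot(xy[:, 0] - focal.x, xy[:, 1] - focal.y)
    return frozenset(i for i, di in zip(scene.ids, d) if di <= radius)


def fixed_point_rule_group(
    scene: Scene, point: tuple[float, float], radius: float
) -> frozenset[str]:
    """All individuals within ``radius`` (inclusive) of a fixed location,
    e.g. the research vessel; may be empty."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    xy = scene.coords
    d = np.hypot(xy[:, 0] - point[0], xy[:, 1] - point[1])
    return frozenset(i for i, di in zip(scene.ids, d) if di <= radius)


def classify_units(partition: GroupPartition) -> SightingSummary:
    """Summarize a partition into the singleton / group / sighting taxonomy.

    Group sizes exclude singletons (a group has >= 2 members); singletons
    are counted separately so they can still enter downstream analyses.
    """
    sizes = sorted(partition.component_sizes().values(), reverse=True)
    group_sizes = tuple(s for s in sizes if s >= 2)
    return SightingSummary(
        scene_id=partition.scene_id,
        n_individuals=sum(sizes),
        n_units=len(sizes),
        n_singletons=sum(1 for s in sizes if s == 1),
        n_groups=len(group_sizes),
        group_sizes=group_sizes,
    )


def membership_partition(
    scene: Scene, members: frozenset[str], group_label: str = "c1"
) -> GroupPartition:
    """Represent a member set (focal / fixed-point rule output) as a
    partition: members one component, every non-member its own singleton."""
    assignment: dict[str, str] = {}
    k = 2
    for ind in sorted(scene.ids):
        if ind in members:
            assignment[ind] = group_label
        else:
            assignment[ind] = f"c{k}"
            k += 1
    return GroupPartition(scene_id=scene.scene_id, assignment=assignment)


def apply_rule(scene: Scene, spec: RuleSpec) -> GroupPartition:
    """Apply any RuleSpec to a scene, returning a partition."""
    if spec.rule_kind == "chain":
        return chain_rule_partition(scene, spec.threshold)
    if spec.rule_kind == "adaptive_chain":
        return adaptive_chain_partition(
            scene, spec.thresholds_by_state, spec.default_threshold
        )
    if spec.rule_kind == "focal":
        if spec.focal_id is None or spec.focal_id not in scene.ids:
            raise ValueError(
                f"focal rule needs a focal_id present in scene "
                f"{scene.scene_id!r} (got {spec.focal_id!r})"
            )
        members = focal_rule_group(scene, spec.focal_id, spec.threshold)
        return membership_partition(scene, members)
    if spec.rule_kind == "fixed_point":
        point = spec.point
        if point is None:
            if scene.observer is None:
                raise ValueError(
                    "fixed_point rule needs a point or a scene observer position"
                )
            point = scene.observer
        members = fixed_point_rule_group(scene, point, spec.threshold)
        return membership_partition(scene, members)
    raise ValueError(f"unknown rule_kind {spec.rule_kind!r}")
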