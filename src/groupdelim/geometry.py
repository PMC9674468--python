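"""Coordinate handling and interindividual distance computations.

The central measurement here is the *directional nearest-neighbor distance*:
for each individual in an instantaneous positional snapshot (a "scene"), the
Euclidean distance to the nearest other individual lying strictly further
along a fixed compass bearing (north, by convention). Pooled over many
scenes, the distribution of these distances separates within-group from
between-group spacing and is the raw material for data-driven group
threshold estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0


@dataclass(frozen=True)
class IndividualRecord:
    """One individual in one scene: planar position in metres, optional
    behavioral state and body length."""

    individual_id: str
    x: float
    y: float
    state: Optional[str] = None
    body_length: Optional[float] = None

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(
                f"individual {self.individual_id!r}: coordinates must be finite"
            )
        if self.body_length is not None and not self.body_length > 0:
            raise ValueError(
                f"individual {self.individual_id!r}: body_length must be > 0"
            )


@dataclass(frozen=True)
class Scene:
    """An instantaneous field observation of a set of individuals.

    ``window`` is an optional rectangular survey bound
    ``(x_min, y_min, x_max, y_max)`` in metres; ``observer`` an optional
    observer position (e.g., the research vessel).
    """

    scene_id: str
    records: tuple[IndividualRecord, ...]
    window: Optional[tuple[float, float, float, float]] = None
    observer: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        ids = [r.individual_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(
                f"scene {self.scene_id!r}: duplicate individual_id(s) {dupes}"
            )
        if self.window is not None:
            x0, y0, x1, y1 = self.window
            for r in self.records:
                if not (x0 <= r.x <= x1 and y0 <= r.y <= y1):
                    raise ValueError(
                        f"scene {self.scene_id!r}: individual "
                        f"{r.individual_id!r} at ({r.x}, {r.y}) lies outside "
                        f"window {self.window}"
                    )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.individual_id for r in self.records]

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of planar coordinates in record order."""
        if not self.records:
            return np.empty((0, 2))
        return np.array([[r.x, r.y] for r in self.records], dtype=float)

    def record(self, individual_id: str) -> IndividualRecord:
        for r in self.records:
            if r.individual_id == individual_id:
                return r
        raise KeyError(f"no individual {individual_id!r} in scene {self.scene_id!r}")


@dataclass(frozen=True)
class DirectionalNNRecord:
    """Distance from ``source_id`` to its nearest neighbor strictly further
    along ``bearing`` (degrees clockwise from north)."""

    scene_id: str
    source_id: str
    neighbor_id: str
    distance: float
    bearing: float
    source_state: Optional[str] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if self.distance < 0:
            raise ValueError("distance must be >= 0")


def to_planar(
    points: Sequence[tuple[float, float]],
    reference: tuple[float, float],
) -> np.ndarray:
    """Project (longitude, latitude) pairs onto a local tangent plane.

    Equirectangular projection about ``reference`` on a spherical Earth
    (R = 6371 km): x = R cos(lat0) dlon, y = R dlat, in metres. Valid for
    points within about a degree of the reference; beyond that a warning is
    logged but the projection is still computed.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    lon0, lat0 = float(reference[0]), float(reference[1])
    lats = np.concatenate([pts[:, 1], [lat0]])
    if np.any(np.abs(lats) > 90.0):
        raise ValueError("latitude out of range [-90, 90]")
    if pts.size and np.max(np.abs(pts - [lon0, lat0])) > 1.0:
        logger.warning(
            "points farther than 1 degree from reference; local tangent-plane "
            "distances may be distorted"
        )
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(pts[:, 0] - lon0)
    y = EARTH_RADIUS_M * np.radians(pts[:, 1] - lat0)
    return np.column_stack([x, y])


def pairwise_distances(scene: Scene) -> np.ndarray:
    """Symmetric matrix of Euclidean distances (metres), in record order."""
    n = len(scene)
    if n == 0:
        return np.empty((0, 0))
    if n == 1:
        return np.zeros((1, 1))
    return squareform(pdist(scene.coords))


def _bearing_axes(bearing: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors along and perpendicular to a compass bearing.

    Bearing is degrees clockwise from north; north is +y, east is +x.
    """
    rad = math.radians(bearing)
    along = np.array([math.sin(rad), math.cos(rad)])
    perp = np.array([math.cos(rad), -math.sin(rad)])
    return along, perp


def directional_nn_distances(
    scene: Scene,
    bearing: float = 0.0,
    body_length_units: bool = False,
) -> list[DirectionalNNRecord]:
    """Nearest-neighbor-in-a-constant-direction distances for one scene.

    For each individual, find all others strictly further along ``bearing``
    and record the full Euclidean distance to the nearest of them. The
    along-bearing-maximal individual yields no record. "Strictly further" is
    a strict total order: greater along-bearing coordinate, ties broken by
    greater perpendicular coordinate, then by identifier — so generic scenes
    yield exactly n - 1 records.

    With ``body_length_units`` the distance is divided by the mean body
    length of the pair (or the single recorded length if only one is known).
    """
    n = len(scene)
    if n == 0:
        raise ValueError("scene must contain at least one individual")
    if body_length_units and any(r.body_length is None for r in scene.records):
        missing = [r.individual_id for r in scene.records if r.body_length is None]
        raise ValueError(
            f"body_length_units requires body_length for all records; "
            f"missing for {missing}"
        )
    if n == 1:
        return []

    xy = scene.coords
    u_along, u_perp = _bearing_axes(bearing)
    along = xy @ u_along
    perp = xy @ u_perp
    ids = scene.ids
    keys = list(zip(along, perp, ids))

    out: list[DirectionalNNRecord] = []
    for i in range(n):
        ahead = [j for j in range(n) if j != i and keys[j] > keys[i]]
        if not ahead:
            continue
        d = np.hypot(xy[ahead, 0] - xy[i, 0], xy[ahead, 1] - xy[i, 1])
        # nearest ahead individual; distance ties broken by identifier
        best = min(zip(d, (ids[j] for j in ahead), ahead))
        dist, _, j = best
        dist = float(dist)
        if body_length_units:
            lens = [
                length
                for length in (scene.records[i].body_length, scene.records[j].body_length)
                if length is not None
            ]
            dist /= float(np.mean(lens))
        out.append(
            DirectionalNNRecord(
                scene_id=scene.scene_id,
                source_id=ids[i],
                neighbor_id=ids[j],
                distance=dist,
                bearing=float(bearing),
                source_state=scene.records[i].state,
            )
        )
    return out
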