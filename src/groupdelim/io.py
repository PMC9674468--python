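"""Reading and writing the tabular dialects used throughout the package.

Scene CSV: one row per individual per scene with columns
``scene_id,individual_id`` plus either planar ``x_m,y_m`` (metres) or
geographic ``lon,lat`` (projected locally per scene about the scene
centroid), and optional ``state`` and ``body_length_m``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .geometry import DirectionalNNRecord, IndividualRecord, Scene, to_planar
from .rules import GroupPartition, SightingSummary
from .thresholds import DistanceSample

PathLike = Union[str, Path]


def read_scenes(path: PathLike) -> list[Scene]:
    """Read scenes from CSV, validating ids and coordinates.

    Rows with non-numeric coordinates or duplicate (scene_id, individual_id)
    raise an error naming the offending row (1-based, excluding header).
    """
    df = pd.read_csv(
        path,
        dtype={"scene_id": str, "individual_id": str},
        float_precision="round_trip",
    )
    required = {"scene_id", "individual_id"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    planar = {"x_m", "y_m"} <= set(df.columns)
    geographic = {"lon", "lat"} <= set(df.columns)
    if not planar and not geographic:
        raise ValueError(f"{path}: need either (x_m, y_m) or (lon, lat) columns")

    coord_cols = ["x_m", "y_m"] if planar else ["lon", "lat"]
    for col in coord_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna() & df[col].notna()] + 1
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {col} in data row(s) {bad.tolist()[:5]}"
            )
        if df[col].isna().any():
            rows = (df.index[df[col].isna()] + 1).tolist()[:5]
            raise ValueError(f"{path}: missing {col} in data row(s) {rows}")
        df[col] = vals

    dup = df.duplicated(subset=["scene_id", "individual_id"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 1).tolist()
        raise ValueError(
            f"{path}: duplicate (scene_id, individual_id) in data row(s) {rows[:10]}"
        )

    scenes: list[Scene] = []
    for scene_id, grp in df.groupby("scene_id", sort=True):
        if planar:
            xy = grp[["x_m", "y_m"]].to_numpy(dtype=float)
        else:
            pts = grp[["lon", "lat"]].to_numpy(dtype=float)
            ref = tuple(pts.mean(axis=0))
            xy = to_planar(pts, ref)
        records = []
        for (_, row), (x, y) in zip(grp.iterrows(), xy):
            state = row.get("state")
            if pd.isna(state):
                state = None
            bl = row.get("body_length_m")
            bl = None if bl is None or pd.isna(bl) else float(bl)
            records.append(
                IndividualRecord(
                    individual_id=str(row["individual_id"]),
                    x=float(x),
                    y=float(y),
                    state=state,
                    body_length=bl,
                )
            )
        records.sort(key=lambda r: r.individual_id)
        scenes.append(Scene(scene_id=str(scene_id), records=tuple(records)))
    return scenes


def write_scenes(scenes: Iterable[Scene], path: PathLike) -> None:
    rows = []
    for scene in scenes:
        for r in sorted(scene.records, key=lambda r: r.individual_id):
            rows.append(
                {
                    "scene_id": scene.scene_id,
                    "individual_id": r.individual_id,
                    "x_m": r.x,
                    "y_m": r.y,
                    "state": r.state,
                    "body_length_m": r.body_length,
                }
            )
    # %.17g round-trips IEEE doubles exactly
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_nn_records(records: Iterable[DirectionalNNRecord], path: PathLike) -> None:
    rows = [
        {
            "scene_id": r.scene_id,
            "source_id": r.source_id,
            "neighbor_id": r.neighbor_id,
            "distance_m": r.distance,
            "bearing_deg": r.bearing,
            "source_state": r.source_state,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_distances(path: PathLike, stratify_by_state: bool = False) -> DistanceSample:
    """Read a DistanceSample from a directional-NN CSV (``distance_m``
    column) or a bare one-column file of distances in metres."""
    df = pd.read_csv(path)
    if "distance_m" in df.columns:
        strata = None
        if stratify_by_state:
            col = df.get("source_state", pd.Series(["unknown"] * len(df)))
            strata = col.fillna("unknown").astype(str).to_numpy()
        prov = (
            df["scene_id"].astype(str).to_numpy() if "scene_id" in df.columns else None
        )
        return DistanceSample(
            distances=df["distance_m"].to_numpy(dtype=float),
            strata=strata,
            provenance=prov,
        )
    if df.shape[1] == 1:
        return DistanceSample(distances=df.iloc[:, 0].to_numpy(dtype=float))
    raise ValueError(
        f"{path}: expected a 'distance_m' column or a single-column distance file"
    )


def write_partitions(partitions: Sequence[GroupPartition], path: PathLike) -> None:
    rows = []
    for part in partitions:
        for ind in sorted(part.assignment):
            comp = part.assignment[ind]
            rows.append(
                {
                    "scene_id": part.scene_id,
                    "individual_id": ind,
                    "component_label": comp,
                    "unit_label": part.unit_labels[comp],
                }
            )
    rows.sort(key=lambda r: (r["scene_id"], r["individual_id"]))
    pd.DataFrame(rows).to_csv(path, index=False)


def write_summary(summaries: Sequence[SightingSummary], path: PathLike) -> None:
    payload = {
        s.scene_id: {
            "n_individuals": s.n_individuals,
            "n_units": s.n_units,
            "n_singletons": s.n_singletons,
            "n_groups": s.n_groups,
            "group_sizes": list(s.group_sizes),
        }
        for s in summaries
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_json(payload: dict, path: PathLike) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(payload, indent=2, default=default) + "\n")
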