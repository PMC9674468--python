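"""Data-driven threshold-distance estimation from directional NN distances.

The procedure: pool nearest-neighbor-in-a-constant-direction distances over
many scenes, estimate their probability density with a Gaussian kernel, and
read naturally occurring cutoff points off the density curve — antimodes
(valleys) where the numerical gradient changes sign from negative to
positive, kept only when sufficiently prominent relative to the flanking
modes. A within-group spacing mode and a between-group spacing mode produce
one cutoff; nested spatial organization (subgroups within groups within
supergroups) produces several, ascending. The smallest cutoff delimits the
tightest level. Per-behavioral-state estimation yields a threshold for each
state, supporting behavior-adaptive chain rules.

Distances are strictly positive and right-skewed, with grouping scales often
separated by orders of magnitude, so the default analysis scale is
logarithmic; estimates are back-transformed to metres for reporting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .geometry import DirectionalNNRecord

logger = logging.getLogger(__name__)

MIN_RELIABLE_N = 30
DEFAULT_MIN_PROMINENCE = 0.10
DEFAULT_GRID_SIZE = 512

#: Conventional names for nested organizational levels, smallest cutoff first.
LEVEL_NAMES = ("subgroup", "group", "supergroup")


@dataclass(frozen=True)
class DistanceSample:
    """Pooled directional NN distances with optional per-distance stratum
    labels (behavioral states) and provenance (scene of origin)."""

    distances: np.ndarray
    strata: Optional[np.ndarray] = None
    provenance: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        object.__setattr__(self, "distances", d)
        if d.ndim != 1:
            raise ValueError("distances must be one-dimensional")
        bad = np.flatnonzero(~(d > 0))
        if bad.size:
            where = ""
            if self.provenance is not None:
                where = f" (provenance: {np.asarray(self.provenance)[bad[:5]]})"
            raise ValueError(
                f"{bad.size} non-positive distance(s) at indices "
                f"{bad[:5].tolist()}{where}; coincident or negative positions "
                "indicate a data problem"
            )
        for name in ("strata", "provenance"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr)
                object.__setattr__(self, name, arr)
                if arr.shape != d.shape:
                    raise ValueError(f"{name} must parallel distances")

    @property
    def n(self) -> int:
        return int(self.distances.size)

    def stratum(self, label: str) -> "DistanceSample":
        if self.strata is None:
            raise ValueError("sample has no strata")
        mask = self.strata == label
        return DistanceSample(
            distances=self.distances[mask],
            strata=self.strata[mask],
            provenance=None if self.provenance is None else self.provenance[mask],
        )


@dataclass(frozen=True)
class DensityCurve:
    """Kernel density estimate on an even grid.

    ``grid`` is on the analysis scale (metres, or log-metres when
    ``log_scale``); ``grid_m`` always gives metres. The curve integrates to
    one on its own scale.
    """

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    log_scale: bool
    n: int = 0
    reliable: bool = True

    def __post_init__(self) -> None:
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)
        if np.any(v < 0):
            raise ValueError("density values must be >= 0")
        area = float(np.trapezoid(v, g))
        if abs(area - 1.0) > 0.01:
            raise ValueError(f"density integrates to {area:.4f}, expected 1 +- 1%")

    @property
    def grid_m(self) -> np.ndarray:
        return np.exp(self.grid) if self.log_scale else self.grid


@dataclass(frozen=True)
class ThresholdEstimate:
    """Ordered cutoff distances with the modes they separate and diagnostics.

    ``cutoffs`` and ``modes`` are in metres and interleave: each cutoff lies
    strictly between two modes. An empty cutoff list is the explicit "no
    natural cutoff" outcome for a unimodal distance distribution.
    """

    cutoffs: tuple[float, ...]
    modes: tuple[float, ...]
    n: int
    diagnostics: dict = field(default_factory=dict)
    per_stratum: Optional[dict[str, "ThresholdEstimate"]] = None

    def __post_init__(self) -> None:
        c = tuple(float(x) for x in self.cutoffs)
        m = tuple(float(x) for x in self.modes)
        object.__setattr__(self, "cutoffs", c)
        object.__setattr__(self, "modes", m)
        if list(c) != sorted(c) or list(m) != sorted(m):
            raise ValueError("cutoffs and modes must be ascending")
        for i, cut in enumerate(c):
            if not (m[i] < cut < m[i + 1]):
                raise ValueError("cutoffs must interleave modes")

    @property
    def primary_cutoff(self) -> Optional[float]:
        """The deepest cutoff (largest absolute density drop), or None.

        This is the single threshold to use when one chain-rule distance is
        needed and the distribution shows only one dominant valley.
        """
        if not self.cutoffs:
            return None
        depths = self.diagnostics.get("depth")
        if not depths or len(depths) != len(self.cutoffs):
            return self.cutoffs[0]
        return self.cutoffs[int(np.argmax(depths))]

    @property
    def level_names(self) -> tuple[str, ...]:
        """Nested-unit naming convention for the ascending cutoffs
        (labelling only): first -> subgroup, second -> group, third ->
        supergroup."""
        return tuple(
            LEVEL_NAMES[i] if i < len(LEVEL_NAMES) else f"level{i + 1}"
            for i in range(len(self.cutoffs))
        )

    def to_dict(self) -> dict:
        out = {
            "n": self.n,
            "cutoffs_m": list(self.cutoffs),
            "modes_m": list(self.modes),
            "level_names": list(self.level_names),
            **self.diagnostics,
        }
        if self.per_stratum is not None:
            out["per_state"] = {s: e.to_dict() for s, e in self.per_stratum.items()}
        return out


def pool_distances(
    nn_records: Iterable[Union[DirectionalNNRecord, Sequence[DirectionalNNRecord]]],
    stratify_by_state: bool = False,
) -> DistanceSample:
    """Concatenate directional NN records (flat, or one list per scene) into
    a pooled DistanceSample, optionally labelled by source-individual state."""
    flat: list[DirectionalNNRecord] = []
    for item in nn_records:
        if isinstance(item, DirectionalNNRecord):
            flat.append(item)
        else:
            flat.extend(item)
    if not flat:
        raise ValueError("no directional NN records to pool")
    for r in flat:
        if not r.distance > 0:
            raise ValueError(
                f"non-positive distance for pair ({r.source_id!r}, "
                f"{r.neighbor_id!r}) in scene {r.scene_id!r}"
            )
    distances = np.array([r.distance for r in flat])
    provenance = np.array([r.scene_id for r in flat])
    strata = None
    if stratify_by_state:
        strata = np.array(
            [r.source_state if r.source_state is not None else "unknown" for r in flat]
        )
    return DistanceSample(distances=distances, strata=strata, provenance=provenance)


def silverman_bandwidth(x: np.ndarray) -> float:
    """Silverman's rule of thumb: 0.9 min(sd, IQR/1.34) n^(-1/5)."""
    x = np.asarray(x, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    spread = min(s for s in (sd, iqr / 1.34) if s > 0) if (sd > 0 or iqr > 0) else 0.0
    if spread == 0.0:
        # degenerate (near-constant) sample: fall back to a tiny positive width
        spread = max(abs(float(np.mean(x))), 1.0) * 1e-3
    return 0.9 * spread * n ** (-1 / 5)


def _resolve_bandwidth(x: np.ndarray, bandwidth_rule) -> float:
    if isinstance(bandwidth_rule, (int, float)):
        h = float(bandwidth_rule)
        if h <= 0:
            raise ValueError("bandwidth must be > 0")
        return h
    if bandwidth_rule == "silverman":
        return silverman_bandwidth(x)
    if bandwidth_rule == "scott":
        sd = float(np.std(x, ddof=1)) if x.size > 1 else 1e-3
        return 1.06 * max(sd, 1e-12) * x.size ** (-1 / 5)
    raise ValueError(f"unknown bandwidth rule {bandwidth_rule!r}")


def estimate_density(
    sample: DistanceSample,
    bandwidth_rule="silverman",
    log_scale: bool = True,
    grid_size: int = DEFAULT_GRID_SIZE,
) -> DensityCurve:
    """Gaussian-kernel density of the pooled distances.

    On the log scale the density is that of log-distance, evaluated on an
    even grid in log-metres (downstream cutoffs are back-transformed to
    metres). On the linear scale the grid is clipped at zero. Samples below
    30 distances are flagged unreliable and a warning is logged.
    """
    if sample.n == 0:
        raise ValueError("empty distance sample")
    reliable = sample.n >= MIN_RELIABLE_N
    if not reliable:
        logger.warning(
            "only %d distances (< %d): density and cutoffs flagged unreliable",
            sample.n,
            MIN_RELIABLE_N,
        )
    x = np.log(sample.distances) if log_scale else sample.distances
    h = _resolve_bandwidth(x, bandwidth_rule)
    lo, hi = float(x.min()) - 3 * h, float(x.max()) + 3 * h
    if not log_scale:
        lo = max(lo, 0.0)
    grid = np.linspace(lo, hi, grid_size)
    # Gaussian kernel sum, chunked over the sample to bound memory
    values = np.zeros_like(grid)
    for start in range(0, x.size, 20_000):
        chunk = x[start : start + 20_000]
        z = (grid[:, None] - chunk[None, :]) / h
        values += np.exp(-0.5 * z * z).sum(axis=1)
    values /= x.size * h * np.sqrt(2 * np.pi)
    if not log_scale and lo == 0.0:
        # renormalize mass lost to the clip at zero
        values /= np.trapezoid(values, grid)
    return DensityCurve(
        grid=grid,
        values=values,
        bandwidth=h,
        log_scale=log_scale,
        n=sample.n,
        reliable=reliable,
    )


def _alternating_extrema(values: np.ndarray) -> tuple[list[int], list[int]]:
    """Indices of local maxima and the interior minima between them.

    Plateaus are handled by carrying the last nonzero slope sign; the
    returned sequence strictly alternates max, min, max, ...
    """
    d = np.diff(values)
    sign = np.sign(d)
    # carry previous nonzero sign through flat stretches
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    maxima: list[int] = []
    minima: list[int] = []
    for i in range(1, sign.size):
        if sign[i - 1] > 0 and sign[i] < 0:
            maxima.append(i)
        elif sign[i - 1] < 0 and sign[i] > 0:
            minima.append(i)
    # boundary maxima (curve decreasing from the start / increasing at the end)
    first = next((s for s in sign if s != 0), 0)
    if first < 0:
        maxima.insert(0, 0)
    last = next((s for s in sign[::-1] if s != 0), 0)
    if last > 0:
        maxima.append(values.size - 1)
    # keep only minima strictly between two maxima
    minima = [m for m in minima if maxima and maxima[0] < m < maxima[-1]]
    return maxima, minima


def find_cutoffs(
    curve: DensityCurve,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_levels: int = 3,
    min_mode_mass: float = 0.02,
) -> ThresholdEstimate:
    """Locate cutoff distances as prominent antimodes of the density curve.

    An antimode is a grid point where the numerical gradient changes sign
    from negative to positive. Modes whose basin (the density mass between
    the adjacent valleys) holds less than ``min_mode_mass`` of the sample
    are discarded first: isolated tail bumps carrying a handful of
    observations are sampling noise, not spacing modes, yet the valleys
    beside them would otherwise score near-unit relative prominence. Each
    surviving antimode's relative prominence is
    (min flanking-mode height - antimode height) / min flanking-mode height.
    Antimodes below ``min_prominence`` are merged away (the shallowest first,
    absorbing the lower of its flanking modes), so the retained cutoffs
    strictly interleave the retained modes. At most ``max_levels`` cutoffs
    are kept, deepest first — depth being the absolute density drop from the
    lower flanking mode to the valley, which is robust to near-unit relative
    prominence at negligible tail bumps — then reported ascending. A
    unimodal curve yields an empty cutoff list — a valid "no natural cutoff"
    outcome.
    """
    if not (0 <= min_prominence <= 1):
        raise ValueError("min_prominence must be in [0, 1]")
    v = curve.values
    maxima, minima = _alternating_extrema(v)

    # discard negligible tail bumps: remove modes whose basin mass is below
    # the floor, merging their valleys (keep the deeper adjacent minimum)
    g = curve.grid

    def basin_mass(i: int) -> float:
        lo = minima[i - 1] if i > 0 else 0
        hi = minima[i] if i < len(minima) else v.size - 1
        return float(np.trapezoid(v[lo : hi + 1], g[lo : hi + 1]))

    while len(maxima) > 1:
        masses = [basin_mass(i) for i in range(len(maxima))]
        i = int(np.argmin(masses))
        if masses[i] >= min_mode_mass:
            break
        if i == 0:
            maxima.pop(0)
            minima.pop(0)
        elif i == len(maxima) - 1:
            maxima.pop()
            minima.pop()
        else:
            maxima.pop(i)
            # of the two valleys now merged, keep the deeper one
            drop = i - 1 if v[minima[i - 1]] >= v[minima[i]] else i
            minima.pop(drop)

    def prom(mi: int, lo_max: int, hi_max: int) -> float:
        flank = min(v[lo_max], v[hi_max])
        if flank <= 0:
            return 0.0
        return float((flank - v[mi]) / flank)

    # iteratively merge the least prominent valley until all pass
    while minima:
        proms = [
            prom(m, maxima[i], maxima[i + 1]) for i, m in enumerate(minima)
        ]
        worst = int(np.argmin(proms))
        if proms[worst] >= min_prominence:
            break
        lo, hi = maxima[worst], maxima[worst + 1]
        maxima.remove(lo if v[lo] <= v[hi] else hi)
        minima.pop(worst)

    def depth(mi: int, lo_max: int, hi_max: int) -> float:
        return float(min(v[lo_max], v[hi_max]) - v[mi])

    depths = [depth(m, maxima[i], maxima[i + 1]) for i, m in enumerate(minima)]
    if len(minima) > max_levels:
        keep = sorted(
            sorted(range(len(minima)), key=lambda i: -depths[i])[:max_levels]
        )
        # drop the unused valleys, merging the lower flanking mode of each
        for i in sorted(set(range(len(minima))) - set(keep), reverse=True):
            lo, hi = maxima[i], maxima[i + 1]
            maxima.remove(lo if v[lo] <= v[hi] else hi)
            minima.pop(i)
    proms = [prom(m, maxima[i], maxima[i + 1]) for i, m in enumerate(minima)]
    depths = [depth(m, maxima[i], maxima[i + 1]) for i, m in enumerate(minima)]

    gm = curve.grid_m
    cutoffs = tuple(float(gm[m]) for m in minima)
    modes = (
        tuple(float(gm[m]) for m in maxima)
        if minima
        else (float(gm[int(np.argmax(v))]),)
    )
    return ThresholdEstimate(
        cutoffs=cutoffs,
        modes=modes,
        n=curve.n,
        diagnostics={
            "bandwidth": curve.bandwidth,
            "scale": "log" if curve.log_scale else "linear",
            "min_prominence": min_prominence,
            "prominence": [round(p, 4) for p in proms],
            "depth": [float(d) for d in depths],
            "reliable": curve.reliable,
        },
    )


def estimate_thresholds(
    sample: DistanceSample,
    bandwidth_rule="silverman",
    log_scale: bool = True,
    grid_size: int = DEFAULT_GRID_SIZE,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_levels: int = 3,
) -> ThresholdEstimate:
    """Convenience: density estimation followed by cutoff detection."""
    curve = estimate_density(sample, bandwidth_rule, log_scale, grid_size)
    return find_cutoffs(curve, min_prominence, max_levels)


def stratified_thresholds(
    sample: DistanceSample,
    bandwidth_rule="silverman",
    log_scale: bool = True,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_levels: int = 3,
) -> ThresholdEstimate:
    """Cutoffs per behavioral state plus the pooled estimate.

    Strata with fewer than 30 distances are skipped and listed in the
    diagnostics; if every stratum is too small, this is an error.
    """
    if sample.strata is None:
        raise ValueError("sample has no strata; pool with stratify_by_state=True")
    labels = sorted(set(sample.strata.tolist()))
    per: dict[str, ThresholdEstimate] = {}
    skipped: list[str] = []
    for lab in labels:
        sub = sample.stratum(lab)
        if sub.n < MIN_RELIABLE_N:
            logger.warning("stratum %r has only %d distances; skipped", lab, sub.n)
            skipped.append(lab)
            continue
        per[lab] = estimate_thresholds(
            sub, bandwidth_rule, log_scale,
            min_prominence=min_prominence, max_levels=max_levels,
        )
    if not per:
        raise ValueError(
            f"all strata below the minimum sample size ({MIN_RELIABLE_N})"
        )
    pooled = estimate_thresholds(
        sample, bandwidth_rule, log_scale,
        min_prominence=min_prominence, max_levels=max_levels,
    )
    diagnostics = dict(pooled.diagnostics)
    diagnostics["skipped_strata"] = skipped
    return ThresholdEstimate(
        cutoffs=pooled.cutoffs,
        modes=pooled.modes,
        n=pooled.n,
        diagnostics=diagnostics,
        per_stratum=per,
    )


def bootstrap_cutoff_interval(
    sample: DistanceSample,
    B: int = 200,
    seed: int = 0,
    bandwidth_rule="silverman",
    log_scale: bool = True,
    min_prominence: float = DEFAULT_MIN_PROMINENCE,
    max_levels: int = 3,
) -> dict:
    """Nonparametric bootstrap stability intervals for each cutoff.

    Resamples the pooled distances with replacement B times, re-runs the
    full estimation, matches each replicate's cutoffs to the original ones
    by nearest distance, and reports 2.5/97.5 percentile intervals plus the
    distribution of cutoff counts across replicates.
    """
    if B < 100:
        raise ValueError("B must be >= 100 for stable percentile intervals")
    base = estimate_thresholds(
        sample, bandwidth_rule, log_scale,
        min_prominence=min_prominence, max_levels=max_levels,
    )
    rng = np.random.default_rng(seed)
    matched: list[list[float]] = [[] for _ in base.cutoffs]
    counts: dict[int, int] = {}
    d = sample.distances
    for _ in range(B):
        boot = DistanceSample(distances=rng.choice(d, size=d.size, replace=True))
        est = estimate_thresholds(
            boot, bandwidth_rule, log_scale,
            min_prominence=min_prominence, max_levels=max_levels,
        )
        counts[len(est.cutoffs)] = counts.get(len(est.cutoffs), 0) + 1
        for c in est.cutoffs:
            if base.cutoffs:
                j = int(np.argmin([abs(c - b) for b in base.cutoffs]))
                matched[j].append(c)
    intervals = []
    for j, c in enumerate(base.cutoffs):
        vals = np.array(matched[j])
        intervals.append(
            {
                "cutoff_m": c,
                "lo_m": float(np.percentile(vals, 2.5)) if vals.size else None,
                "hi_m": float(np.percentile(vals, 97.5)) if vals.size else None,
                "n_matched": int(vals.size),
            }
        )
    return {
        "B": B,
        "seed": seed,
        "intervals": intervals,
        "replicate_cutoff_counts": {str(k): v for k, v in sorted(counts.items())},
    }
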