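"""Data-conditioning chain applied before ordination and inference.

Steps, in pipeline order:

1. spatial averaging of behavior-specific used locations closer together
   than the plot-overlap threshold (so no two habitat plots overlap);
2. collinearity screening of candidate attributes (Pearson |r| against a
   configurable threshold, keeping the higher-priority member of each pair);
3. collapse of the seven woody-debris size-class counts to their first
   principal component;
4. pooled z-transformation of analysis attributes;
5. signed shortest distance from each site to the woodland-shrubland
   ecotone polyline (positive on the woodland side).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point

from rsfperm.dataset_io import AnalysisDataset, EcotoneLine, WOODY_DEBRIS_ATTRIBUTES

EARTH_RADIUS_M = 6_371_008.8

#: Field plot area of one forest-inventory plot, hectares.
PLOT_AREA_HA = 0.405

ACRE_TO_HECTARE = 0.40468564224


def acres_to_hectares(acres: float) -> float:
    """Exact acre -> hectare conversion (the inventory grid spacing of one
    plot per 6,000 acres is one per 2,428 ha)."""
    return acres * ACRE_TO_HECTARE


def plot_overlap_threshold(plot_area_ha: float = PLOT_AREA_HA) -> float:
    """Minimum center separation (m) at which two circular plots of the
    given area do not overlap: twice the plot radius, ``2*sqrt(A/pi)``.

    For the standard 0.405-ha plot this is 71.8 m.
    """
    if plot_area_ha <= 0:
        raise ValueError("plot area must be positive")
    return 2.0 * math.sqrt(plot_area_ha * 1e4 / math.pi)


def equirectangular_projection(
    ref_lat: float, ref_lon: float
) -> Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Local lon/lat -> planar meters projection about a reference point.

    Adequate for the <= ~100 km extents over which merge thresholds of tens
    of meters are applied; a study-area UTM projection can be substituted
    through the same callable interface.
    """
    cos_ref = math.cos(math.radians(ref_lat))

    def project(lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.radians(np.asarray(lon) - ref_lon) * cos_ref * EARTH_RADIUS_M
        y = np.radians(np.asarray(lat) - ref_lat) * EARTH_RADIUS_M
        return x, y

    return project


# ---------------------------------------------------------------------------
# Spatial averaging of near-duplicate used locations
# ---------------------------------------------------------------------------


@dataclass
class MergeResult:
    """Outcome of merging near-duplicate used locations."""

    merged_records: pd.DataFrame          # record_id, behavior, region, x, y, source_ids
    merge_map: dict[str, str]             # original id -> merged id
    threshold_m: float

    @property
    def n_merged_away(self) -> int:
        return len(self.merge_map) - len(self.merged_records)


def merge_close_locations(
    locations: pd.DataFrame,
    threshold_m: float | None = None,
    project: Callable | None = None,
) -> MergeResult:
    """Greedy closest-pair spatial averaging within (behavior, region).

    Repeatedly replaces the closest pair of same-behavior, same-region
    locations at distance < ``threshold_m`` by their unweighted coordinate
    centroid until every remaining pair is at least the threshold apart.
    Different behaviors (or regions) never merge.  Ties are broken by the
    lexicographically smallest (record_id, record_id) pair, so the result
    is deterministic and independent of row order.

    ``locations`` needs columns record_id, behavior, region, and either
    planar ``x``/``y`` meters or ``longitude``/``latitude`` plus a
    ``project`` callable.
    """
    if threshold_m is None:
        threshold_m = plot_overlap_threshold()
    loc = locations.copy()
    if loc["behavior"].isna().any() or (loc.get("behavior") == "none").any():
        raise ValueError("all locations must carry a behavior label")

    if "x" not in loc.columns or "y" not in loc.columns:
        if project is None:
            ref_lat = float(loc["latitude"].mean())
            ref_lon = float(loc["longitude"].mean())
            project = equirectangular_projection(ref_lat, ref_lon)
        x, y = project(loc["longitude"].to_numpy(float), loc["latitude"].to_numpy(float))
        loc["x"], loc["y"] = x, y

    merged_rows: list[dict] = []
    merge_map: dict[str, str] = {}

    for (behavior, region), group in loc.groupby(["behavior", "region"], sort=True):
        # cluster state: id -> (x, y, sorted tuple of source ids)
        clusters: dict[str, tuple[float, float, tuple[str, ...]]] = {
            str(r.record_id): (float(r.x), float(r.y), (str(r.record_id),))
            for r in group.itertuples()
        }
        while True:
            ids = sorted(clusters)
            if len(ids) < 2:
                break
            best: tuple[float, str, str] | None = None
            for i, a in enumerate(ids):
                ax, ay, _ = clusters[a]
                for b in ids[i + 1:]:
                    bx, by, _ = clusters[b]
                    d = math.hypot(ax - bx, ay - by)
                    if d < threshold_m and (best is None or d < best[0] - 1e-12):
                        best = (d, a, b)
            if best is None:
                break
            _, a, b = best
            ax, ay, asrc = clusters.pop(a)
            bx, by, bsrc = clusters.pop(b)
            sources = tuple(sorted(asrc + bsrc))
            new_id = sources[0]
            clusters[new_id] = ((ax + bx) / 2.0, (ay + by) / 2.0, sources)

        for cid, (cx, cy, sources) in sorted(clusters.items()):
            merged_rows.append(
                {
                    "record_id": cid,
                    "behavior": behavior,
                    "region": region,
                    "x": cx,
                    "y": cy,
                    "source_ids": sources,
                }
            )
            for s in sources:
                merge_map[s] = cid

    merged = pd.DataFrame(
        merged_rows, columns=["record_id", "behavior", "region", "x", "y", "source_ids"]
    )
    return MergeResult(merged_records=merged, merge_map=merge_map, threshold_m=threshold_m)


# ---------------------------------------------------------------------------
# Attribute screening
# ---------------------------------------------------------------------------


@dataclass
class AttributeScreen:
    """Result of collinearity screening."""

    retained: list[str]
    dropped: dict[str, str] = field(default_factory=dict)            # attr -> reason
    composite_definitions: dict[str, dict] = field(default_factory=dict)


#: Default keep-priority: direct field measurements first, derived indices
#: and transect-based duplicates last (so they are the ones dropped).
DEFAULT_SCREEN_PRIORITY: tuple[str, ...] = (
    "elevation",
    "slope",
    "stand_age",
    "tree_cover",
    "shrub_cover",
    "forb_cover",
    "grass_cover",
    *WOODY_DEBRIS_ATTRIBUTES,
    "distance_to_road",
    "distance_to_edge",
    "canopy_cover",
    "stand_density_index",
)


def screen_attributes(
    dataset: AnalysisDataset,
    candidates: Sequence[str],
    corr_threshold: float = 0.65,
    priority: Sequence[str] | None = None,
) -> AttributeScreen:
    """Drop the lower-priority member of each highly correlated pair.

    Pearson correlations are computed on complete cases over the candidate
    set; pairs with |r| >= ``corr_threshold`` are resolved by keeping the
    attribute that appears earlier in ``priority``.  Zero-variance
    attributes are dropped as degenerate.
    """
    if not (0.0 < corr_threshold < 1.0):
        raise ValueError("corr_threshold must lie in (0, 1)")
    priority = list(priority) if priority is not None else list(DEFAULT_SCREEN_PRIORITY)

    def rank(attr: str) -> int:
        return priority.index(attr) if attr in priority else len(priority)

    data = dataset.frame[list(candidates)].dropna()
    screen = AttributeScreen(retained=[], dropped={})

    active = []
    for attr in candidates:
        sd = float(data[attr].std(ddof=1)) if len(data) > 1 else 0.0
        if not np.isfinite(sd) or sd == 0.0:
            screen.dropped[attr] = "degenerate (zero variance)"
        else:
            active.append(attr)

    corr = data[active].corr(method="pearson")
    pairs = []
    for i, a in enumerate(active):
        for b in active[i + 1:]:
            r = float(corr.loc[a, b])
            if abs(r) >= corr_threshold:
                pairs.append((abs(r), r, a, b))
    # resolve strongest correlations first
    for _, r, a, b in sorted(pairs, reverse=True):
        if a in screen.dropped or b in screen.dropped:
            continue
        keep, drop = (a, b) if rank(a) <= rank(b) else (b, a)
        screen.dropped[drop] = f"|r| = {abs(r):.2f} with {keep}"

    screen.retained = [a for a in candidates if a not in screen.dropped]
    return screen


# ---------------------------------------------------------------------------
# Woody-debris collapse
# ---------------------------------------------------------------------------


def collapse_woody_debris(
    dataset: AnalysisDataset,
    members: Sequence[str] = WOODY_DEBRIS_ATTRIBUTES,
    name: str = "woody_debris",
) -> tuple[AnalysisDataset, float]:
    """Collapse the woody-debris size classes to their first principal component.

    Members are z-scored, the correlation matrix is eigen-decomposed, and
    first-component scores become the composite attribute.  The component
    is oriented so the mean loading over members is positive (more debris
    -> larger composite).  Returns the updated dataset and the fraction of
    member variance the component describes.
    """
    members = list(members)
    if len(members) < 2:
        raise ValueError("need at least two member attributes")
    data = dataset.frame[members]
    complete = data.dropna()
    means = complete.mean()
    sds = complete.std(ddof=1)
    if (sds == 0).all() or not np.isfinite(sds).any():
        raise ValueError("all woody-debris members are constant")
    live = [m for m in members if sds[m] > 0 and np.isfinite(sds[m])]
    if len(live) < 2:
        raise ValueError("fewer than two non-constant woody-debris members")

    z = (complete[live] - means[live]) / sds[live]
    corr = np.corrcoef(z.to_numpy(), rowvar=False)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    w = eigvecs[:, 0]
    if w.mean() < 0:
        w = -w
    fraction = float(eigvals[0] / eigvals.sum())

    # scores for every record with complete members; NaN elsewhere
    z_all = (data[live] - means[live]) / sds[live]
    scores = z_all.to_numpy() @ w
    scores[data[live].isna().any(axis=1).to_numpy()] = np.nan

    ds = dataset.copy()
    ds.frame[name] = scores
    ds.registry[name] = "pc_score"
    ds.composites[name] = {
        "members": live,
        "weights": {m: float(wi) for m, wi in zip(live, w)},
        "member_means": {m: float(means[m]) for m in live},
        "member_sds": {m: float(sds[m]) for m in live},
        "variance_fraction": fraction,
    }
    ds.log(
        f"collapse_woody_debris: {len(live)} classes -> '{name}', "
        f"first PC describes {100 * fraction:.1f}% of variation"
    )
    return ds, fraction


# ---------------------------------------------------------------------------
# Pooled z-transformation
# ---------------------------------------------------------------------------


def standardize(
    dataset: AnalysisDataset,
    attributes: Sequence[str],
    reference: str = "all",
) -> AnalysisDataset:
    """z-transform attributes over all records pooled across regions and roles.

    Uses the sample standard deviation (n-1).  Scaling parameters are
    stored on the dataset for inverse transformation; attributes already
    standardized are left untouched, so the operation is idempotent.

    ``reference`` selects the records whose mean/sd define the scale:
    ``"all"`` (default, pooled across roles) or ``"controls"`` (the
    availability sample only — useful when coefficients must be read on
    the availability distribution's scale); the transformation is applied
    to every record either way.
    """
    if reference not in ("all", "controls"):
        raise ValueError("reference must be 'all' or 'controls'")
    ds = dataset.copy()
    ref_mask = (
        np.ones(len(ds.frame), dtype=bool)
        if reference == "all"
        else (ds.frame["role"] == "control").to_numpy()
    )
    done = []
    for attr in attributes:
        if attr in ds.scaling:
            continue
        values = pd.to_numeric(ds.frame[attr], errors="coerce")
        mean = float(values[ref_mask].mean())
        sd = float(values[ref_mask].std(ddof=1))
        if not np.isfinite(sd) or sd == 0.0:
            raise ValueError(f"cannot standardize '{attr}': zero or undefined variance")
        ds.frame[attr] = (values - mean) / sd
        ds.scaling[attr] = (mean, sd)
        done.append(attr)
    if done:
        ds.log(f"standardize: z-transformed {done} (reference={reference}, n-1 sd)")
    return ds


def destandardize(dataset: AnalysisDataset, attributes: Sequence[str] | None = None) -> AnalysisDataset:
    """Invert :func:`standardize` using the stored scaling parameters."""
    ds = dataset.copy()
    attrs = list(attributes) if attributes is not None else list(ds.scaling)
    for attr in attrs:
        if attr not in ds.scaling:
            continue
        mean, sd = ds.scaling.pop(attr)
        ds.frame[attr] = ds.frame[attr] * sd + mean
    ds.log(f"destandardize: restored original scale for {attrs}")
    return ds


# ---------------------------------------------------------------------------
# Signed distance to the ecotone
# ---------------------------------------------------------------------------


def distance_to_edge(point: Sequence[float], line: EcotoneLine) -> float:
    """Signed shortest distance (m) from a planar point to the ecotone.

    The magnitude is the minimum Euclidean distance to any segment of the
    polyline; the sign follows the line's declared woodland side (positive
    in woodland, negative in shrubland, 0 on the line).
    """
    px, py = float(point[0]), float(point[1])
    if not (math.isfinite(px) and math.isfinite(py)):
        raise ValueError("point coordinates must be finite")
    ls = line.as_linestring()
    dist = ls.distance(Point(px, py))
    if dist == 0.0:
        return 0.0

    # side of the nearest segment: + = left of the directed polyline
    s = ls.project(Point(px, py))
    eps = min(1e-6, ls.length / 1e6)
    p0 = ls.interpolate(max(0.0, s - eps))
    p1 = ls.interpolate(min(ls.length, s + eps))
    tx, ty = p1.x - p0.x, p1.y - p0.y
    nearest = ls.interpolate(s)
    cross = tx * (py - nearest.y) - ty * (px - nearest.x)
    side = 1.0 if cross > 0 else (-1.0 if cross < 0 else 0.0)
    if side == 0.0:
        return 0.0
    if line.woodland_side == "right":
        side = -side
    return side * dist


def distances_to_edge(points: np.ndarray, line: EcotoneLine) -> np.ndarray:
    """Vectorized :func:`distance_to_edge` over an (n, 2) array."""
    return np.array([distance_to_edge(p, line) for p in np.asarray(points, dtype=float)])
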