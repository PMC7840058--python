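"""Synthetic study generator.

Emulates the statistical structure the analysis assumes: three study
regions, each with a pool of control plots whose habitat attributes are
drawn from a region-specific multivariate normal (truncated to valid
ranges) with a realistic correlation structure (tree cover vs stand
density index, correlated woody-debris size classes), behavior-specific
used locations drawn from a large availability pool by a log-linear
selection function ``w ∝ exp(u_region + β'z(x))`` with region-level
intercept heterogeneity, scattered missing cells, and an ecotone polyline
toward which low-elevation (hence selected) sites are biased.

Because used locations are a weighted resample of the same attribute
distribution the controls come from, the case-control logistic contrast
identifies exactly the generating ``β`` (on the z-scale of the
availability pool), which makes end-to-end parameter recovery a
well-defined test of the whole pipeline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from rsfperm.dataset_io import (
    ALL_COLUMNS,
    COVER_ATTRIBUTES,
    FEET_TO_METERS,
    WOODY_DEBRIS_ATTRIBUTES,
    AnalysisDataset,
    EcotoneLine,
)
from rsfperm.preprocess import EARTH_RADIUS_M, distances_to_edge, plot_overlap_threshold

#: Attributes generated from the multivariate normal, in order.
GENERATED_ATTRIBUTES: tuple[str, ...] = (
    "elevation",
    "slope",
    "stand_age",
    "stand_density_index",
    "canopy_cover",
    "tree_cover",
    "shrub_cover",
    "forb_cover",
    "grass_cover",
    *WOODY_DEBRIS_ATTRIBUTES,
    "distance_to_road",
)

NONNEGATIVE_ATTRIBUTES: tuple[str, ...] = (
    "slope",
    "stand_age",
    "stand_density_index",
    *WOODY_DEBRIS_ATTRIBUTES,
    "distance_to_road",
)

REF_LAT, REF_LON = 39.0, -116.0  # Great Basin reference for pseudo lon/lat


@dataclass
class RegionSpec:
    """Control pool definition for one study region."""

    n_controls: int
    means: dict[str, float]
    cov: np.ndarray                      # over GENERATED_ATTRIBUTES, PSD
    center_xy: tuple[float, float]
    disturbance_rate: float = 0.2

    def __post_init__(self) -> None:
        self.cov = np.asarray(self.cov, dtype=float)
        if self.n_controls < 0:
            raise ValueError("control count must be non-negative")
        if not np.allclose(self.cov, self.cov.T):
            raise ValueError("covariance must be symmetric")
        if np.linalg.eigvalsh(self.cov).min() < -1e-8 * np.abs(self.cov).max():
            raise ValueError("covariance must be positive semi-definite")


@dataclass
class BehaviorSpec:
    """Selection function for one behavior type."""

    used_counts: dict[str, int]          # region -> baseline used-location count
    beta: dict[str, float]               # attribute (z-scale) -> selection coefficient


@dataclass
class SyntheticTruth:
    """Generating settings and coefficients behind a simulated dataset."""

    regions: dict[str, RegionSpec]
    behaviors: dict[str, BehaviorSpec]
    random_intercept_sd: float = 1.0
    missingness_rate: float = 0.02
    seed: int = 0
    close_pair_fraction: float = 0.1     # fraction of used points forced within the merge threshold
    pool_factor: int = 12                # availability pool size per used location

    def __post_init__(self) -> None:
        for b, spec in self.behaviors.items():
            for attr in spec.beta:
                if attr != "disturbance_presence" and attr not in GENERATED_ATTRIBUTES:
                    raise ValueError(f"behavior {b!r} has beta for unknown attribute {attr!r}")
            for region in spec.used_counts:
                if region not in self.regions:
                    raise ValueError(f"behavior {b!r} references unknown region {region!r}")
            if any(n < 0 for n in spec.used_counts.values()):
                raise ValueError("used counts must be non-negative")

    # -- default configurations -------------------------------------------

    @classmethod
    def study_default(
        cls,
        seed: int = 0,
        random_intercept_sd: float = 1.0,
        missingness_rate: float = 0.02,
    ) -> "SyntheticTruth":
        """Study-shaped truth: three Great Basin regions with the field
        study's control pools (212 / 81 / 53) and per-region behavior
        counts (caching 12/32/26, foraging 0/19/22, nesting 12/0/28,
        roosting 3 in one region)."""
        cov = default_covariance()
        means = default_attribute_means()
        regions = {
            "eastern_nevada": RegionSpec(212, {**means, "elevation": 2100.0}, cov, (0.0, 0.0)),
            "southern_idaho": RegionSpec(81, {**means, "elevation": 1750.0}, cov, (150_000.0, 0.0)),
            "central_nevada": RegionSpec(53, {**means, "elevation": 2000.0}, cov, (300_000.0, 0.0)),
        }
        behaviors = {
            "caching": BehaviorSpec(
                used_counts={"eastern_nevada": 12, "southern_idaho": 32, "central_nevada": 26},
                beta={
                    "elevation": -0.4, "slope": -1.0, "tree_cover": -0.6,
                    "distance_to_road": -0.8, "disturbance_presence": 1.0,
                },
            ),
            "foraging": BehaviorSpec(
                used_counts={"southern_idaho": 19, "central_nevada": 22},
                beta={"slope": -0.6, "grass_cover": -0.5, "distance_to_road": -0.5},
            ),
            "nesting": BehaviorSpec(
                used_counts={"eastern_nevada": 12, "central_nevada": 28},
                beta={"elevation": -0.8, "forb_cover": -0.7, "tree_cover": 0.3},
            ),
            "roosting": BehaviorSpec(
                used_counts={"eastern_nevada": 3},
                beta={"elevation": -0.5},
            ),
        }
        return cls(
            regions=regions,
            behaviors=behaviors,
            random_intercept_sd=random_intercept_sd,
            missingness_rate=missingness_rate,
            seed=seed,
        )

    @classmethod
    def recovery_default(
        cls,
        beta: Mapping[str, float] | None = None,
        n_controls_per_region: int = 550,
        n_used_per_region: int = 120,
        random_intercept_sd: float = 0.5,
        seed: int = 0,
    ) -> "SyntheticTruth":
        """Clean three-region truth (~2,000 records) for parameter-recovery
        simulations: no missingness, known β on five attributes."""
        if beta is None:
            beta = {
                "elevation": -0.8, "slope": -0.5, "tree_cover": 0.7,
                "grass_cover": 0.0, "distance_to_road": -1.0,
            }
        cov = default_covariance()
        means = default_attribute_means()
        regions = {
            name: RegionSpec(n_controls_per_region, {**means, "elevation": elev}, cov, (x, 0.0))
            for name, elev, x in (
                ("eastern_nevada", 2100.0, 0.0),
                ("southern_idaho", 1750.0, 150_000.0),
                ("central_nevada", 2000.0, 300_000.0),
            )
        }
        behaviors = {
            "caching": BehaviorSpec(
                used_counts={r: n_used_per_region for r in regions},
                beta=dict(beta),
            )
        }
        return cls(
            regions=regions,
            behaviors=behaviors,
            random_intercept_sd=random_intercept_sd,
            missingness_rate=0.0,
            seed=seed,
        )

    @classmethod
    def recovery_pair(
        cls,
        beta: Mapping[str, float] | None = None,
        n_controls_per_region: int = 550,
        n_used_per_region: int = 120,
        random_intercept_sd: float = 0.5,
        seed: int = 0,
    ) -> "SyntheticTruth":
        """Like :meth:`recovery_default` but with a second, null-selection
        behavior alongside the focal one, so the permutation allocation
        actually partitions the control pool (and the null behavior doubles
        as a calibration check)."""
        truth = cls.recovery_default(
            beta=beta,
            n_controls_per_region=n_controls_per_region,
            n_used_per_region=n_used_per_region,
            random_intercept_sd=random_intercept_sd,
            seed=seed,
        )
        focal = truth.behaviors["caching"]
        truth.behaviors["foraging"] = BehaviorSpec(
            used_counts=dict(focal.used_counts),
            beta={a: 0.0 for a in focal.beta},
        )
        return truth


def default_attribute_means() -> dict[str, float]:
    return {
        "elevation": 2000.0, "slope": 15.0, "stand_age": 120.0,
        "stand_density_index": 120.0, "canopy_cover": 25.0, "tree_cover": 30.0,
        "shrub_cover": 20.0, "forb_cover": 6.0, "grass_cover": 12.0,
        "woody_debris_1": 300.0, "woody_debris_2": 200.0, "woody_debris_3": 120.0,
        "woody_debris_4": 40.0, "woody_debris_5": 15.0, "woody_debris_6": 6.0,
        "woody_debris_7": 2.5, "distance_to_road": 1.5,
    }


def default_attribute_sds() -> dict[str, float]:
    return {
        "elevation": 200.0, "slope": 10.0, "stand_age": 50.0,
        "stand_density_index": 60.0, "canopy_cover": 12.0, "tree_cover": 15.0,
        "shrub_cover": 10.0, "forb_cover": 4.0, "grass_cover": 7.0,
        "woody_debris_1": 150.0, "woody_debris_2": 100.0, "woody_debris_3": 60.0,
        "woody_debris_4": 25.0, "woody_debris_5": 10.0, "woody_debris_6": 5.0,
        "woody_debris_7": 2.0, "distance_to_road": 1.2,
    }


def default_covariance(
    corr_overrides: Mapping[tuple[str, str], float] | None = None,
) -> np.ndarray:
    """Attribute covariance with the correlation structure the study shows:
    tree cover vs stand density index r = 0.68, canopy tied to both,
    age/density along an elevation gradient, and a correlated woody-debris
    block.  Clipped to the nearest PSD matrix if the assembled correlations
    are slightly inconsistent."""
    attrs = list(GENERATED_ATTRIBUTES)
    idx = {a: i for i, a in enumerate(attrs)}
    corr = np.eye(len(attrs))
    pairs: dict[tuple[str, str], float] = {
        ("tree_cover", "stand_density_index"): 0.68,
        ("tree_cover", "canopy_cover"): 0.72,
        ("canopy_cover", "stand_density_index"): 0.50,
        ("stand_age", "tree_cover"): 0.40,
        ("stand_age", "stand_density_index"): 0.35,
        ("elevation", "slope"): 0.35,
        ("elevation", "grass_cover"): -0.30,
        ("tree_cover", "shrub_cover"): -0.35,
        ("shrub_cover", "grass_cover"): 0.30,
    }
    # strongly co-varying debris loads: first PC of the seven classes
    # describes ~86% of their variation, as woodland fuel surveys show
    for i, a in enumerate(WOODY_DEBRIS_ATTRIBUTES):
        for b in WOODY_DEBRIS_ATTRIBUTES[i + 1:]:
            pairs[(a, b)] = 0.84
    for a in ("woody_debris_5", "woody_debris_6", "woody_debris_7"):
        pairs[(a, "stand_age")] = 0.25
    if corr_overrides:
        pairs.update({tuple(k): v for k, v in corr_overrides.items()})
    for (a, b), r in pairs.items():
        corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = r
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() < 1e-8:
        corr = (vecs * np.clip(vals, 1e-8, None)) @ vecs.T
        d = np.sqrt(np.diag(corr))
        corr = corr / np.outer(d, d)
    sds = np.array([default_attribute_sds()[a] for a in attrs])
    return corr * np.outer(sds, sds)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


def _truncate(frame: pd.DataFrame) -> pd.DataFrame:
    for a in COVER_ATTRIBUTES:
        frame[a] = frame[a].clip(0.0, 100.0)
    for a in NONNEGATIVE_ATTRIBUTES:
        frame[a] = frame[a].clip(lower=0.0)
    return frame


def _to_lonlat(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lon = REF_LON + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(REF_LAT))))
    lat = REF_LAT + np.degrees(y / EARTH_RADIUS_M)
    return lon, lat


def _region_sites(
    region: str, spec: RegionSpec, n: int, rng: np.random.Generator, prefix: str
) -> pd.DataFrame:
    """Draw n truncated MVN attribute vectors plus coordinates for one region.

    The north-south coordinate tracks elevation, so low-elevation sites sit
    near the (southern) woodland-shrubland ecotone — selection on elevation
    then produces used locations biased toward the edge.
    """
    mean = np.array([spec.means[a] for a in GENERATED_ATTRIBUTES])
    X = rng.multivariate_normal(mean, spec.cov, size=n)
    frame = pd.DataFrame(X, columns=list(GENERATED_ATTRIBUTES))
    frame = _truncate(frame)
    frame.insert(0, "record_id", [f"{prefix}-{region}-{i:05d}" for i in range(n)])
    frame["region"] = region

    elev = frame["elevation"].to_numpy()
    sd = math.sqrt(spec.cov[0, 0])
    rel = (elev - (spec.means["elevation"] - 2.0 * sd)) / (4.0 * sd)
    cx, cy = spec.center_xy
    x = cx + rng.uniform(-15_000.0, 15_000.0, size=n)
    y = ECOTONE_Y + rel * 20_000.0 + rng.normal(0.0, 1_500.0, size=n)
    frame["x"], frame["y"] = x, y
    frame["disturbance_presence"] = rng.random(n) < spec.disturbance_rate
    frame["habitat_type_code"] = "PJ"
    return frame


ECOTONE_Y = -10_000.0  # planar y of the synthetic woodland-shrubland ecotone


def make_ecotone(x_min: float = -60_000.0, x_max: float = 460_000.0) -> EcotoneLine:
    """Gently kinked west-east ecotone; woodland is the north (left) side."""
    xs = np.linspace(x_min, x_max, 9)
    ys = ECOTONE_Y + 1_200.0 * np.sin(np.linspace(0.0, 2.5 * np.pi, 9))
    return EcotoneLine(np.column_stack([xs, ys]), woodland_side="left")


def _inject_missing(
    frame: pd.DataFrame, rate: float, rng: np.random.Generator
) -> pd.DataFrame:
    if rate <= 0:
        return frame
    for a in GENERATED_ATTRIBUTES:
        mask = rng.random(len(frame)) < rate
        frame.loc[mask, a] = np.nan
    return frame


def generate_controls(
    truth: SyntheticTruth, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Control plots for every region, with missing cells injected."""
    rng = rng if rng is not None else np.random.default_rng(truth.seed)
    parts = [
        _region_sites(region, spec, spec.n_controls, rng, prefix="C")
        for region, spec in truth.regions.items()
    ]
    frame = pd.concat(parts, ignore_index=True)
    frame["role"] = "control"
    frame["behavior"] = "none"
    return _inject_missing(frame, truth.missingness_rate, rng)


def generate_availability_pool(
    truth: SyntheticTruth, behavior: str, rng: np.random.Generator
) -> pd.DataFrame:
    """Large control-like sample the used locations are selected from."""
    spec = truth.behaviors[behavior]
    parts = []
    # intercept heterogeneity can shift the whole behavior total into one
    # region, so each region's pool is sized for the total
    total = sum(spec.used_counts.values())
    for region, n_used in spec.used_counts.items():
        if n_used == 0:
            continue
        n_pool = max(truth.pool_factor * total, 100)
        parts.append(_region_sites(region, truth.regions[region], n_pool, rng, prefix=f"P{behavior[:2]}"))
    if not parts:
        return pd.DataFrame(columns=["record_id", "region", *GENERATED_ATTRIBUTES])
    return pd.concat(parts, ignore_index=True)


def generate_used_locations(
    truth: SyntheticTruth,
    behavior: str,
    availability_pool: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Sample used locations from the pool with weight exp(u_r + β'z(x)).

    ``z`` standardizes each attribute by the pool's own mean and sd
    (binary disturbance enters raw), so the generating β is on the same
    z-scale the inference model estimates.  Sampling is without
    replacement (Efraimidis-Spirakis exponential-key method).  Region
    intercepts ``u_r ~ N(0, σ²)`` redistribute the behavior's total count
    across regions (multinomial over baseline shares × exp(u_r)); with
    σ = 0 the configured counts are used exactly.  A controllable fraction
    of the sampled points is nudged within the plot-overlap merge
    threshold of a neighbor to exercise spatial averaging.
    """
    spec = truth.behaviors[behavior]
    regions = [r for r, n in spec.used_counts.items() if n > 0]
    if not regions:
        return availability_pool.iloc[:0].copy()

    # z-scale from the pool (pooled across regions)
    beta_attrs = [a for a in spec.beta if a != "disturbance_presence"]
    stats = {
        a: (float(availability_pool[a].mean()), float(availability_pool[a].std(ddof=1)))
        for a in beta_attrs
    }

    total = sum(spec.used_counts[r] for r in regions)
    sigma = truth.random_intercept_sd
    u = {r: (rng.normal(0.0, sigma) if sigma > 0 else 0.0) for r in regions}
    if sigma > 0:
        shares = np.array([spec.used_counts[r] * math.exp(u[r]) for r in regions], dtype=float)
        counts = rng.multinomial(total, shares / shares.sum())
        n_by_region = {r: int(c) for r, c in zip(regions, counts)}
    else:
        n_by_region = {r: spec.used_counts[r] for r in regions}

    picks = []
    for r in regions:
        n_r = n_by_region[r]
        if n_r == 0:
            continue
        pool_r = availability_pool[availability_pool["region"] == r]
        if len(pool_r) < 10 * n_r:
            raise ValueError(
                f"availability pool for region {r!r} ({len(pool_r)}) is below "
                f"10x the requested used count ({n_r})"
            )
        logw = np.full(len(pool_r), u[r])
        for a in beta_attrs:
            mean, sd = stats[a]
            logw = logw + spec.beta[a] * ((pool_r[a].to_numpy() - mean) / sd)
        if "disturbance_presence" in spec.beta:
            logw = logw + spec.beta["disturbance_presence"] * pool_r["disturbance_presence"].to_numpy(float)
        if not np.any(np.isfinite(logw)):
            raise ValueError("degenerate selection weights (all zero)")
        keys = logw + rng.gumbel(size=len(pool_r))
        chosen = pool_r.iloc[np.argsort(-keys)[:n_r]].copy()
        picks.append(chosen)

    used = pd.concat(picks, ignore_index=True) if picks else availability_pool.iloc[:0].copy()
    used["role"] = "used"
    used["behavior"] = behavior
    used["record_id"] = [f"U-{behavior}-{i:04d}" for i in range(len(used))]

    # coordinate jitter + forced close pairs (exercises the merge step)
    n = len(used)
    if n:
        used["x"] = used["x"].to_numpy() + rng.normal(0.0, 300.0, size=n)
        used["y"] = used["y"].to_numpy() + rng.normal(0.0, 300.0, size=n)
        threshold = plot_overlap_threshold()
        n_close = int(truth.close_pair_fraction * n / 2)
        for region in used["region"].unique():
            ridx = used.index[used["region"] == region].to_numpy()
            for j in range(min(n_close, len(ridx) // 2)):
                a, b = ridx[2 * j], ridx[2 * j + 1]
                angle = rng.uniform(0.0, 2.0 * np.pi)
                d = rng.uniform(0.2, 0.8) * threshold
                used.loc[b, "x"] = used.loc[a, "x"] + d * math.cos(angle)
                used.loc[b, "y"] = used.loc[a, "y"] + d * math.sin(angle)
    return used


@dataclass
class SyntheticStudy:
    """A generated dataset plus the truth that produced it."""

    dataset: AnalysisDataset
    ecotone: EcotoneLine
    truth: SyntheticTruth


def generate_study(truth: SyntheticTruth) -> SyntheticStudy:
    """Full reproducible dataset: controls, all behaviors' used locations,
    signed distance to a synthetic ecotone, pseudo lon/lat coordinates."""
    rng = np.random.default_rng(truth.seed)
    controls = generate_controls(truth, rng)
    parts = [controls]
    for behavior in truth.behaviors:
        pool = generate_availability_pool(truth, behavior, rng)
        if len(pool) == 0:
            continue
        used = generate_used_locations(truth, behavior, pool, rng)
        used = _inject_missing(used, truth.missingness_rate, rng)
        parts.append(used)
    frame = pd.concat(parts, ignore_index=True)

    ecotone = make_ecotone()
    xy = frame[["x", "y"]].to_numpy(dtype=float)
    frame["distance_to_edge"] = distances_to_edge(xy, ecotone)
    lon, lat = _to_lonlat(frame["x"].to_numpy(), frame["y"].to_numpy())
    frame["longitude"], frame["latitude"] = lon, lat

    # emit elevation in feet, as an FIA-style export would carry it
    frame["elevation"] = frame["elevation"] / FEET_TO_METERS

    frame = frame[[c for c in ALL_COLUMNS if c in frame.columns] + ["x", "y"]]
    ds = AnalysisDataset(frame=frame.reset_index(drop=True))
    ds.log(
        f"generate_study: seed={truth.seed}, {len(controls)} controls, "
        f"{len(frame) - len(controls)} used locations, sigma={truth.random_intercept_sd}"
    )
    return SyntheticStudy(dataset=ds, ecotone=ecotone, truth=truth)
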