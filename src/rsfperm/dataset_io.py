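"""Reading, validation, and unit normalization of site tables.

A *site table* is a flat delimited or spreadsheet table with one row per
used location or control plot.  Each row carries a role (``used`` or
``control``), a behavior type for used locations, a study region,
coordinates, and the forest-inventory habitat attributes (elevation, slope,
stand age, cover percentages, seven woody-debris size-class counts,
distance-to-road, disturbance presence, ...).  This module turns such a
table into the validated in-memory :class:`AnalysisDataset` that the rest
of the pipeline consumes, converts imperial/ordinal fields to metric, and
produces validation reports.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely.wkt
from shapely.geometry import LineString

# ---------------------------------------------------------------------------
# Vocabularies and attribute registry
# ---------------------------------------------------------------------------

DEFAULT_BEHAVIORS: tuple[str, ...] = ("caching", "foraging", "nesting", "roosting")
DEFAULT_REGIONS: tuple[str, ...] = ("eastern_nevada", "southern_idaho", "central_nevada")

#: Behavior label carried by control plots (which have no behavior).
NO_BEHAVIOR = "none"

WOODY_DEBRIS_ATTRIBUTES: tuple[str, ...] = tuple(f"woody_debris_{i}" for i in range(1, 8))

#: Continuous habitat attributes, in canonical column order.
CONTINUOUS_ATTRIBUTES: tuple[str, ...] = (
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
    "distance_to_edge",
)

COVER_ATTRIBUTES: tuple[str, ...] = (
    "canopy_cover",
    "tree_cover",
    "shrub_cover",
    "forb_cover",
    "grass_cover",
)

STRUCTURAL_COLUMNS: tuple[str, ...] = (
    "record_id",
    "role",
    "behavior",
    "region",
    "latitude",
    "longitude",
)

ALL_COLUMNS: tuple[str, ...] = (
    *STRUCTURAL_COLUMNS,
    *CONTINUOUS_ATTRIBUTES,
    "disturbance_presence",
    "habitat_type_code",
)

#: Default units per attribute as they arrive from an FIA-style export.
#: ``ft`` elevations and ordinal ``class`` road distances are converted by
#: :func:`convert_units`; everything else is already metric / percent / count.
DEFAULT_UNITS: dict[str, str] = {
    "elevation": "ft",
    "slope": "percent",
    "stand_age": "years",
    "stand_density_index": "index",
    "canopy_cover": "percent",
    "tree_cover": "percent",
    "shrub_cover": "percent",
    "forb_cover": "percent",
    "grass_cover": "percent",
    **{a: "count" for a in WOODY_DEBRIS_ATTRIBUTES},
    "distance_to_road": "km",
    "distance_to_edge": "m",
}

FEET_TO_METERS = 0.3048

#: Example ordinal-class → midpoint-km map for FIA-style distance-to-road
#: codes (classes bounded in feet/miles; open top class uses 1.5x its lower
#: bound).  Real deployments supply their own map; this one is shipped so the
#: conversion path is testable.
EXAMPLE_ROAD_CLASS_MIDPOINTS_KM: dict[str, float] = {
    "1": 50 * FEET_TO_METERS / 1000,        # <= 100 ft
    "2": 200 * FEET_TO_METERS / 1000,       # 101-300 ft
    "3": 400 * FEET_TO_METERS / 1000,       # 301-500 ft
    "4": 750 * FEET_TO_METERS / 1000,       # 501-1000 ft
    "5": 1820 * FEET_TO_METERS / 1000,      # 1001-2640 ft
    "6": 0.75 * 1.609344,                   # 0.5-1 mi
    "7": 2.0 * 1.609344,                    # 1-3 mi
    "8": 4.0 * 1.609344,                    # 3-5 mi
    "9": 7.5 * 1.609344,                    # > 5 mi (open class)
}


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SiteRecord:
    """One used location or control plot."""

    record_id: str
    role: str
    behavior: str
    region: str
    latitude: float
    longitude: float
    attributes: dict[str, float] = field(default_factory=dict)
    disturbance_presence: bool | None = None
    habitat_type_code: str | None = None


@dataclass
class ValidationIssue:
    record_id: str
    field: str
    message: str


@dataclass
class ReadReport:
    """Row-level problems found while reading a site table."""

    n_read: int = 0
    n_accepted: int = 0
    rejected: list[ValidationIssue] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len({issue.record_id for issue in self.rejected})


@dataclass
class ValidationReport:
    """Report-only summary produced by :func:`validate_dataset`."""

    group_counts: pd.DataFrame          # region x behavior used-location counts
    control_counts: pd.Series           # per-region control counts
    flagged_behaviors: list[str]        # used-location count < min_group_size
    missingness: pd.Series              # per-attribute missing fraction
    min_group_size: int

    def to_frame(self) -> pd.DataFrame:
        out = self.group_counts.copy()
        out["control"] = self.control_counts.reindex(out.index).fillna(0).astype(int)
        return out


@dataclass
class AnalysisDataset:
    """Validated collection of site records plus attribute metadata.

    ``frame`` holds one row per record with the canonical columns; the
    ``registry`` maps each continuous attribute to its current unit so unit
    conversion is idempotent; ``scaling`` stores per-attribute (mean, sd)
    once z-transformation has been applied; ``provenance`` is the ordered
    log of processing steps applied so far.
    """

    frame: pd.DataFrame
    registry: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_UNITS))
    scaling: dict[str, tuple[float, float]] = field(default_factory=dict)
    provenance: list[str] = field(default_factory=list)
    composites: dict[str, dict] = field(default_factory=dict)
    read_report: ReadReport | None = None

    def __post_init__(self) -> None:
        ids = self.frame["record_id"]
        if ids.duplicated().any():
            dupes = ids[ids.duplicated()].unique()[:5]
            raise ValueError(f"duplicate record_ids: {list(dupes)}")

    def copy(self) -> "AnalysisDataset":
        return AnalysisDataset(
            frame=self.frame.copy(),
            registry=dict(self.registry),
            scaling=dict(self.scaling),
            provenance=list(self.provenance),
            composites={k: dict(v) for k, v in self.composites.items()},
            read_report=self.read_report,
        )

    def log(self, message: str) -> None:
        self.provenance.append(message)

    @property
    def n_records(self) -> int:
        return len(self.frame)

    def used(self, behavior: str | None = None) -> pd.DataFrame:
        mask = self.frame["role"] == "used"
        if behavior is not None:
            mask &= self.frame["behavior"] == behavior
        return self.frame[mask]

    def controls(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "control"]

    def records(self) -> Iterable[SiteRecord]:
        attr_cols = [c for c in CONTINUOUS_ATTRIBUTES if c in self.frame.columns]
        for _, row in self.frame.iterrows():
            yield SiteRecord(
                record_id=row["record_id"],
                role=row["role"],
                behavior=row["behavior"],
                region=row["region"],
                latitude=row["latitude"],
                longitude=row["longitude"],
                attributes={c: row[c] for c in attr_cols},
                disturbance_presence=(
                    None if pd.isna(row.get("disturbance_presence")) else bool(row["disturbance_presence"])
                ),
                habitat_type_code=row.get("habitat_type_code"),
            )


@dataclass
class EcotoneLine:
    """Woodland-shrubland ecotone as a projected polyline.

    ``woodland_side`` declares which side of the directed vertex sequence is
    woodland ("left" or "right"); signed distances are positive on the
    woodland side and negative on the shrubland side.
    """

    vertices: np.ndarray
    woodland_side: str = "left"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError("ecotone line needs >= 2 planar (x, y) vertices")
        if np.any(np.all(np.diff(self.vertices, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive ecotone vertices must be distinct")
        if self.woodland_side not in ("left", "right"):
            raise ValueError("woodland_side must be 'left' or 'right'")

    def as_linestring(self) -> LineString:
        return LineString(self.vertices)

    def reversed(self) -> "EcotoneLine":
        side = "right" if self.woodland_side == "left" else "left"
        return EcotoneLine(self.vertices[::-1].copy(), woodland_side=side)


# ---------------------------------------------------------------------------
# Reading
# ---------------------------------------------------------------------------


def _coerce_bool(value) -> bool | float:
    if pd.isna(value):
        return np.nan
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise ValueError(f"unparseable yes/no value {value!r}")


def read_site_table(
    path: str | Path,
    dialect: str | None = None,
    column_map: Mapping[str, str] | None = None,
    behaviors: Sequence[str] = DEFAULT_BEHAVIORS,
    regions: Sequence[str] = DEFAULT_REGIONS,
    units: Mapping[str, str] | None = None,
) -> AnalysisDataset:
    """Read a site table into an :class:`AnalysisDataset` of raw values.

    Parameters
    ----------
    path:
        Delimited text (comma or tab, sniffed) or a spreadsheet workbook
        with one header row.
    dialect:
        ``"delimited"`` or ``"spreadsheet"``; inferred from the file suffix
        when omitted.
    column_map:
        Optional ``{file column -> canonical column}`` renaming.
    behaviors, regions:
        Accepted vocabulary; rows with labels outside it are rejected and
        listed in ``dataset.read_report`` rather than raising.
    units:
        Per-attribute unit overrides (e.g. ``{"elevation": "m"}`` when the
        table is already metric, or ``{"distance_to_road": "class"}`` for
        ordinal road-distance codes).

    Missing attribute cells are preserved as missing; rows whose role,
    behavior, or region cannot be interpreted are excluded with reasons.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "spreadsheet" if path.suffix.lower() in (".xlsx", ".xls", ".xlsm") else "delimited"
    if dialect == "spreadsheet":
        raw = pd.read_excel(path)
    elif dialect == "delimited":
        raw = pd.read_csv(path, sep=None, engine="python")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if column_map:
        raw = raw.rename(columns=dict(column_map))
    raw.columns = [str(c).strip() for c in raw.columns]

    required = {"record_id", "role", "region"}
    missing_cols = required - set(raw.columns)
    if missing_cols:
        raise ValueError(f"site table lacks required columns: {sorted(missing_cols)}")

    report = ReadReport(n_read=len(raw))
    behaviors = tuple(behaviors)
    regions = tuple(regions)
    ok_rows: list[dict] = []

    for i, row in raw.iterrows():
        rid = str(row["record_id"]) if not pd.isna(row["record_id"]) else f"<row {i}>"
        issues: list[ValidationIssue] = []

        role = str(row["role"]).strip().lower() if not pd.isna(row["role"]) else ""
        if role not in ("used", "control"):
            issues.append(ValidationIssue(rid, "role", f"unknown role {row['role']!r}"))

        behavior = row.get("behavior")
        behavior = str(behavior).strip().lower() if not pd.isna(behavior) else NO_BEHAVIOR
        if role == "control" and behavior != NO_BEHAVIOR:
            issues.append(ValidationIssue(rid, "behavior", f"control plot carries behavior {behavior!r}"))
        elif role == "used" and behavior == NO_BEHAVIOR:
            issues.append(ValidationIssue(rid, "behavior", "used location lacks a behavior"))
        elif behavior != NO_BEHAVIOR and behavior not in behaviors:
            issues.append(ValidationIssue(rid, "behavior", f"unknown behavior {behavior!r}"))

        region = str(row["region"]).strip().lower() if not pd.isna(row["region"]) else ""
        if region not in regions:
            issues.append(ValidationIssue(rid, "region", f"unknown region {row['region']!r}"))

        rec: dict = {
            "record_id": rid,
            "role": role,
            "behavior": behavior,
            "region": region,
            "latitude": pd.to_numeric(row.get("latitude"), errors="coerce"),
            "longitude": pd.to_numeric(row.get("longitude"), errors="coerce"),
            "habitat_type_code": None if pd.isna(row.get("habitat_type_code")) else str(row["habitat_type_code"]),
        }

        try:
            rec["disturbance_presence"] = _coerce_bool(row.get("disturbance_presence"))
        except ValueError as exc:
            issues.append(ValidationIssue(rid, "disturbance_presence", str(exc)))

        road_is_class = units is not None and units.get("distance_to_road") == "class"
        for attr in CONTINUOUS_ATTRIBUTES:
            value = row.get(attr)
            if attr == "distance_to_road" and road_is_class and not pd.isna(value):
                # ordinal class codes are carried as strings until convert_units
                rec[attr] = value
                continue
            value = pd.to_numeric(value, errors="coerce")
            if not pd.isna(value):
                if attr in COVER_ATTRIBUTES and not (0.0 <= value <= 100.0):
                    issues.append(ValidationIssue(rid, attr, f"cover percentage {value} outside [0, 100]"))
                if attr in WOODY_DEBRIS_ATTRIBUTES and value < 0:
                    issues.append(ValidationIssue(rid, attr, f"negative debris count {value}"))
            rec[attr] = value

        if issues:
            report.rejected.extend(issues)
        else:
            ok_rows.append(rec)

    report.n_accepted = len(ok_rows)
    frame = pd.DataFrame(ok_rows, columns=list(ALL_COLUMNS))
    registry = dict(DEFAULT_UNITS)
    if units:
        registry.update(units)
    ds = AnalysisDataset(frame=frame, registry=registry, read_report=report)
    ds.log(
        f"read_site_table: {report.n_read} rows read, {report.n_accepted} accepted, "
        f"{report.n_rejected} rejected from {path.name}"
    )
    return ds


def write_site_table(dataset: AnalysisDataset, path: str | Path) -> None:
    """Write the dataset back out as delimited text (round-trip safe)."""
    path = Path(path)
    frame = dataset.frame.copy()
    frame.to_csv(path, sep="\t", index=False)


def read_ecotone(path: str | Path, woodland_side: str = "left") -> EcotoneLine:
    """Read ecotone geometry from WKT (``LINESTRING``) or a two-column x,y table."""
    path = Path(path)
    text = path.read_text().strip()
    if text.upper().startswith("LINESTRING"):
        geom = shapely.wkt.loads(text)
        return EcotoneLine(np.asarray(geom.coords, dtype=float), woodland_side=woodland_side)
    table = pd.read_csv(path, sep=None, engine="python")
    if table.shape[1] < 2:
        raise ValueError("vertex table needs two columns (x, y in meters)")
    return EcotoneLine(table.iloc[:, :2].to_numpy(dtype=float), woodland_side=woodland_side)


# ---------------------------------------------------------------------------
# Unit conversion and validation
# ---------------------------------------------------------------------------


def convert_units(
    dataset: AnalysisDataset,
    road_class_map: Mapping[str, float] | None = None,
) -> AnalysisDataset:
    """Convert attributes to metric units; idempotent.

    Elevation flagged as feet is multiplied by 0.3048; an ordinal
    distance-to-road class is replaced by its class-midpoint km per
    ``road_class_map``.  Attributes already metric are untouched, so running
    the conversion twice is a no-op.
    """
    ds = dataset.copy()
    steps: list[str] = []

    if ds.registry.get("elevation") == "ft":
        ds.frame["elevation"] = pd.to_numeric(ds.frame["elevation"], errors="coerce") * FEET_TO_METERS
        ds.registry["elevation"] = "m"
        steps.append("elevation ft -> m (x0.3048)")

    if ds.registry.get("distance_to_road") == "class":
        cmap = {str(k): float(v) for k, v in (road_class_map or EXAMPLE_ROAD_CLASS_MIDPOINTS_KM).items()}
        raw = ds.frame["distance_to_road"]

        def to_midpoint(value):
            if pd.isna(value):
                return np.nan
            key = str(value).strip()
            if key.endswith(".0"):  # numeric codes read as floats
                key = key[:-2]
            if key not in cmap:
                raise KeyError(f"unknown distance-to-road class {value!r}")
            return cmap[key]

        errors: list[str] = []
        converted = []
        for rid, value in zip(ds.frame["record_id"], raw):
            try:
                converted.append(to_midpoint(value))
            except KeyError as exc:
                errors.append(f"{rid}: {exc.args[0]}")
                converted.append(np.nan)
        ds.frame["distance_to_road"] = converted
        ds.registry["distance_to_road"] = "km"
        steps.append("distance_to_road ordinal class -> midpoint km")
        if errors:
            steps.append(f"distance_to_road: {len(errors)} unknown class codes set missing")
            warnings.warn(f"unknown road classes for {len(errors)} records", stacklevel=2)

    if steps:
        ds.log("convert_units: " + "; ".join(steps))
    else:
        ds.log("convert_units: no-op (all attributes already metric)")
    return ds


def validate_dataset(dataset: AnalysisDataset, min_group_size: int = 5) -> ValidationReport:
    """Report per-region x behavior counts, missingness, and small groups.

    Behavior types with a total used-location count below ``min_group_size``
    are flagged for exclusion (the study's roosting class, n = 3, is the
    motivating case).  Report-only: the dataset is never mutated.
    """
    frame = dataset.frame
    used = frame[frame["role"] == "used"]
    counts = (
        used.pivot_table(index="region", columns="behavior", values="record_id", aggfunc="count")
        .fillna(0)
        .astype(int)
    )
    control_counts = frame[frame["role"] == "control"].groupby("region")["record_id"].count()
    totals = used.groupby("behavior")["record_id"].count()
    flagged = sorted(b for b, n in totals.items() if n < min_group_size)

    attrs = [c for c in CONTINUOUS_ATTRIBUTES if c in frame.columns]
    if len(frame):
        missingness = frame[attrs].isna().mean()
    else:
        missingness = pd.Series(0.0, index=attrs)

    return ValidationReport(
        group_counts=counts,
        control_counts=control_counts,
        flagged_behaviors=flagged,
        missingness=missingness,
        min_group_size=min_group_size,
    )
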