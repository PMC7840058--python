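"""Configured end-to-end pipeline.

Stages, in order: read -> unit conversion -> validation -> spatial
averaging of used locations -> collinearity screen -> woody-debris
collapse -> pooled z-transformation -> PCA ordination -> per-behavior
permutation inference -> box-plot summaries.  All stage record counts are
logged so the filtering trail is auditable, and every output table carries
the run seed and a configuration hash.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from rsfperm import dataset_io, inference, ordination, preprocess, report
from rsfperm.dataset_io import AnalysisDataset, EcotoneLine, WOODY_DEBRIS_ATTRIBUTES
from rsfperm.simulate import SyntheticTruth, generate_study

#: Attributes entering the ordination (the woody-debris size classes stay
#: separate there; the derived stand-density index is excluded).
DEFAULT_ORDINATION_ATTRIBUTES: tuple[str, ...] = (
    "elevation",
    "slope",
    "stand_age",
    "canopy_cover",
    "tree_cover",
    "shrub_cover",
    "forb_cover",
    "grass_cover",
    *WOODY_DEBRIS_ATTRIBUTES,
    "distance_to_road",
)

#: Candidates for the collinearity screen ahead of the regression.
DEFAULT_SCREEN_CANDIDATES: tuple[str, ...] = (
    "elevation",
    "slope",
    "stand_age",
    "stand_density_index",
    "canopy_cover",
    "tree_cover",
    "shrub_cover",
    "forb_cover",
    "grass_cover",
    "distance_to_road",
)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on; a pure function of this and
    the input files."""

    site_table: str | None = None
    dialect: str | None = None
    column_map: dict = dataclass_field(default_factory=dict)
    units: dict = dataclass_field(default_factory=dict)
    road_class_map: dict | None = None
    ecotone: str | None = None
    ecotone_woodland_side: str = "left"

    synthetic: bool = False
    synthetic_sigma: float = 1.0
    synthetic_missingness: float = 0.02

    merge: bool = True
    merge_threshold_m: float | None = None
    corr_threshold: float = 0.65
    screen_candidates: tuple[str, ...] = DEFAULT_SCREEN_CANDIDATES
    screen_priority: tuple[str, ...] | None = None
    min_group_size: int = 5

    ordination_attributes: tuple[str, ...] = DEFAULT_ORDINATION_ATTRIBUTES
    behaviors: tuple[str, ...] = ("caching", "foraging", "nesting")
    fixed_attrs: tuple[str, ...] | None = None
    n_perm: int = 1000
    seed: int = 0
    out_dir: str = "rsf_out"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("screen_candidates", "screen_priority", "ordination_attributes", "behaviors", "fixed_attrs"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


@dataclass
class PipelineResult:
    dataset: AnalysisDataset
    validation: dataset_io.ValidationReport
    screen: preprocess.AttributeScreen
    woody_debris_fraction: float
    ordination: ordination.OrdinationResult
    centroids: pd.DataFrame
    inference: dict[str, inference.PooledInference]
    boxplots: pd.DataFrame
    merge: preprocess.MergeResult | None
    out_dir: Path | None


def _load_dataset(config: RunConfig) -> tuple[AnalysisDataset, EcotoneLine | None]:
    if config.synthetic:
        study = generate_study(
            SyntheticTruth.study_default(
                seed=config.seed,
                random_intercept_sd=config.synthetic_sigma,
                missingness_rate=config.synthetic_missingness,
            )
        )
        return study.dataset, study.ecotone
    if not config.site_table:
        raise ValueError("config needs either a site_table path or synthetic: true")
    ds = dataset_io.read_site_table(
        config.site_table,
        dialect=config.dialect,
        column_map=config.column_map or None,
        units=config.units or None,
    )
    eco = (
        dataset_io.read_ecotone(config.ecotone, woodland_side=config.ecotone_woodland_side)
        if config.ecotone
        else None
    )
    return ds, eco


def _apply_merge(ds: AnalysisDataset, threshold_m: float | None) -> tuple[AnalysisDataset, preprocess.MergeResult]:
    """Spatially average near-duplicate used locations, averaging their
    habitat attributes alongside the coordinates."""
    used = ds.used().copy()
    if {"x", "y"}.issubset(ds.frame.columns):
        cols = ["record_id", "behavior", "region", "x", "y"]
    else:
        cols = ["record_id", "behavior", "region", "longitude", "latitude"]
    result = preprocess.merge_close_locations(used[cols], threshold_m=threshold_m)

    merged_frames = []
    numeric = [c for c in dataset_io.CONTINUOUS_ATTRIBUTES if c in ds.frame.columns]
    by_id = used.set_index("record_id")
    for row in result.merged_records.itertuples():
        sources = by_id.loc[list(row.source_ids)]
        rep = sources.iloc[0].copy()
        rep[numeric] = sources[numeric].mean()
        rep["disturbance_presence"] = bool(sources["disturbance_presence"].any())
        rep["latitude"] = sources["latitude"].mean()
        rep["longitude"] = sources["longitude"].mean()
        if "x" in used.columns:
            rep["x"], rep["y"] = row.x, row.y
        rep = rep.to_frame().T
        rep.insert(0, "record_id", row.record_id)
        merged_frames.append(rep)

    out = ds.copy()
    merged_used = pd.concat(merged_frames, ignore_index=True) if merged_frames else used.iloc[:0]
    controls = ds.controls()
    out.frame = pd.concat([merged_used[ds.frame.columns], controls], ignore_index=True)
    for col in numeric + ["latitude", "longitude"]:
        out.frame[col] = pd.to_numeric(out.frame[col], errors="coerce")
    out.log(
        f"merge_close_locations: {len(used)} used locations -> {len(merged_used)} "
        f"at threshold {result.threshold_m:.1f} m"
    )
    return out, result


def run_pipeline(config: RunConfig | Mapping | str | Path, write: bool = True) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Outputs (when ``write``): validation report, provenance log, PCA
    loadings/variance/scores/centroids, one inference table and pooled-draw
    archive per behavior, box-plot quantile table, and a run log with
    retained/discarded permutation counts.
    """
    if isinstance(config, (str, Path)):
        config = RunConfig.from_yaml(config)
    elif isinstance(config, Mapping):
        config = RunConfig(**dict(config))

    # hash the analytic configuration only: where outputs land must not
    # change what they contain
    cfg_hash = report.config_hash({k: v for k, v in config.as_dict().items() if k != "out_dir"})
    ds, _eco = _load_dataset(config)

    ds = dataset_io.convert_units(ds, road_class_map=config.road_class_map)
    validation = dataset_io.validate_dataset(ds, min_group_size=config.min_group_size)

    known = set(ds.frame.loc[ds.frame["role"] == "used", "behavior"].unique())
    unknown = [b for b in config.behaviors if b not in known]
    if unknown:
        raise ValueError(
            f"configured behavior(s) {unknown} have no used locations in the dataset"
        )
    behaviors = [b for b in config.behaviors if b not in validation.flagged_behaviors]
    for b in config.behaviors:
        if b in validation.flagged_behaviors:
            ds.log(
                f"validate_dataset: behavior '{b}' excluded "
                f"(n < {config.min_group_size})"
            )

    merge_result = None
    if config.merge:
        ds, merge_result = _apply_merge(ds, config.merge_threshold_m)

    screen = preprocess.screen_attributes(
        ds, list(config.screen_candidates),
        corr_threshold=config.corr_threshold,
        priority=config.screen_priority,
    )
    ds.log(f"screen_attributes: retained {screen.retained}; dropped {screen.dropped}")

    ds, wd_fraction = preprocess.collapse_woody_debris(ds)

    ord_attrs = [a for a in config.ordination_attributes if a in ds.frame.columns]
    if config.fixed_attrs is not None:
        fixed_attrs = list(config.fixed_attrs)
    else:
        fixed_attrs = [a for a in screen.retained if a != "distance_to_edge"]
        fixed_attrs.append("woody_debris")
        if ds.frame["disturbance_presence"].notna().any():
            fixed_attrs.append("disturbance_presence")
    to_standardize = sorted(
        (set(ord_attrs) | set(fixed_attrs)) - {"disturbance_presence"},
        key=lambda a: (ord_attrs + fixed_attrs).index(a),
    )
    ds = preprocess.standardize(ds, to_standardize)
    ds.frame["disturbance_presence"] = ds.frame["disturbance_presence"].astype(float)

    include = (ds.frame["role"] == "control") | (
        (ds.frame["role"] == "used") & ds.frame["behavior"].isin(behaviors)
    )
    ord_result = ordination.fit_pca(ds, ord_attrs, include=include)
    ord_result = ordination.orient_components(ord_result, anchors={"PC1": "elevation"})
    labels = pd.Series(
        np.where(ds.frame["role"] == "control", "control", ds.frame["behavior"]),
        index=pd.Index(ds.frame["record_id"], name="record_id"),
    ).loc[ord_result.scores.index]
    centroids = ordination.group_centroids(ord_result, labels)

    results = inference.run_study_analysis(
        ds, fixed_attrs, behaviors=behaviors, n_perm=config.n_perm, seed=config.seed
    )

    box_attrs = [a for a in ds.frame.columns if a in dataset_io.CONTINUOUS_ATTRIBUTES] + ["woody_debris"]
    boxplots = report.summarize_boxplots(ds, box_attrs)

    out_dir = None
    if write:
        out_dir = Path(config.out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        seed = config.seed
        report.write_table(validation.to_frame(), out_dir / "validation_counts.tsv", seed, cfg_hash)
        report.write_table(
            pd.DataFrame({"missing_fraction": validation.missingness}),
            out_dir / "validation_missingness.tsv", seed, cfg_hash,
        )
        report.write_table(ord_result.loadings.round(3), out_dir / "pca_loadings.tsv", seed, cfg_hash)
        report.write_table(
            pd.DataFrame(
                {
                    "component": ord_result.components,
                    "variance_fraction": ord_result.variance_fractions,
                }
            ),
            out_dir / "pca_variance.tsv", seed, cfg_hash, index=False,
        )
        report.write_table(ord_result.scores, out_dir / "pca_scores.tsv", seed, cfg_hash)
        report.write_table(centroids, out_dir / "pca_centroids.tsv", seed, cfg_hash)
        report.write_table(boxplots, out_dir / "boxplot_summary.tsv", seed, cfg_hash, index=False)
        log_lines = []
        for b, pooled in results.items():
            report.write_table(
                report.inference_table(pooled), out_dir / f"inference_{b}.tsv", seed, cfg_hash,
                note=f"behavior={b} n_retained={pooled.n_retained} mean_accuracy={pooled.mean_accuracy:.3f}",
            )
            report.write_table(
                pooled.pooled_draws, out_dir / f"pooled_draws_{b}.tsv", seed, cfg_hash, index=False,
            )
            log_lines.append(
                f"{b}: {pooled.n_retained}/{pooled.n_permutations_run} permutations retained, "
                f"mean accuracy {pooled.mean_accuracy:.3f}, "
                f"zero-variance fraction {pooled.prob_zero_variance:.3f}"
            )
        (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
        (out_dir / "provenance.txt").write_text("\n".join(ds.provenance) + "\n")

    return PipelineResult(
        dataset=ds,
        validation=validation,
        screen=screen,
        woody_debris_fraction=wd_fraction,
        ordination=ord_result,
        centroids=centroids,
        inference=results,
        boxplots=boxplots,
        merge=merge_result,
        out_dir=out_dir,
    )
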