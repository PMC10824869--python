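"""Readers, writers, configuration and the end-to-end pipeline.

Profile tables travel as CSV with columns transect_id, reef_id,
distance_m, depth_m; reef polygons and transect lines as GeoJSON; the
pipeline configuration as YAML. All defaults equal the study design's
stated values (base-case algorithm parameters, 500-m transect spacing,
10-m sampling, 2-m truncation, 10-m shallow/deep split, 1000-m reef search
radius, thresholds 10..90 with critical 30/40/50).
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import shape

from . import core, metrics, sensitivity
from .mixture import fit_beta_mixture
from .synthetic import (
    ReefGridSpec,
    annular_axis,
    make_reef_grid,
    transects_along_polyline,
)
from .transects import Profile, TransectLine, extract_profiles

PROFILE_COLUMNS = ["transect_id", "reef_id", "distance_m", "depth_m"]


class SchemaError(ValueError):
    """An input table violates the expected schema."""


def read_profiles(path: str | Path, clean: bool = False) -> pd.DataFrame:
    """Read and validate a profile CSV.

    Rejects missing columns, missing values, duplicate
    (transect_id, distance_m) rows and non-monotone distances, naming the
    offence; with ``clean`` duplicates and missing values are dropped
    instead and counted in ``df.attrs['cleaning_report']``.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"{path}: missing columns {missing_cols}")
    report = {"n_rows_in": len(df), "n_missing_dropped": 0, "n_duplicates_dropped": 0}
    na = df[["transect_id", "distance_m", "depth_m"]].isna().any(axis=1)
    if na.any():
        if not clean:
            raise SchemaError(f"{path}: {na.sum()} rows with missing values")
        report["n_missing_dropped"] = int(na.sum())
        df = df[~na]
    dup = df.duplicated(subset=["transect_id", "distance_m"])
    if dup.any():
        if not clean:
            raise SchemaError(f"{path}: {dup.sum()} duplicated (transect, distance) rows")
        report["n_duplicates_dropped"] = int(dup.sum())
        df = df[~dup]
    for tid, grp in df.groupby("transect_id"):
        if not np.all(np.diff(grp["distance_m"].to_numpy()) > 0):
            raise SchemaError(f"{path}: non-monotone distance_m in transect {tid!r}")
    df = df.reset_index(drop=True)
    df.attrs["cleaning_report"] = report
    return df


def write_profiles(profiles: list[Profile], path: str | Path) -> None:
    rows = []
    for p in profiles:
        for d, z in zip(p.distance_m, p.depth_m):
            rows.append(
                {
                    "transect_id": p.transect_id,
                    "reef_id": p.reef_id if p.reef_id is not None else "",
                    "distance_m": d,
                    "depth_m": z,
                }
            )
    pd.DataFrame(rows, columns=PROFILE_COLUMNS).to_csv(path, index=False)


def profiles_from_table(df: pd.DataFrame) -> list[Profile]:
    """Profile objects from a validated long table."""
    out = []
    for tid, grp in df.groupby("transect_id", sort=True):
        reef = grp["reef_id"].iloc[0]
        if pd.isna(reef) or reef == "":
            reef = None
        out.append(
            Profile(
                transect_id=str(tid),
                reef_id=None if reef is None else str(reef),
                distance_m=grp["distance_m"].to_numpy(float),
                depth_m=grp["depth_m"].to_numpy(float),
            )
        )
    return out


def read_geojson_polygons(path: str | Path) -> dict:
    """Reef polygons keyed by their ``id`` property (or feature id)."""
    with open(path) as fh:
        gj = json.load(fh)
    out = {}
    for i, feat in enumerate(gj.get("features", [])):
        key = str(feat.get("properties", {}).get("id", feat.get("id", i)))
        out[key] = shape(feat["geometry"])
    return out


def read_geojson_lines(path: str | Path) -> list[TransectLine]:
    with open(path) as fh:
        gj = json.load(fh)
    lines = []
    for i, feat in enumerate(gj.get("features", [])):
        geom = feat["geometry"]
        if geom["type"] != "LineString":
            raise SchemaError(f"{path}: feature {i} is not a LineString")
        coords = geom["coordinates"]
        props = feat.get("properties", {})
        lines.append(
            TransectLine(
                id=str(props.get("id", i)),
                start=tuple(coords[0]),
                end=tuple(coords[-1]),
                reef_id=props.get("reef_id"),
            )
        )
    return lines


@dataclass
class PipelineConfig:
    """End-to-end run configuration with study-design defaults."""

    profiles_csv: str | None = None
    grid_ascii: str | None = None
    transects_geojson: str | None = None
    reefs_geojson: str | None = None
    synthetic_demo: bool = False
    demo_reefs: int = 12
    moving_window_m: float = 50.0
    rubble_height_m: float = 0.5
    roll_depth_range_m: float = 5.0
    flat_depth_change_m: float = 0.5
    thresholds: list[int] = field(default_factory=lambda: list(range(10, 100, 10)))
    critical_thresholds: list[int] = field(default_factory=lambda: [30, 40, 50])
    transect_spacing_m: float = 500.0
    sample_spacing_m: float = 10.0
    truncation_depth_m: float = 2.0
    shallow_deep_split_m: float = 10.0
    reef_search_radius_m: float = 1000.0
    seed: int = 0
    clean: bool = False
    run_sensitivity: bool = True
    run_regression: bool = False
    zero_base_thresholds: str = "exclude"  # or "include"

    def rubble_params(self) -> core.RubbleParams:
        return core.RubbleParams(
            moving_window_m=self.moving_window_m,
            rubble_height_m=self.rubble_height_m,
            roll_depth_range_m=self.roll_depth_range_m,
            flat_depth_change_m=self.flat_depth_change_m,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise SchemaError(f"{path}: unknown config keys {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.rubble_params()  # validate early, before any computation
        if cfg.zero_base_thresholds not in ("exclude", "include"):
            raise SchemaError("zero_base_thresholds must be 'exclude' or 'include'")
        return cfg

    def config_hash(self) -> str:
        canon = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def demo_profiles(n_reefs: int = 12, seed: int = 0) -> list[Profile]:
    """Synthetic multi-reef demo: annular platforms with varied slopes.

    Each reef is an annular platform whose slope width (hence steepness)
    and noise vary, giving a spread of rubble susceptibilities; transects
    are normals to the mid-slope ring at 500-m spacing.
    """
    rng = np.random.default_rng(seed)
    profiles: list[Profile] = []
    for r in range(n_reefs):
        spec = ReefGridSpec(
            shape=(90, 90),
            geometry="annular_platform",
            crest_depth_m=float(rng.uniform(1.2, 2.5)),
            slope_base_depth_m=float(rng.uniform(16.0, 25.0)),
            slope_width_m=float(rng.choice([60.0, 100.0, 150.0, 220.0, 300.0])),
            noise_sd_m=float(rng.uniform(0.0, 0.35)),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        grid = make_reef_grid(spec)
        lines = [
            TransectLine(id=f"R{r:02d}T{i:02d}", start=a, end=b, reef_id=f"R{r:02d}")
            for i, (a, b) in enumerate(
                transects_along_polyline(annular_axis(spec), spacing_m=500.0)
            )
        ]
        profiles.extend(extract_profiles(grid, lines))
    return profiles


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Run transect evaluation, reef aggregation and optional analyses.

    Writes per-point flags, per-transect summaries, per-reef
    susceptibility, the region summary, sensitivity tables and a manifest
    into ``outdir``; returns the manifest dict.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.rubble_params()
    if config.synthetic_demo:
        profiles = demo_profiles(config.demo_reefs, config.seed)
    elif config.profiles_csv:
        profiles = profiles_from_table(read_profiles(config.profiles_csv, config.clean))
    elif config.grid_ascii and config.transects_geojson:
        from .grids import read_esri_ascii

        grid = read_esri_ascii(config.grid_ascii)
        lines = read_geojson_lines(config.transects_geojson)
        polys = (
            read_geojson_polygons(config.reefs_geojson) if config.reefs_geojson else None
        )
        profiles = extract_profiles(grid, lines, polys)
    else:
        raise SchemaError("config provides no input (profiles, grid, or demo)")
    if not profiles:
        raise SchemaError("no usable profiles after extraction/truncation")

    write_profiles(profiles, outdir / "profiles.csv")
    results = [core.evaluate_transect(p, params) for p in profiles]
    flags = pd.DataFrame(
        [
            {
                "transect_id": r.transect_id,
                "distance_m": i * config.sample_spacing_m,
                "depth_m": d,
                "filled_depth_m": f,
                "accumulates": bool(a),
                "section": s,
            }
            for r in results
            for i, (d, f, a, s) in enumerate(
                zip(r.depth_m, r.filled_depth_m, r.accumulates, r.section)
            )
        ]
    )
    flags.to_csv(outdir / "point_flags.csv", index=False)
    table = metrics.results_table(results)
    table.to_csv(outdir / "transect_summary.csv", index=False)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reef = metrics.reef_susceptibility(
            table, tuple(config.thresholds), config.transect_spacing_m
        )
        region = metrics.summarize_region(reef, table)
    reef.to_csv(outdir / "reef_susceptibility.csv", index=False)
    region.to_csv(outdir / "region_summary.csv", index=False)
    manifest = {
        "config_hash": config.config_hash(),
        "n_profiles": len(profiles),
        "n_reefs": int(region.attrs["n_reefs"]),
        "outputs": ["profiles.csv", "point_flags.csv", "transect_summary.csv",
                    "reef_susceptibility.csv", "region_summary.csv"],
    }
    if config.run_sensitivity:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            oat = sensitivity.run_oat(
                profiles, params, tuple(config.critical_thresholds),
                config.transect_spacing_m,
            )
            ranking = sensitivity.rank_parameters(
                oat, include_zero_base=config.zero_base_thresholds == "include"
            )
        oat.counts.to_csv(outdir / "oat_counts.csv", index=False)
        oat.rank_changes.to_csv(outdir / "oat_rank_changes.csv", index=False)
        ranking.to_csv(outdir / "parameter_ranking.csv", index=False)
        manifest["outputs"] += ["oat_counts.csv", "oat_rank_changes.csv",
                                "parameter_ranking.csv"]
    if config.run_regression:
        aspect_map = {p.transect_id: p.aspect_class for p in profiles}
        obs = observation_table(results, aspect_map)
        if len(obs) >= 50:
            fit = fit_beta_mixture(obs, seed=config.seed)
            fit.summary().to_csv(outdir / "mixture_coefficients.csv", index=False)
            summary = {
                "weights": fit.weights_.tolist(),
                "precisions": fit.precision_.tolist(),
                "loglik": fit.loglik_,
            }
            (outdir / "mixture_fit.json").write_text(json.dumps(summary, indent=2))
            manifest["outputs"] += ["mixture_coefficients.csv", "mixture_fit.json"]
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def observation_table(results, aspect_classes: dict | None = None) -> pd.DataFrame:
    """Proportion observations for the regression stage.

    One observation per transect x depth-section with defined cover;
    aspect classes come from the profiles when available, else a supplied
    mapping (transects without one are dropped).
    """
    rows = []
    for r in results:
        aspect = (aspect_classes or {}).get(r.transect_id)
        for cls, cover in (
            ("shallow", r.cover_pct_shallow),
            ("deep", r.cover_pct_deep),
        ):
            if not np.isnan(cover):
                rows.append(
                    {
                        "transect_id": r.transect_id,
                        "depth_class": cls,
                        "aspect_class": aspect if aspect else "N",
                        "proportion": cover / 100.0,
                    }
                )
    return pd.DataFrame(rows)
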