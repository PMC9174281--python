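"""Formats, configuration and the end-to-end pipeline driver.

Coordinate tables are tab-delimited text with columns
``embryo_id, frame, time_h, x, y, z, volume_voxels`` (isotropic units, z
pre-scaled by dz/dx).  Rendered volumes are written as one multi-page TIFF
per time point, slice order z-ascending.  ``run_pipeline`` ties simulation
(or detection, or an external coordinate table) to tracking, synchrony,
morphometrics and the cohort statistics, deterministically under one seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detect import detect_frame
from .lineage import (
    TrackingError,
    lineage_to_frame,
    link_tracks,
    synchrony_profile,
)
from .morphometrics import morphometric_series
from .simulate import SimulationConfig, simulate_cohort
from .stats import cohort_report, roc_analysis
from .types import OBSERVATION_COLUMNS, DetectionParams, VoxelGrid

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Volumes


def write_stack(path, grid: VoxelGrid) -> None:
    """Write one 3D volume as a multi-page TIFF (slices z-ascending)."""
    tifffile.imwrite(str(path), grid.intensities.astype(np.float32))


def read_stack(
    path, spacing=(0.8, 0.8, 2.0), time: float = 0.0, frame_index: int = 0
) -> VoxelGrid:
    """Read one multi-page TIFF z-stack into a VoxelGrid."""
    vol = np.asarray(tifffile.imread(str(path)), dtype=float)
    if vol.ndim == 2:
        vol = vol[None]
    return VoxelGrid(vol, spacing=tuple(spacing), time=time, frame_index=frame_index)


# ---------------------------------------------------------------------------
# Coordinate tables


def write_coordinates(df: pd.DataFrame, path) -> None:
    cols = [c for c in OBSERVATION_COLUMNS if c in df.columns]
    df[cols].to_csv(path, sep="\t", index=False)


def read_coordinates(
    path, mapping: dict | None = None, z_divisor: float = 1.0
) -> pd.DataFrame:
    """Read and validate a coordinate table.

    ``mapping`` renames source columns to the canonical names
    (canonical → source).  ``z_divisor`` divides the stored z; use 2.5 to
    recover slice indices from tables that store the pre-scaled isotropic z.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    if mapping:
        missing = [src for src in mapping.values() if src not in df.columns]
        if missing:
            raise ValueError(f"mapped columns not found in {path}: {missing}")
        df = df.rename(columns={src: dst for dst, src in mapping.items()})
    required = ["embryo_id", "frame", "time_h", "x", "y", "z"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns in {path}: {missing}")
    for col in ["frame", "time_h", "x", "y", "z"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad or coerced.isna().any():
            rows = bad or df.index[coerced.isna()].tolist()
            raise ValueError(f"non-numeric or missing {col!r} at rows {rows[:10]}")
        df[col] = coerced
    if "volume_voxels" not in df.columns:
        df["volume_voxels"] = 0.0
    dup = df.duplicated(subset=["embryo_id", "frame", "x", "y", "z"])
    if dup.any():
        raise ValueError(f"duplicate observations at rows {df.index[dup].tolist()[:10]}")
    if z_divisor != 1.0:
        df["z"] = df["z"] / z_divisor
    logger.info(
        "%s: %d rows, %d embryos", path, len(df), df["embryo_id"].nunique()
    )
    return df


# ---------------------------------------------------------------------------
# Run configuration and pipeline


@dataclass
class RunConfig:
    """One reproducible pipeline run."""

    mode: str = "simulate"  # simulate | images | coordinates
    input_path: str | None = None
    outdir: str = "embryosync_out"
    cutoff: float = 0.15
    z_divisor: float = 1.0
    column_mapping: dict = field(default_factory=dict)
    seed: int = 0
    detection: DetectionParams = field(default_factory=DetectionParams)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "images", "coordinates"):
            raise ValueError("mode must be simulate, images or coordinates")
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")
        # one seed drives everything, including the simulator
        self.simulation = dataclasses.replace(self.simulation, seed=self.seed)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        det = DetectionParams(**raw.pop("detection", {}))
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(detection=det, simulation=sim, **raw)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _collect_image_observations(config: RunConfig) -> pd.DataFrame:
    """Detect nuclei in every embryo's TIFF series under input_path.

    Layout: ``<input_path>/<embryo_id>/frame_<k>.tif``; frame times are
    k × the configured frame interval.
    """
    root = Path(config.input_path)
    from .types import observations_to_frame

    all_obs = []
    for embryo_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        for k, tif in enumerate(sorted(embryo_dir.glob("*.tif*"))):
            grid = read_stack(
                tif,
                spacing=config.simulation.voxel_spacing,
                time=k * config.simulation.frame_interval,
                frame_index=k,
            )
            all_obs.extend(detect_frame(grid, config.detection, embryo_dir.name))
    return observations_to_frame(all_obs)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write every intermediate table.

    simulate mode: generate the cohort (coordinates + ground truth) →
    track → synchrony/morphometrics → cohort statistics.  images mode runs
    detection first; coordinates mode starts from a table on disk.
    Deterministic for identical config and seed.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    outcomes: dict[str, str] = {}
    if config.mode == "simulate":
        cohort = simulate_cohort(config.simulation)
        obs = pd.concat([g.observations for g in cohort], ignore_index=True)
        outcomes = {g.embryo_id: g.outcome for g in cohort}
        truth = pd.DataFrame(
            [
                (g.embryo_id, g.true_round_cvs.get(3, np.nan), g.outcome)
                for g in cohort
            ],
            columns=["embryo_id", "true_third_cv", "outcome"],
        )
        write_coordinates(obs, outdir / "coordinates.tsv")
        truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
        pd.concat(
            [lineage_to_frame(g.lineage) for g in cohort], ignore_index=True
        ).to_csv(outdir / "lineage.tsv", sep="\t", index=False)
    elif config.mode == "images":
        obs = _collect_image_observations(config)
        write_coordinates(obs, outdir / "coordinates.tsv")
    else:
        obs = read_coordinates(
            config.input_path, config.column_mapping or None, config.z_divisor
        )

    profiles = []
    morpho_tables = []
    excluded = []
    for embryo_id, sub in obs.groupby("embryo_id", sort=True):
        try:
            tree = link_tracks(sub, str(embryo_id))
            profiles.append(synchrony_profile(tree, cutoff=config.cutoff))
        except (TrackingError, ValueError) as exc:
            excluded.append({"embryo_id": str(embryo_id), "reason": str(exc)})
            continue
        morpho_tables.append(morphometric_series(sub))

    prof_df = pd.DataFrame(
        [
            (p.embryo_id, p.second_diff_norm, p.third_cv, p.fourth_cv, p.synchrony_class)
            for p in profiles
        ],
        columns=["embryo_id", "second_diff_norm", "third_cv", "fourth_cv", "synchrony_class"],
    )
    prof_df.to_csv(outdir / "synchrony.tsv", sep="\t", index=False)
    if morpho_tables:
        pd.concat(morpho_tables, ignore_index=True).to_csv(
            outdir / "morphometrics.tsv", sep="\t", index=False
        )

    results: dict = {
        "n_embryos": len(profiles),
        "n_excluded": len(excluded),
        "excluded": excluded,
    }
    analyzed = {p.embryo_id for p in profiles}
    outcomes = {e: o for e, o in outcomes.items() if e in analyzed}
    if outcomes and len(set(outcomes.values())) == 2:
        results["cohort"] = cohort_report(profiles, outcomes, cutoff=config.cutoff)
        scores = [p.third_cv for p in profiles]
        labels = [outcomes[p.embryo_id] for p in profiles]
        roc = roc_analysis(scores, labels)
        results["roc"] = {
            "selected_cutoff": roc.selected_cutoff,
            "auc": roc.auc,
            **{f"at_selected_{k}": v for k, v in roc.at_cutoff(roc.selected_cutoff).items()},
        }
    elif outcomes:
        results["cohort"] = cohort_report(profiles, outcomes, cutoff=config.cutoff)

    emit_report(results, config, outdir)
    return results


def emit_report(results: dict, config: RunConfig, outdir) -> None:
    """Write the machine-readable (JSON) and human-readable run report."""
    outdir = Path(outdir)
    payload = {
        "software_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "results": results,
    }
    (outdir / "report.json").write_text(json.dumps(payload, indent=2, default=_jsonable))
    lines = [
        f"embryosync v{__version__}",
        f"config hash: {config.config_hash()}  seed: {config.seed}",
        f"embryos analyzed: {results.get('n_embryos', 0)}"
        f" (excluded: {results.get('n_excluded', 0)})",
    ]
    cohort = results.get("cohort")
    if cohort:
        lines += [
            f"high-CV fraction of aborts: {cohort['high_fraction_of_aborts']:.3f}",
            f"high-CV fraction of all:    {cohort['high_fraction_of_all']:.3f}",
            f"born rate high/low: {cohort['born_rate_high']:.3f} / {cohort['born_rate_low']:.3f}"
            f"  (prop-test p = {cohort['born_rate_p']:.4g})",
        ]
    roc = results.get("roc")
    if roc:
        lines.append(
            f"ROC: cutoff {roc['selected_cutoff']:.3f}, "
            f"sens {roc['at_selected_sensitivity']:.3f}, "
            f"spec {roc['at_selected_specificity']:.3f}, "
            f"acc {roc['at_selected_accuracy']:.3f}, AUC {roc['auc']:.3f}"
        )
    if not results.get("n_embryos"):
        lines.append("zero embryos analyzed")
    (outdir / "report.txt").write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)
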