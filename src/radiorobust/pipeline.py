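"""End-to-end experiment orchestration.

Runs cohort generation (or loading) → full factorial feature extraction →
robustness statistics, writing tidy CSV artifacts:

* ``manifest.csv`` — per-patient lesion parameters and seeds;
* ``features_<config_id>.csv`` — one long-form feature table per grid point
  (the config id encodes all four preprocessing parameters, so outputs from
  different configs cannot be mixed up);
* ``icc.csv`` — per (config, feature) ICC with 95% CI and excellence flag;
* ``sensitivity.csv`` — per (feature, parameter) worst-case ICC-lower-bound
  range;
* ``cv_correlation.csv`` — per-feature Spearman rho of CV vs lesion volume;
* ``run_log.yaml`` — seeds, versions, sizes, wall times.

Re-running with the same config reproduces all numeric outputs; existing
per-config feature files are re-used (resumable extraction).
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .features import N_FEATURES_TOTAL, extract_grid
from .images import Mask, Volume, read_mask, read_volume
from .preprocessing import DEFAULT_GRID, ExtractionConfig, Interpolator, make_grid
from .stats import (
    GRID_PARAMETERS,
    cv_size_correlation,
    cv_table,
    robustness_table,
    sensitivity_table,
)
from .synthetic import STYLES, CohortConfig, PatientPhantom, generate_cohort, write_cohort

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.17g"


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce one robustness experiment."""

    out_dir: str = "radiorobust_out"
    n_patients: int = 48
    master_seed: int = 0
    cohort_dir: str | None = None  # load instead of simulate when set
    grid: dict = field(default_factory=lambda: {
        "bin_width": list(DEFAULT_GRID["bin_width"]),
        "pixel_distance": list(DEFAULT_GRID["pixel_distance"]),
        "interpolator": [i.value for i in DEFAULT_GRID["interpolator"]],
        "resolution_mm": list(DEFAULT_GRID["resolution_mm"]),
    })
    icc_excellent: float = 0.9
    sensitivity_low: float = 0.1
    save_cohort: bool = False
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not all(self.grid.get(p) for p in GRID_PARAMETERS):
            raise ValueError(f"grid must provide nonempty values for {GRID_PARAMETERS}")
        for t in (self.icc_excellent, self.sensitivity_low):
            if not 0 < t < 1:
                raise ValueError("thresholds must lie in (0, 1)")

    def configs(self) -> list[ExtractionConfig]:
        return make_grid(
            bin_width=self.grid["bin_width"],
            pixel_distance=self.grid["pixel_distance"],
            interpolator=[Interpolator(i) for i in self.grid["interpolator"]],
            resolution_mm=self.grid["resolution_mm"],
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "cohort" in raw:
            raw["cohort"] = CohortConfig(**{
                k: tuple(v) if isinstance(v, list) else v
                for k, v in raw["cohort"].items()
            })
        return cls(**raw)


# ---------------------------------------------------------------------------
# Cohort I/O


def read_cohort(directory: str | Path) -> list[PatientPhantom | tuple]:
    """Load a written cohort: per patient one volume and three styled masks.

    Patients with missing or misaligned files are rejected individually (with
    a logged per-patient error listing); the rest load normally.
    """
    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    cohort = []
    errors: dict[str, str] = {}
    for _, row in manifest.iterrows():
        pid = row["patient_id"]
        try:
            volume = read_volume(directory / row["volume_path"])
            masks = {}
            for style in STYLES:
                col = f"mask_{style.value}"
                path = directory / str(row[col])
                if pd.isna(row.get(col)) or not path.exists():
                    raise FileNotFoundError(f"missing mask file for style {style.value}")
                mask = read_mask(path, style=style.value)
                mask.check_aligned(volume)
                masks[style] = mask
            cohort.append((pid, volume, masks))
        except Exception as e:  # per-patient isolation
            errors[pid] = str(e)
            logger.error("rejecting patient %s: %s", pid, e)
    if errors:
        logger.error("rejected %d patients: %s", len(errors), sorted(errors))
    return cohort


def _cohort_records(config: ExperimentConfig, out: Path):
    if config.cohort_dir:
        records = read_cohort(config.cohort_dir)
        manifest = pd.read_csv(Path(config.cohort_dir) / "manifest.csv")
        manifest.to_csv(out / "manifest.csv", index=False)
        return records
    cohort = generate_cohort(config.n_patients, config.master_seed, config.cohort)
    if config.save_cohort:
        write_cohort(cohort, out / "cohort")
    rows = [
        {
            "patient_id": p.patient_id,
            "seed": p.spec.seed,
            "radius_x_mm": p.spec.lesion_radii[0],
            "radius_y_mm": p.spec.lesion_radii[1],
            "radius_z_mm": p.spec.lesion_radii[2],
        }
        for p in cohort
    ]
    pd.DataFrame(rows).to_csv(out / "manifest.csv", index=False)
    return [(p.patient_id, p.volume, p.masks) for p in cohort]


# ---------------------------------------------------------------------------
# Extraction


def extract_feature_table(
    records: list[tuple[str, Volume, dict]],
    configs: list[ExtractionConfig],
    out_dir: Path | None = None,
) -> pd.DataFrame:
    """Long-form feature table over patients × segmentations × configs.

    With ``out_dir`` set, one CSV per config is written and configs whose
    file already exists (with the expected row count) are loaded instead of
    recomputed, making partial runs resumable.
    """
    per_config: dict[str, list[pd.DataFrame]] = {c.config_id: [] for c in configs}
    todo = list(configs)
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for cfg in list(todo):
            path = out_dir / f"features_{cfg.config_id}.csv"
            if path.exists():
                cached = pd.read_csv(path)
                expected = len(records) * len(STYLES) * N_FEATURES_TOTAL
                if len(cached) == expected:
                    per_config[cfg.config_id] = [cached]
                    todo.remove(cfg)
                else:
                    raise ValueError(
                        f"corrupt intermediate file {path.name}: "
                        f"{len(cached)} rows, expected {expected}"
                    )
    for pid, volume, masks in records:
        for style in STYLES:
            if not todo:
                break
            vectors = extract_grid(volume, masks[style], todo)
            for cfg in todo:
                vec = vectors[cfg.config_id]
                per_config[cfg.config_id].append(
                    pd.DataFrame(
                        {
                            "patient_id": pid,
                            "segmentation": style.value,
                            "config_id": cfg.config_id,
                            "feature": list(vec.keys()),
                            "value": list(vec.values()),
                        }
                    )
                )
    frames = []
    for cfg in configs:
        tbl = pd.concat(per_config[cfg.config_id], ignore_index=True)
        tbl = tbl.sort_values(
            ["patient_id", "segmentation", "feature"], kind="mergesort"
        ).reset_index(drop=True)
        if out_dir is not None and cfg in todo:
            tbl.to_csv(
                out_dir / f"features_{cfg.config_id}.csv",
                index=False,
                float_format=_FLOAT_FMT,
            )
        frames.append(tbl)
    return pd.concat(frames, ignore_index=True)


def configs_frame(configs: list[ExtractionConfig]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "config_id": [c.config_id for c in configs],
            "bin_width": [c.bin_width for c in configs],
            "pixel_distance": [c.pixel_distance for c in configs],
            "interpolator": [c.interpolator.value for c in configs],
            "resolution_mm": [c.resolution_mm for c in configs],
        }
    )


# ---------------------------------------------------------------------------
# Full experiment


def run_experiment(config: ExperimentConfig) -> Path:
    """Run the whole robustness analysis; returns the output directory."""
    t0 = time.monotonic()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    records = _cohort_records(config, out)
    if not records:
        raise RuntimeError("no usable patients in cohort")
    timings["cohort_s"] = round(time.monotonic() - t0, 2)

    configs = config.configs()
    t1 = time.monotonic()
    features = extract_feature_table(records, configs, out_dir=out)
    timings["extraction_s"] = round(time.monotonic() - t1, 2)

    t2 = time.monotonic()
    icc = robustness_table(features, icc_excellent=config.icc_excellent)
    icc.to_csv(out / "icc.csv", index=False, float_format=_FLOAT_FMT)

    sens = sensitivity_table(
        icc,
        configs_frame(configs),
        sensitivity_low=config.sensitivity_low,
        on_incomplete="skip",
    )
    sens.to_csv(out / "sensitivity.csv", index=False, float_format=_FLOAT_FMT)

    # CV analysis at the reference grid point (first config, sorted id order)
    ref_config = sorted(c.config_id for c in configs)[0]
    cvs = cv_table(features, config_id=ref_config)
    volumes = (
        features.query(
            "config_id == @ref_config and segmentation == 'accurate_freehand' "
            "and feature == 'original_shape_VoxelVolume'"
        )
        .set_index("patient_id")["value"]
    )
    corr = cv_size_correlation(cvs, volumes)
    corr.to_csv(out / "cv_correlation.csv", index=False, float_format=_FLOAT_FMT)
    timings["stats_s"] = round(time.monotonic() - t2, 2)

    log = {
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "master_seed": config.master_seed,
        "n_patients": len(records),
        "n_configs": len(configs),
        "reference_config": ref_config,
        "grid": config.grid,
        "timings": timings,
    }
    with open(out / "run_log.yaml", "w") as fh:
        yaml.safe_dump(log, fh, sort_keys=True)
    return out
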