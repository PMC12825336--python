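"""Run configuration, validation, and the staged pipeline.

A run is described by a YAML (or TOML) document with one block per stage,
mirroring the library dataclasses; unknown keys are rejected with an error
naming them, and defaults are the study parameters.  ``run_pipeline``
executes the selected stages (simulate -> analyze, synth -> analyze, and/or
dehydration) and writes a JSON manifest with versions, seeds and checksums
so every artifact is reproducible from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path
from typing import Any

import numpy as np

from .dehydration import DEFAULT_CONDITIONS, ChannelCondition, calibrate
from .grids import GridSpec
from .morphometrics import filter_satellites, segment_droplets, size_statistics
from .solver import SolverConfig, run_simulation
from .synthetic import SyntheticImageSpec, generate_droplet_image
from .thermo import BinodalModel, Composition, InteractionSchedule, ThermoParams

__all__ = ["RunConfig", "AnalyzeConfig", "DehydrationConfig", "ConfigError",
           "load_config", "save_config", "run_pipeline"]

log = logging.getLogger("dexdrop")


class ConfigError(ValueError):
    """Configuration file violates the schema."""


@dataclass(frozen=True)
class AnalyzeConfig:
    threshold: float = 0.5
    min_area: float = 2.0  # µm^2
    grid_scale: float = 1.0  # µm / px (ignored for simulated fields)
    satellite_min_diameter: float | None = None  # µm; None = no filter
    exclude_boundary: bool = True
    periodic_x: bool = False


@dataclass(frozen=True)
class DehydrationConfig:
    mode: str = "quadratic"
    conditions_csv: str | None = None  # columns width_um, c_peg, c_dex, onset_min


@dataclass
class RunConfig:
    stages: tuple[str, ...] = ("simulate", "analyze")
    outdir: str = "dexdrop_out"
    seed: int = 0
    log_level: str = "INFO"
    grid: GridSpec = dataclass_field(default_factory=GridSpec)
    solver: SolverConfig = dataclass_field(default_factory=SolverConfig)
    thermo: ThermoParams = dataclass_field(default_factory=ThermoParams)
    synth: SyntheticImageSpec = dataclass_field(default_factory=SyntheticImageSpec)
    analyze: AnalyzeConfig = dataclass_field(default_factory=AnalyzeConfig)
    dehydration: DehydrationConfig = dataclass_field(default_factory=DehydrationConfig)

    def to_dict(self) -> dict[str, Any]:
        def plain(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return plain(self)


_BLOCKS = {
    "grid": GridSpec,
    "solver": SolverConfig,
    "thermo": ThermoParams,
    "synth": SyntheticImageSpec,
    "analyze": AnalyzeConfig,
    "dehydration": DehydrationConfig,
}
_KNOWN_STAGES = ("simulate", "analyze", "synth", "dehydration")


def _build_block(name: str, cls, data: dict, errors: list[str]):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    errors.extend(f"{name}.{k}" for k in sorted(unknown))
    kwargs = {k: v for k, v in data.items() if k in fields}
    for k, v in kwargs.items():
        if isinstance(v, list):
            kwargs[k] = tuple(v)
    try:
        return cls(**kwargs)
    except (ValueError, TypeError) as err:
        raise ConfigError(f"invalid values in block '{name}': {err}") from None


def config_from_dict(doc: dict[str, Any] | None) -> RunConfig:
    """Build a validated RunConfig; unknown keys raise listing each offender."""
    doc = dict(doc or {})
    errors: list[str] = []
    top_fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown_top = set(doc) - top_fields
    errors.extend(sorted(unknown_top))
    kwargs: dict[str, Any] = {}
    for name, cls in _BLOCKS.items():
        block = doc.get(name)
        if block is None:
            continue
        if not isinstance(block, dict):
            raise ConfigError(f"block '{name}' must be a mapping")
        kwargs[name] = _build_block(name, cls, block, errors)
    if errors:
        raise ConfigError("unknown configuration keys: " + ", ".join(errors))
    for key in ("outdir", "seed", "log_level"):
        if key in doc:
            kwargs[key] = doc[key]
    if "stages" in doc:
        stages = tuple(doc["stages"])
        bad = [s for s in stages if s not in _KNOWN_STAGES]
        if bad:
            raise ConfigError(f"unknown stage name(s): {', '.join(bad)}")
        kwargs["stages"] = stages
    try:
        return RunConfig(**kwargs)
    except (ValueError, TypeError) as err:
        raise ConfigError(str(err)) from None


def load_config(path: str | Path) -> RunConfig:
    """Parse and validate a YAML or TOML run configuration.

    An empty file yields the all-defaults configuration (the study
    parameters).
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".toml", ".tml"):
        import tomllib

        doc = tomllib.loads(text)
    else:
        import yaml

        doc = yaml.safe_load(text)
    if doc is not None and not isinstance(doc, dict):
        raise ConfigError("configuration root must be a mapping")
    return config_from_dict(doc)


def save_config(cfg: RunConfig, path: str | Path) -> None:
    import yaml

    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_droplet_outputs(ds, outdir: Path, acfg: AnalyzeConfig) -> dict[str, str]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas as pd

    if acfg.satellite_min_diameter is not None:
        ds = filter_satellites(ds, acfg.satellite_min_diameter)
    rows = [
        {
            "id": d.id,
            "x_um": d.centroid[0],
            "z_um": d.centroid[1],
            "area_um2": d.area,
            "equiv_diameter_um": d.equiv_diameter,
            "touches_boundary": d.touches_boundary,
        }
        for d in ds.droplets
    ]
    csv_path = outdir / "droplets.csv"
    pd.DataFrame(rows).to_csv(csv_path, index=False)
    artifacts = {"droplets_csv": str(csv_path)}
    if len(ds):
        stats = size_statistics(ds, exclude_boundary=acfg.exclude_boundary)
        stats_path = outdir / "stats.json"
        stats_path.write_text(json.dumps(dataclasses.asdict(stats), indent=2))
        artifacts["stats_json"] = str(stats_path)
        fig, ax = plt.subplots(figsize=(5, 3.2))
        ax.hist(ds.diameters(), bins="auto", color="#4878b0", edgecolor="white")
        ax.set_xlabel("equivalent diameter (µm)")
        ax.set_ylabel("count")
        fig.tight_layout()
        png_path = outdir / "diameter_histogram.png"
        fig.savefig(png_path, dpi=150)
        plt.close(fig)
        artifacts["histogram_png"] = str(png_path)
    else:
        log.warning("empty segmentation: no stats written")
    return artifacts


def run_pipeline(cfg: RunConfig) -> tuple[int, dict[str, Any]]:
    """Execute the configured stages; returns (exit_status, manifest).

    The top-level ``seed`` drives every stochastic stage.  Partial outputs
    are preserved with a failure marker in the manifest if a stage raises.
    """
    from . import __version__

    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "stages": list(cfg.stages),
        "artifacts": {},
    }
    status = 0
    analysis_source = None  # (array, grid_scale, periodic_x)
    try:
        for stage in cfg.stages:
            log.info("stage: %s", stage)
            if stage == "simulate":
                solver_cfg = dataclasses.replace(cfg.solver, seed=cfg.seed)
                schedule = InteractionSchedule(cfg.thermo)
                traj = run_simulation(cfg.grid, solver_cfg, schedule)
                manifest["artifacts"].update(traj.save(outdir))
                final = traj.snapshots[-1]
                analysis_source = (final.eta, cfg.grid.dx, True)
            elif stage == "synth":
                import pandas as pd
                import tifffile

                spec = dataclasses.replace(cfg.synth, seed=cfg.seed)
                image, truth = generate_droplet_image(spec)
                tif_path = outdir / "synthetic_image.tif"
                tifffile.imwrite(tif_path, image.T.astype(np.float32))
                truth_path = outdir / "synthetic_truth.csv"
                pd.DataFrame(
                    [
                        {
                            "id": d.id,
                            "x_um": d.center[0],
                            "z_um": d.center[1],
                            "diameter_um": d.diameter,
                            "is_satellite": d.is_satellite,
                        }
                        for d in truth.droplets
                    ]
                ).to_csv(truth_path, index=False)
                manifest["artifacts"]["synthetic_tiff"] = str(tif_path)
                manifest["artifacts"]["synthetic_truth_csv"] = str(truth_path)
                analysis_source = (image, spec.px_scale, False)
            elif stage == "analyze":
                if analysis_source is None:
                    raise RuntimeError(
                        "analyze stage needs a preceding simulate or synth stage"
                    )
                arr, scale, periodic = analysis_source
                ds = segment_droplets(
                    arr,
                    threshold=cfg.analyze.threshold,
                    min_area=cfg.analyze.min_area,
                    grid_scale=scale,
                    periodic_x=periodic or cfg.analyze.periodic_x,
                )
                manifest["artifacts"].update(
                    _write_droplet_outputs(ds, outdir, cfg.analyze)
                )
            elif stage == "dehydration":
                conditions = DEFAULT_CONDITIONS
                if cfg.dehydration.conditions_csv:
                    import pandas as pd

                    tbl = pd.read_csv(cfg.dehydration.conditions_csv)
                    conditions = [
                        ChannelCondition(
                            r.width_um, Composition(r.c_peg, r.c_dex), r.onset_min
                        )
                        for r in tbl.itertuples()
                    ]
                params, report = calibrate(
                    conditions, BinodalModel(), mode=cfg.dehydration.mode
                )
                params_path = outdir / "dehydration_params.json"
                params_path.write_text(json.dumps(dataclasses.asdict(params), indent=2))
                pred_path = outdir / "dehydration_predictions.csv"
                report.to_csv(pred_path, index=False)
                manifest["artifacts"]["dehydration_params_json"] = str(params_path)
                manifest["artifacts"]["dehydration_predictions_csv"] = str(pred_path)
            else:  # pragma: no cover - config validation rejects these
                raise RuntimeError(f"unknown stage {stage!r}")
    except Exception as err:  # noqa: BLE001 - pipeline boundary
        log.error("stage failed: %s", err)
        manifest["failure"] = str(err)
        status = 1

    manifest["checksums"] = {
        name: _sha256(Path(p))
        for name, p in manifest["artifacts"].items()
        if Path(p).exists()
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return status, manifest
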