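"""End-to-end run: simulate two groups, segment every stack, compare.

A :class:`RunConfig` fully determines a run (one global seed governs all
randomness); :func:`run_pipeline` writes ``cells.csv``, ``groups.csv``,
``comparison.csv``, the resolved config, and a log beside each other and is
byte-reproducible for a fixed config.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

import wallvol
from wallvol.segmentation import (
    SegmentationParams,
    measurements_to_dataframe,
    segment_cells,
)
from wallvol.synthetic import (
    OpticsSpec,
    PopulationGeometry,
    simulate_population,
)
from wallvol.volumetrics import (
    compare_groups,
    comparison_to_dataframe,
    summarize_group,
)

__all__ = ["RunConfig", "StageError", "PipelineReport", "run_pipeline", "STAGE_EXIT_CODES"]

STAGE_EXIT_CODES = {"config": 2, "simulate": 3, "segment": 4, "stats": 5, "io": 6}

log = logging.getLogger("wallvol.pipeline")


class StageError(RuntimeError):
    """Failure tagged with the pipeline stage it occurred in."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class RunConfig:
    """Serializable description of one simulated two-group experiment."""

    seed: int = 0
    n_control: int = 20
    n_treated: int = 20
    wall_multiplier: float = 1.0
    cell_multiplier: float = 1.0
    spacing: tuple[float, float, float] = (0.2, 0.08, 0.08)
    poisson: bool = True
    gaussian_sd: float = 0.0
    geometry: PopulationGeometry = field(default_factory=PopulationGeometry)
    optics: OpticsSpec = field(
        default_factory=lambda: OpticsSpec(psf_sigma=(0.15, 0.1, 0.1), background=2.0)
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        if "geometry" in data and isinstance(data["geometry"], dict):
            geo = dict(data["geometry"])
            for key in ("radius_bounds_um", "wall_thickness_bounds_um"):
                if key in geo:
                    geo[key] = tuple(geo[key])
            data["geometry"] = PopulationGeometry(**geo)
        if "optics" in data and isinstance(data["optics"], dict):
            opt = dict(data["optics"])
            if "psf_sigma" in opt:
                opt["psf_sigma"] = tuple(opt["psf_sigma"])
            data["optics"] = OpticsSpec(**opt)
        if "segmentation" in data and isinstance(data["segmentation"], dict):
            data["segmentation"] = SegmentationParams(**data["segmentation"])
        if "spacing" in data:
            data["spacing"] = tuple(data["spacing"])
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class PipelineReport:
    """Paths and in-memory tables produced by one pipeline run."""

    outdir: Path
    cells: pd.DataFrame
    groups: pd.DataFrame
    comparison: pd.DataFrame
    truth: pd.DataFrame


def _setup_run_log(outdir: Path) -> logging.Handler:
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: RunConfig, outdir: str | Path) -> PipelineReport:
    """Simulate → segment → summarize → compare, writing all artefacts.

    Raises :class:`StageError` (with a distinct exit code per stage) on any
    failure.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_log(outdir)
    try:
        log.info(
            "wallvol %s | numpy %s scipy %s | seed=%d",
            wallvol.__version__,
            np.__version__,
            scipy.__version__,
            config.seed,
        )
        config.save(outdir / "run_config.json")

        try:
            population = simulate_population(
                n_control=config.n_control,
                n_treated=config.n_treated,
                geometry=config.geometry,
                wall_multiplier=config.wall_multiplier,
                cell_multiplier=config.cell_multiplier,
                seed=config.seed,
                spacing=config.spacing,
                optics=config.optics,
                poisson=config.poisson,
                gaussian_sd=config.gaussian_sd,
            )
        except Exception as exc:  # noqa: BLE001 - stage tagging
            raise StageError("simulate", str(exc)) from exc
        log.info("simulated %d stacks", len(population.stacks))

        try:
            frames = []
            for stack_index, stack in enumerate(population.stacks):
                measurements = segment_cells(stack, config.segmentation)
                df = measurements_to_dataframe(measurements)
                df.insert(0, "stack_index", stack_index)
                df.insert(1, "group", stack.meta.get("group", ""))
                frames.append(df)
            cells = pd.concat(frames, ignore_index=True)
            cells["cell_uid"] = [
                f"{g}_{s}_{c}"
                for g, s, c in zip(cells["group"], cells["stack_index"], cells["cell_id"])
            ]
        except Exception as exc:  # noqa: BLE001
            raise StageError("segment", str(exc)) from exc
        log.info("segmented %d cells", len(cells))

        try:
            control = cells[cells["group"] == "control"]
            treated = cells[cells["group"] == "treated"]
            summaries = {
                "control": summarize_group(control),
                "treated": summarize_group(treated),
            }
            groups = pd.DataFrame(
                [{"group": name, **dataclasses.asdict(s)} for name, s in summaries.items()]
            )
            comparison = comparison_to_dataframe(compare_groups(control, treated))
        except Exception as exc:  # noqa: BLE001
            raise StageError("stats", str(exc)) from exc

        try:
            truth = population.truth_table()
            cells.to_csv(outdir / "cells.csv", index=False)
            groups.to_csv(outdir / "groups.csv", index=False)
            comparison.to_csv(outdir / "comparison.csv", index=False)
            truth.to_csv(outdir / "truth.csv", index=False)
        except Exception as exc:  # noqa: BLE001
            raise StageError("io", str(exc)) from exc
        log.info("wrote outputs to %s", outdir)
        return PipelineReport(
            outdir=outdir, cells=cells, groups=groups, comparison=comparison, truth=truth
        )
    finally:
        log.removeHandler(handler)
        handler.close()
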