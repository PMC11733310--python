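"""End-to-end orchestration: simulate -> aggregate -> correct -> land-cover
stats -> mosquito proxy -> GAM, with a checksummed run manifest.

A run is driven by one flat :class:`RunConfig`; every stage output is
written to the output directory and listed in ``manifest.json`` with
its SHA-256 checksum, so a rerun with identical config + seed must
reproduce identical checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as pkg_version
from pathlib import Path

import numpy as np
import yaml

from . import gam as gam_mod
from . import landcover as lc_mod
from .grids import write_ascii_grid
from .presence import to_rate
from .roost import DecayParams, RoostCorrector
from .synthetic import LandscapeConfig, simulate_activity, simulate_covariates, simulate_landcover
from .tpc import AbundanceParams, MosquitoAbundanceModel

logger = logging.getLogger(__name__)

STAGES = ("simulate", "aggregate", "correct", "landcover", "mosquito", "gam")


@dataclass
class RunConfig:
    """Flat configuration of a full pipeline run."""

    landscape: LandscapeConfig = field(default_factory=LandscapeConfig)
    decay_amplitude: float = 1.0
    decay_scale: float = 5000.0
    decay_mode: str = "nearest"
    n_boot: int = 1000
    traits_file: str | None = None
    cell_size: float = 980.0
    reference_class: str = "miscellaneous"
    k_mosq: int = 10
    k_space: int = 8
    seed: int = 0
    outdir: str = "batscape_run"

    def __post_init__(self) -> None:
        DecayParams(amplitude=self.decay_amplitude, scale=self.decay_scale)
        if self.decay_mode not in ("nearest", "sum"):
            raise ValueError("decay_mode must be 'nearest' or 'sum'")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        # all stage randomness keys off one seed
        self.landscape.seed = self.seed

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        land = doc.pop("landscape", {})
        if land.get("roosts") is not None:
            land["roosts"] = [tuple(p) for p in land["roosts"]]
        return cls(landscape=LandscapeConfig(**land), **doc)

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["landscape"]["roosts"] = [
            list(p) for p in (self.landscape.roosts or [])
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage on a synthetic landscape and return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    grid = config.landscape.grid
    manifest: dict = {
        "package_version": pkg_version("batscape"),
        "seed": config.seed,
        "stages": {},
    }

    def record(stage: str, files: dict[str, Path], params: dict) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "files": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in files.items()},
        }

    stage = "simulate"
    try:
        layer = simulate_landcover(config.landscape)
        raster = simulate_activity(config.landscape, layer)
        temp, lights, irrigated = simulate_covariates(config.landscape, layer)
        f_lc = out / "landcover.geojson"
        layer.to_geojson(f_lc)
        f_lights = out / "lights.asc"
        write_ascii_grid(f_lights, lights, grid)
        f_irr = out / "irrigated_fraction.asc"
        write_ascii_grid(f_irr, irrigated, grid)
        record(
            stage,
            {"landcover": f_lc, "lights": f_lights, "irrigated": f_irr},
            {"seed": config.seed, "n_scenes": raster.n_scenes},
        )

        stage = "aggregate"
        rate = to_rate(raster)
        f_counts = out / "activity_counts.asc"
        write_ascii_grid(f_counts, raster.counts.astype(float), grid)
        f_rate = out / "activity_rate.asc"
        write_ascii_grid(f_rate, rate, grid)
        record(
            stage,
            {"counts": f_counts, "rate": f_rate},
            {"n_nights": raster.n_nights, "n_scenes": raster.n_scenes,
             "pixel_area_ha": grid.pixel_area_ha},
        )

        stage = "correct"
        corrector = RoostCorrector(
            roosts=config.landscape.roost_set,
            amplitude=config.decay_amplitude,
            scale=config.decay_scale,
            mode=config.decay_mode,
        )
        corrected = corrector.transform(raster)
        f_corr = out / "activity_corrected.asc"
        write_ascii_grid(f_corr, corrected, grid)
        record(
            stage,
            {"corrected": f_corr},
            {"amplitude": config.decay_amplitude, "scale_m": config.decay_scale,
             "mode": config.decay_mode},
        )

        stage = "landcover"
        summarizer = lc_mod.LandCoverSummarizer(
            layer=layer, n_boot=config.n_boot, seed=config.seed,
            n_nights=config.landscape.n_nights,
        ).fit((corrected, grid))
        f_parcels = out / "parcel_stats.csv"
        summarizer.parcel_table_.to_csv(f_parcels, index=False)
        f_summ = out / "class_summaries.csv"
        summarizer.summaries_.to_csv(f_summ, index=False)
        f_rank = out / "class_ranking.csv"
        summarizer.ranking_.to_csv(f_rank, index=False)
        f_fig = out / "class_means.png"
        lc_mod.plot_class_means(summarizer.summaries_, f_fig)
        record(
            stage,
            {"parcels": f_parcels, "summaries": f_summ, "ranking": f_rank},
            {"n_boot": config.n_boot, "seed": config.seed},
        )

        stage = "mosquito"
        params = (
            AbundanceParams.from_yaml(config.traits_file)
            if config.traits_file
            else AbundanceParams.default()
        )
        mosq_model = MosquitoAbundanceModel(params=params)
        mosquito = mosq_model.transform(temp)
        f_mosq = out / "mosquito_abundance.asc"
        write_ascii_grid(f_mosq, mosquito, grid)
        record(stage, {"abundance": f_mosq}, {"mu_floor": params.mu_floor})

        stage = "gam"
        codes = layer.class_raster(grid)
        records = gam_mod.build_pixel_table(
            corrected, mosquito, lights, irrigated, codes, grid,
            cell_size=config.cell_size,
        )
        f_table = out / "pixel_table.csv"
        records.to_csv(f_table, index=False)
        model = gam_mod.BatMosquitoGAM(
            reference_class=config.reference_class,
            k_mosq=config.k_mosq,
            k_space=config.k_space,
        ).fit(records)
        text, doc = gam_mod.summarize_fit(model)
        f_report = out / "gam_report.json"
        gam_mod.write_report(doc, f_report)
        f_text = out / "gam_report.txt"
        f_text.write_text(text + "\n")
        record(
            stage,
            {"pixel_table": f_table, "report": f_report, "report_text": f_text},
            {"cell_size_m": config.cell_size, "k_mosq": config.k_mosq,
             "k_space": config.k_space, "reference_class": model.reference_class_},
        )
    except Exception as exc:  # noqa: BLE001 - annotate failing stage
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("pipeline complete: %d stages -> %s", len(manifest["stages"]), out)
    return manifest
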