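"""Pipeline orchestration: staged runs with a reproducibility manifest.

A run is configured by one mapping (usually loaded from YAML).  Stages
execute in the declared order

    simulate | ingest -> trace (optional) -> geometry -> angles
                      -> meshing -> report

any of which can be skipped.  All randomness flows from a single
top-level seed; every output file is listed in the manifest with a
content hash, so identical config + inputs reproduce identical bundles.
"""

from __future__ import annotations

import hashlib
import json
import math
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__, io as wio
from .angular import assess_bimodality, classify_layering
from .datatypes import TomogramContext, TraceSet
from .geometry import metrics_to_dataframe, process_traceset
from .meshing import meshing_fiber_pipeline
from .synthetic import FiberFieldSpec, MeshingSpec, RenderSpec, make_phantom, write_phantom
from .tracing import TracingParams, trace_volume


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}] {code}: {message}")
        self.stage = stage
        self.code = code


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    seed: int
    version: str = __version__
    stages: list[str] = field(default_factory=list)
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256
    started: float = field(default_factory=time.time)
    finished: float | None = None

    def record(self, path: str | Path) -> None:
        p = Path(path)
        h = hashlib.sha256(p.read_bytes()).hexdigest()
        self.outputs[p.name] = h

    def write(self, path: str | Path) -> None:
        self.finished = time.time()
        doc = {
            "version": self.version,
            "seed": self.seed,
            "stages": self.stages,
            "config": self.config,
            "outputs": self.outputs,
            "started": self.started,
            "finished": self.finished,
        }
        Path(path).write_text(json.dumps(doc, indent=2, default=str))


def _default_config(seed: int = 0) -> dict:
    return {
        "seed": seed,
        "stages": ["simulate", "geometry", "angles", "meshing", "report"],
        "simulate": {
            "box_dims": [1000.0, 1000.0, 400.0],
            "n_layers": 2,
            "layer_thickness": 200.0,
            "mode_angles": [45.0, 135.0],
            "angular_sd": 8.0,
            "pattern": "staggered",
            "fiber_spacing": 20.0,
            "fiber_length_range": [300.0, 600.0],
            "slope_sd": 0.02,
            "meshing": {"density_at_surface": 400.0, "depth_decay": 1000.0},
            "render": {"voxel_size": 4.0, "fiber_radius": 3.5, "noise_sd": 0.02},
        },
        "geometry": {
            "theta_max_deg": 70.0,
            "zz_max": 0.8,
            "resample_delta_nm": 1.0,
            "filter_before_rotation": True,
        },
        "angles": {},
        "meshing": {"fiber_threshold": 0.5, "meshing_threshold": 0.5},
        "tracing": {},
    }


def run_pipeline(config: dict, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the result summary dict.

    Outputs land in ``outdir``: per-fiber metrics CSV, angular model
    JSON, occupancy CSV, phantom files (when simulating) and
    ``manifest.json``.  On stage failure the partial outputs are moved
    under ``failed/`` and a StageError propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(config=config, seed=seed)
    stages = config.get("stages", ["simulate", "geometry", "angles", "meshing", "report"])
    report: dict = {"seed": seed}

    phantom = None
    ts: TraceSet | None = None
    fiber_map = all_map = None
    try:
        if "simulate" in stages:
            # user keys override the default simulation conditions
            sim = dict(_default_config(seed)["simulate"])
            sim.update(config.get("simulate", {}))
            mesh_cfg = sim.pop("meshing", {})
            rend_cfg = sim.pop("render", {})
            fspec = FiberFieldSpec(
                **{
                    **sim,
                    "box_dims": tuple(sim.get("box_dims", (1000.0, 1000.0, 400.0))),
                    "mode_angles": tuple(sim.get("mode_angles", (45.0, 135.0))),
                    "fiber_length_range": tuple(sim.get("fiber_length_range", (300.0, 600.0))),
                    "seed": seed,
                }
            )
            mspec = MeshingSpec(**{**mesh_cfg, "seed": seed + 1})
            rspec = RenderSpec(**{**rend_cfg, "seed": seed + 2})
            phantom = make_phantom(fspec, mspec, rspec)
            paths = write_phantom(phantom, outdir / "phantom")
            for p in paths.values():
                manifest.record(p)
            ts = phantom.traces
            fiber_map, all_map = phantom.fiber_map, phantom.all_features_map
            manifest.stages.append("simulate")

        if "ingest" in stages:
            ing = config["ingest"]
            ctx = wio.load_context(ing["context"]) if "context" in ing else TomogramContext()
            ts = wio.read_trace_table(
                ing["traces"], dialect=ing.get("dialect", "xyz_csv"),
                scale=ing.get("scale", 1.0),
            )
            ts = TraceSet(ts.traces, ctx, ts.provenance)
            if "fiber_map" in ing:
                fiber_map = wio.read_volume(ing["fiber_map"])
            if "all_features_map" in ing:
                all_map = wio.read_volume(ing["all_features_map"])
            manifest.stages.append("ingest")

        if "trace" in stages:
            if fiber_map is None:
                raise StageError("trace", "E_INPUT", "no fiber map available to trace")
            params = TracingParams(**config.get("tracing", {}))
            ctx = ts.context if ts is not None else TomogramContext(
                voxel_size_nm=fiber_map.voxel_size_nm
            )
            ts = trace_volume(fiber_map, params, context=ctx)
            wio.write_trace_table(ts, outdir / "traced.csv", dialect="xyz_csv")
            manifest.record(outdir / "traced.csv")
            report["n_traced"] = len(ts)
            manifest.stages.append("trace")

        metrics_df = None
        if "geometry" in stages:
            if ts is None:
                raise StageError("geometry", "E_INPUT", "no traces available")
            g = config.get("geometry", {})
            metrics, ts_proc, rejections = process_traceset(
                ts,
                theta_max_deg=g.get("theta_max_deg", 70.0),
                zz_max=g.get("zz_max", 0.8),
                xz_abs_max=g.get("xz_abs_max"),
                resample_delta_nm=g.get("resample_delta_nm", 1.0),
                filter_before_rotation=g.get("filter_before_rotation", True),
            )
            metrics_df = metrics_to_dataframe(metrics, ts.context)
            metrics_df.to_csv(outdir / "fiber_metrics.csv", index=False)
            manifest.record(outdir / "fiber_metrics.csv")
            report["n_fibers"] = len(metrics_df)
            finite_r = metrics_df["menger_radius_nm"].replace(
                [np.inf, -np.inf], np.nan
            ).dropna()
            # null when every fiber is straight (infinite-radius flag)
            report["mean_menger_radius_nm"] = (
                float(finite_r.mean()) if len(finite_r) else None
            )
            report["mean_slope"] = float(metrics_df["slope"].mean())
            report["rejected"] = {r.stage: r.n_removed for r in rejections}
            manifest.stages.append("geometry")

        if "angles" in stages:
            if metrics_df is None or len(metrics_df) < 50:
                raise StageError(
                    "angles", "E_INPUT", "need >= 50 fiber metrics for angular analysis"
                )
            angles = metrics_df["angle_deg"].dropna().to_numpy()
            model = assess_bimodality(angles, seed=seed)
            call = classify_layering(angles, metrics_df["mean_z_nm"].to_numpy(), model)
            doc = {"model": model.to_dict(), "layering": call.to_dict()}
            (outdir / "angular_model.json").write_text(json.dumps(doc, indent=2))
            manifest.record(outdir / "angular_model.json")
            report["bimodal"] = model.bimodal
            report["modes_deg"] = [round(m, 3) for m in model.modes_deg]
            if model.bimodal:
                report["mode_separation_deg"] = round(model.mode_separation(), 3)
            report["pattern"] = call.pattern
            manifest.stages.append("angles")

        if "meshing" in stages:
            if fiber_map is None or all_map is None:
                raise StageError("meshing", "E_INPUT", "both maps required")
            m = config.get("meshing", {})
            ctx = ts.context if ts is not None else None
            occ, _, _ = meshing_fiber_pipeline(
                fiber_map,
                all_map,
                fiber_threshold=m.get("fiber_threshold", 0.5),
                meshing_threshold=m.get("meshing_threshold", 0.5),
                context=ctx,
                dilate_radius_vox=m.get("dilate_radius_vox", 0),
            )
            import pandas as pd

            pd.DataFrame([occ.to_dict()]).to_csv(outdir / "occupancy.csv", index=False)
            manifest.record(outdir / "occupancy.csv")
            report["meshing_fiber_ratio"] = occ.ratio_meshing_over_fiber
            report["fiber_fraction"] = occ.fiber_fraction
            manifest.stages.append("meshing")

        if "report" in stages:
            (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
            manifest.record(outdir / "report.json")
            manifest.stages.append("report")

        manifest.write(outdir / "manifest.json")
        return report
    except StageError:
        failed = outdir / "failed"
        failed.mkdir(exist_ok=True)
        for p in outdir.iterdir():
            if p.is_file():
                p.rename(failed / p.name)
        raise


def default_config(seed: int = 0, **overrides) -> dict:
    cfg = _default_config(seed)
    cfg.update(overrides)
    return cfg
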