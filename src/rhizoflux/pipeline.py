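"""End-to-end orchestration of the simulate -> process -> segment ->
analyze chain, with provenance capture.

A run is driven by a :class:`RunConfig` (usually loaded from YAML).  The
pipeline either generates a synthetic radiograph experiment or consumes an
existing directory holding ``frames.csv``, per-frame TIFFs and the
``flat``/``dark``/``dry`` reference frames, then inverts the imaging
chain, builds masks (automatic segmentation of the wet-phase average map,
or a manual skeleton), and reduces the series to compartment dynamics,
uptake rates and a transition estimate.  Every stage writes its artifacts
under ``out_dir`` and a ``provenance.json`` records versions, seeds,
parameters and per-stage warnings.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__, drydown, dynamics, hydraulics, processing, segmentation
from . import simulate as sim

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "load_config"]


class PipelineError(RuntimeError):
    """A stage failure; carries the stage name and last good artifact."""

    def __init__(self, stage: str, message: str, last_artifact=None):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.last_artifact = last_artifact


@dataclass
class RunConfig:
    """Configuration of one pipeline run.  All paths may be relative."""

    out_dir: str = "rhizoflux_run"
    data_dir: str | None = None  # existing experiment; None -> simulate
    soil: str = "sand"  # fixture name for theta->psi conversion
    # simulation block (used when data_dir is None)
    scenario: dict = field(default_factory=dict)
    box: dict = field(default_factory=dict)
    attenuation: dict = field(default_factory=dict)
    geometry_seed: int = 0
    noise_seed: int | None = 0
    n_laterals: int = 20
    # segmentation block
    manual_skeleton: str | None = None
    dilation_um: float = 1000.0
    wet_frames: int = 16
    seg_params: dict = field(default_factory=dict)
    # analysis block
    window_min: float = 30.0
    tau: float = 1.5
    k_consecutive: int = 3
    diff_min: float = 15.0
    sg_window: int = 9
    sg_order: int = 2
    write_theta_maps: bool = False

    def box_spec(self) -> sim.RhizoboxSpec:
        kw = dict(self.box)
        if "grid" in kw:
            kw["grid"] = tuple(kw["grid"])
        return sim.RhizoboxSpec(**kw)

    def atten_params(self) -> sim.AttenuationParams:
        return sim.AttenuationParams(**self.attenuation)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _scenario_from_config(cfg: RunConfig) -> drydown.DrydownScenario:
    maker = drydown.sand_scenario if cfg.soil == "sand" else drydown.loam_scenario
    overrides = dict(cfg.scenario)
    if "geometry" in overrides:
        overrides["geometry"] = hydraulics.RadialGeometry(**overrides["geometry"])
    return maker(**overrides)


def _load_frames_meta(data_dir: Path) -> pd.DataFrame:
    frames_csv = data_dir / "frames.csv"
    if not frames_csv.exists():
        raise PipelineError("process", f"missing frames metadata {frames_csv}")
    return pd.read_csv(frames_csv)


def _reference_counts(data_dir: Path, name: str) -> np.ndarray:
    path = data_dir / f"{name}.tif"
    if not path.exists():
        raise PipelineError("process", f"missing {name}-field reference frame {path}")
    return tifffile.imread(path).astype(float)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns a dict of result artifacts.

    Raises :class:`PipelineError` naming the failing stage; partial
    outputs up to that stage remain on disk.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    warnings_log: dict[str, list[str]] = {}
    box = cfg.box_spec()
    atten = cfg.atten_params()
    soil = hydraulics.FIXTURES[cfg.soil]

    # -- stage: simulate (optional) -------------------------------------
    if cfg.data_dir is None:
        scenario = _scenario_from_config(cfg)
        try:
            exp = sim.generate_experiment(
                scenario,
                box,
                atten,
                geometry_seed=cfg.geometry_seed,
                noise_seed=cfg.noise_seed,
                out_dir=out / "data",
                n_laterals=cfg.n_laterals,
            )
        except Exception as err:  # noqa: BLE001 - stage boundary
            raise PipelineError("simulate", str(err)) from err
        data_dir = exp["out_dir"]
    else:
        data_dir = Path(cfg.data_dir)
        if not data_dir.exists():
            raise PipelineError("simulate", f"data directory {data_dir} does not exist")

    # -- stage: process --------------------------------------------------
    meta = _load_frames_meta(data_dir)
    flat = _reference_counts(data_dir, "flat")
    dark = _reference_counts(data_dir, "dark")
    dry = _reference_counts(data_dir, "dry")
    try:
        corr, dry_ot = processing.make_corrections(
            flat, dark, dry, scatter_frac=atten.scatter_frac
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("process", str(err)) from err

    theta_dir = out / "theta_maps"
    if cfg.write_theta_maps:
        theta_dir.mkdir(exist_ok=True)

    maps = []
    for _, row in meta.iterrows():
        counts = tifffile.imread(data_dir / row.filename).astype(float)
        wmap = processing.process_frame(counts, corr, dry_ot, atten, box)
        maps.append(wmap)
        if cfg.write_theta_maps:
            tifffile.imwrite(
                theta_dir / f"theta_{int(row['index']):04d}.tif",
                wmap.theta.astype(np.float32),
            )
    n_floored = int(np.sum([m.n_floored for m in maps]))
    warnings_log["process"] = [f"{n_floored} negative-theta pixels floored at 0"]

    total = pd.DataFrame(
        {
            "time_min": meta.time_min,
            "light": meta.light,
            "total_water_cm3": [processing.total_water(m, box) for m in maps],
        }
    )
    total_csv = out / "total_water.csv"
    total.to_csv(total_csv, index=False)

    # -- stage: segment --------------------------------------------------
    shape = tuple(box.grid)
    soil_region = np.ones(shape, dtype=bool)
    try:
        if cfg.manual_skeleton is not None:
            skeleton = segmentation.import_manual_skeleton(cfg.manual_skeleton, shape)
        else:
            day_idx = meta.index[meta.light == 1][: cfg.wet_frames]
            if len(day_idx) == 0:
                raise ValueError("no light-on frames available for segmentation")
            wet_avg = np.mean([maps[i].theta for i in day_idx], axis=0)
            den = segmentation.denoise(wet_avg)
            root_mask = segmentation.segment_roots(den, **cfg.seg_params)
            if not root_mask.any():
                raise ValueError("automatic segmentation found no roots")
            skeleton = segmentation.skeletonize_mask(root_mask)
        dilation_px = int(np.ceil(cfg.dilation_um * 1e-4 / box.pixel_size))
        masks = segmentation.build_masks(skeleton, soil_region, dilation_px)
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001
        raise PipelineError("segment", str(err), last_artifact=total_csv) from err
    tifffile.imwrite(out / "skeleton.tif", masks.skeleton.astype(np.uint8) * 255)
    tifffile.imwrite(out / "bulk_mask.tif", masks.bulk.astype(np.uint8) * 255)

    # -- stage: analyze --------------------------------------------------
    try:
        series = dynamics.compartment_series(maps, masks, meta, box)
        baseline = dynamics.night_baseline(series)
        ratio = dynamics.depletion_ratio(series, window_min=cfg.window_min, soil=soil)
        rwu, mean_rwu = dynamics.rwu_series(
            series, diff_min=cfg.diff_min, sg_window=cfg.sg_window, sg_order=cfg.sg_order
        )
        transition = dynamics.detect_transition(
            ratio, baseline, tau=cfg.tau, k_consecutive=cfg.k_consecutive
        )
        rho, n_assoc = dynamics.ratio_rwu_association(ratio, rwu)
        # radial profile: earliest vs latest light-on frame
        day_idx = meta.index[meta.light == 1]
        i0, i1 = day_idx[0], day_idx[-1]
        profile = dynamics.radial_depletion_profile(
            maps[i0].theta,
            maps[i1].theta,
            masks.skeleton,
            pixel_size=box.pixel_size,
            dt_h=(meta.time_min[i1] - meta.time_min[i0]) / 60.0,
        )
    except Exception as err:  # noqa: BLE001
        raise PipelineError("analyze", str(err), last_artifact=out / "skeleton.tif") from err

    series.to_csv(out / "compartments.csv", index=False)
    ratio.to_csv(out / "ratio.csv", index=False)
    rwu.to_csv(out / "rwu.csv", index=False)
    profile.to_csv(out / "profile.csv", index=False)

    transition_payload = {
        "psi_transition_kPa": transition.psi_transition,
        "tau": transition.tau,
        "k_consecutive": transition.k_consecutive,
        "first_window_index": transition.first_window_index,
        "baseline": dataclasses.asdict(baseline),
        "mean_rwu_cm3_h": mean_rwu,
        "spearman_ratio_rwu": None if np.isnan(rho) else rho,
        "n_association_pairs": n_assoc,
        "soil": cfg.soil,
    }
    with open(out / "transition.json", "w") as fh:
        json.dump(transition_payload, fh, indent=2, sort_keys=True)

    provenance = {
        "rhizoflux_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "config": dataclasses.asdict(cfg),
        "warnings": warnings_log,
        "n_frames": int(len(meta)),
        "n_frames_retained": int(len(series)),
        "dilation_radius_px": masks.dilation_radius_px,
    }
    with open(out / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)

    return {
        "out_dir": out,
        "series": series,
        "baseline": baseline,
        "ratio": ratio,
        "rwu": rwu,
        "mean_rwu": mean_rwu,
        "transition": transition,
        "profile": profile,
        "masks": masks,
        "transition_json": out / "transition.json",
        "provenance_json": out / "provenance.json",
    }
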