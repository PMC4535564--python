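"""Pipeline orchestration: configuration, logging, summary statistics and a
reproducible end-to-end run with a hashed artifact manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .constitutive import CORNEA_PARAMS, SCLERA_PARAMS, MaterialParams
from .geometry import EyeGeometryConfig, build_eye_mesh, write_vtk
from .inverse import FitConfig, nsga2_fit
from .pressurize import (PressureLoad, SolverConfig, regional_summary,
                         solve_pressurized)
from .synthetic import LCMorphometry, NoiseModel, lc_table_to_frame, load_lc_table
from .tensile import write_curve_csv

__all__ = ["PipelineConfig", "run_pipeline", "lc_summary_stats",
           "params_to_yaml", "params_from_yaml"]

logger = logging.getLogger("oculomech")


def lc_summary_stats(table: list[LCMorphometry], ddof: int = 0) -> pd.DataFrame:
    """Mean / SD / min / max per LC axis.

    The default population SD (``ddof=0``, n denominator) matches the
    published summary row; pass ``ddof=1`` for the sample SD.
    """
    if not table:
        raise ValueError("empty morphometry table")
    frame = lc_table_to_frame(table)
    rows = {}
    for axis in ("naso_temporal_mm", "longitudinal_mm"):
        v = frame[axis].to_numpy()
        rows[axis] = {"mean": float(v.mean()),
                      "sd": float(v.std(ddof=ddof)),
                      "min": float(v.min()),
                      "max": float(v.max())}
    return pd.DataFrame(rows).T


def params_to_yaml(params: MaterialParams, path) -> None:
    data = {"alpha": params.alpha, "mu_mpa": params.mu, "beta_per_s": params.beta,
            "g_visc_mpa": params.g_visc, "tissue": params.tissue}
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def params_from_yaml(path) -> MaterialParams:
    data = yaml.safe_load(Path(path).read_text())
    return MaterialParams(alpha=data["alpha"], mu=data["mu_mpa"],
                          beta=data["beta_per_s"], g_visc=data["g_visc_mpa"],
                          tissue=data.get("tissue", ""))


@dataclass
class PipelineConfig:
    """End-to-end run configuration.  Stage toggles allow partial runs."""

    seed: int = 0
    out_dir: str = "pipeline_out"
    iop_mmhg: tuple[float, ...] = (10.0, 30.0, 60.0, 100.0)
    noise_force_sd: float = 0.0
    use_fitted_params: bool = False  # False: use the published tissue constants
    fit: FitConfig = field(default_factory=FitConfig)
    geometry: EyeGeometryConfig = field(default_factory=EyeGeometryConfig)
    solver: SolverConfig = field(default_factory=SolverConfig)
    lc_softening: float = 1.0  # LC modulus = softening * sclera modulus
    stages: tuple[str, ...] = ("curves", "fit", "mesh", "pressurize", "summarize")

    def __post_init__(self) -> None:
        if "pressurize" in self.stages and not self.iop_mmhg:
            raise ValueError("IOP list must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "fit" in kwargs:
            kwargs["fit"] = FitConfig(**kwargs["fit"])
        if "geometry" in kwargs:
            kwargs["geometry"] = EyeGeometryConfig(**kwargs["geometry"])
        if "solver" in kwargs:
            kwargs["solver"] = SolverConfig(**kwargs["solver"])
        for key in ("iop_mmhg", "stages"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages and return a manifest of hashed artifacts.

    Deterministic given the seed: rerunning with the same config reproduces
    identical manifest hashes.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, dict] = {}
    t_start = time.time()

    def register(path: Path) -> None:
        manifest[str(path.relative_to(out))] = {"sha256": _sha256(path)}

    def stage(name):
        logger.info("stage=%s seed=%d elapsed=%.1fs", name, config.seed,
                    time.time() - t_start)

    curves = None
    materials = {"sclera": SCLERA_PARAMS, "cornea": CORNEA_PARAMS}

    try:
        if "curves" in config.stages:
            stage("curves")
            curves = synthetic.gen_tensile_dataset(
                noise=NoiseModel(force_sd=config.noise_force_sd, seed=config.seed))
            for c in curves:
                path = out / f"curve_{c.tissue}_{c.rate:g}mmps.csv"
                write_curve_csv(c, path)
                register(path)

        if "fit" in config.stages:
            stage("fit")
            if curves is None:
                raise RuntimeError("fit stage requires the curves stage")
            fitted = {}
            for tissue in ("sclera", "cornea"):
                tissue_curves = [c for c in curves if c.tissue == tissue]
                fit_cfg = FitConfig(**{**asdict(config.fit), "seed": config.seed})
                result = nsga2_fit(tissue_curves, tissue_curves[0].geometry,
                                   fit_cfg, tissue=tissue)
                fitted[tissue] = result.best
                params_to_yaml(result.best, out / f"best_params_{tissue}.yaml")
                register(out / f"best_params_{tissue}.yaml")
                pd.DataFrame(
                    [{"alpha": p.alpha, "mu": p.mu, "beta": p.beta,
                      "g_visc": p.g_visc,
                      **{f"rmse_{i}": float(o) for i, o in enumerate(obj)}}
                     for p, obj in result.pareto_set]
                ).to_csv(out / f"pareto_{tissue}.csv", index=False)
                register(out / f"pareto_{tissue}.csv")
                pd.DataFrame({"generation": np.arange(len(result.convergence)),
                              "best_summed_rmse": result.convergence}
                             ).to_csv(out / f"convergence_{tissue}.csv", index=False)
                register(out / f"convergence_{tissue}.csv")
            if config.use_fitted_params:
                materials = fitted

        mesh = None
        if "mesh" in config.stages:
            stage("mesh")
            mesh = build_eye_mesh(config.geometry)
            write_vtk(out / "eye_mesh.vtk", mesh)
            register(out / "eye_mesh.vtk")

        if "pressurize" in config.stages:
            stage("pressurize")
            if mesh is None:
                mesh = build_eye_mesh(config.geometry)
            sclera = materials["sclera"]
            lc_mus = tuple(config.lc_softening * m for m in sclera.mus)
            lc_params = MaterialParams(alpha=sclera.alpha,
                                       mu=lc_mus if len(lc_mus) > 1 else lc_mus[0],
                                       beta=sclera.beta, g_visc=sclera.g_visc,
                                       tissue="lamina_cribrosa")
            region_materials = {
                "cornea": materials["cornea"],
                "anterior_sclera": materials["sclera"],
                "posterior_sclera": materials["sclera"],
                "lamina_cribrosa": lc_params,
            }
            summaries = []
            for iop in config.iop_mmhg:
                result = solve_pressurized(mesh, region_materials,
                                           PressureLoad(iop), config.solver)
                path = out / f"fields_{iop:g}mmHg.vtk"
                write_vtk(path, mesh,
                          cell_data={"eq_stress_mpa": result.eq_stress,
                                     "eq_strain": result.eq_strain},
                          point_data={"displacement_mm": result.displacement})
                register(path)
                summary = regional_summary(mesh, result)
                summary.insert(0, "iop_mmhg", iop)
                summaries.append(summary)
            combined = pd.concat(summaries, ignore_index=True)
            combined.to_csv(out / "regional_summary.csv", index=False)
            register(out / "regional_summary.csv")

        if "summarize" in config.stages:
            stage("summarize")
            table = load_lc_table()
            stats = lc_summary_stats(table)
            stats.to_csv(out / "lc_summary.csv")
            register(out / "lc_summary.csv")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    stage("done")
    return manifest
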