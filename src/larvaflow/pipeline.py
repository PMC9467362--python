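"""End-to-end orchestration: generate fields, simulate larvae, analyze flow,
and run the settlement statistics for a set of substrates.

``run_pipeline`` executes the full substrate comparison (flat, sub-millimetre
ridges, millimetre ridges) at full or thinned lattice scale, writes per-stage
outputs under a run directory, and returns a manifest describing them.  The
pipeline is deterministic for a fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flowfield import (FluidProperties, OscillatoryForcing, RenderOptics,
                        RidgedCavityFlow, StokesLayerFlow, SubstrateProfile,
                        advect_tracers, render_frames, write_field)
from .flowstats import band_speed, q_field, settling_windows, vortex_regions
from .larvasim import LarvaParams, SimConfig, run_simulation
from .stats import anova_tukey

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "make_fixtures",
           "build_provider", "default_substrates"]

log = logging.getLogger("larvaflow.pipeline")


def default_substrates() -> dict:
    """The three study substrates: flat, 0.25 mm and 2.5 mm ridges (ratio 3)."""
    return {
        "flat": SubstrateProfile.flat(),
        "ridged_0.25": SubstrateProfile.ridged(0.25),
        "ridged_2.5": SubstrateProfile.ridged(2.5),
    }


def build_provider(substrate: SubstrateProfile,
                   forcing: OscillatoryForcing = OscillatoryForcing(),
                   fluid: FluidProperties = FluidProperties()):
    """Analytic flow provider appropriate for a substrate profile."""
    if substrate.kind == "flat":
        return StokesLayerFlow(forcing=forcing, fluid=fluid, substrate=substrate)
    return RidgedCavityFlow(forcing=forcing, fluid=fluid, substrate=substrate)


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run."""

    substrates: dict = dc_field(default_factory=default_substrates)
    forcing: OscillatoryForcing = OscillatoryForcing()
    fluid: FluidProperties = FluidProperties()
    larva: LarvaParams = LarvaParams()
    sim: SimConfig = SimConfig()
    band_height: float = 1.5      # settling-window band [mm]
    analysis_dx: float = 0.1      # grid spacing for flow analysis output [mm]
    analysis_nt: int = 32         # stored time slices for flow analysis
    outdir: str = "runs/latest"
    seed: int = 0
    scale: float = 1.0            # lattice thinning factor in (0, 1]
    write_fields: bool = True

    def __post_init__(self):
        if not 0 < self.scale <= 1:
            raise ValueError("scale must be in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "substrates": {k: json.loads(s.to_json())
                           for k, s in self.substrates.items()},
            "forcing": {"U0": self.forcing.U0, "T": self.forcing.T,
                        "phase0": self.forcing.phase0},
            "fluid": {"nu": self.fluid.nu},
            "larva": {"a": self.larva.a, "b": self.larva.b,
                      "u_ell": self.larva.u_ell, "sd_u": self.larva.sd_u},
            "sim": {"dt": self.sim.dt, "n_positions": self.sim.n_positions,
                    "n_orientations": self.sim.n_orientations,
                    "n_phases": self.sim.n_phases,
                    "seed_height": self.sim.seed_height,
                    "max_time": self.sim.max_time,
                    "integrator": self.sim.integrator},
            "band_height": self.band_height,
            "analysis_dx": self.analysis_dx,
            "analysis_nt": self.analysis_nt,
            "seed": self.seed,
            "scale": self.scale,
        }

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        if "substrates" in raw:
            kwargs["substrates"] = {k: SubstrateProfile(**v)
                                    for k, v in raw["substrates"].items()}
        if "forcing" in raw:
            kwargs["forcing"] = OscillatoryForcing(**raw["forcing"])
        if "fluid" in raw:
            kwargs["fluid"] = FluidProperties(**raw["fluid"])
        if "larva" in raw:
            kwargs["larva"] = LarvaParams(**raw["larva"])
        if "sim" in raw:
            kwargs["sim"] = SimConfig(**raw["sim"])
        for key in ("band_height", "analysis_dx", "analysis_nt", "outdir",
                    "seed", "scale", "write_fields"):
            if key in raw:
                kwargs[key] = raw[key]
        return cls(**kwargs)


@dataclass
class RunManifest:
    """What a pipeline run produced, and from which configuration."""

    config_hash: str
    version: str
    started: str
    finished: str = ""
    outputs: dict = dc_field(default_factory=dict)
    log_path: str = ""

    def to_json(self, path):
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def _analysis_dx(cfg: PipelineConfig, sub: SubstrateProfile) -> float:
    """Analysis grid spacing, refined so a cavity spans >= 10 nodes."""
    if sub.kind == "ridged":
        return min(cfg.analysis_dx, sub.ridge_spacing / 10.0)
    return cfg.analysis_dx


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Run generate-flow -> simulate -> analyze-flow -> stats for every
    substrate in the configuration; write outputs and a manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    manifest = RunManifest(config_hash=config.config_hash(), version=__version__,
                           started=time.strftime("%Y-%m-%dT%H:%M:%S"),
                           log_path=str(log_path))
    sim_cfg = config.sim.scaled(config.scale) if config.scale < 1 else config.sim
    per_phase_frames = []
    summary = {"settlement_pct": {}, "windows": {}, "q_thresh": {},
               "lattice_size": sim_cfg.lattice_size}
    try:
        for name, sub in config.substrates.items():
            t0 = time.time()
            provider = build_provider(sub, config.forcing, config.fluid)
            stage_out = {}

            # --- flow generation & analysis (gridded) -----------------------
            dx = _analysis_dx(config, sub)
            fld = provider.to_grid(dx=dx, nt=config.analysis_nt)
            if config.write_fields:
                fpath = outdir / f"field_{name}.h5"
                write_field(fld, fpath)
                stage_out["field"] = str(fpath)
            qf = q_field(fld)
            series = band_speed(fld, config.band_height,
                                cavities_only=(sub.kind == "ridged"))
            win = settling_windows(fld.t, series, u_ell=config.larva.u_ell,
                                   sd_u=config.larva.sd_u, T=config.forcing.T,
                                   band_height=config.band_height)
            n_regions = int(vortex_regions(qf.max_q_map, qf.q_thresh).max())
            wpath = outdir / f"windows_{name}.json"
            wpath.write_text(json.dumps({
                **win.summary(), "q_thresh": qf.q_thresh,
                "n_vortex_regions_max_map": n_regions}, indent=2))
            stage_out["windows"] = str(wpath)
            summary["windows"][name] = win.summary()
            summary["q_thresh"][name] = qf.q_thresh
            log.info("analyze-flow %s: q_thresh=%.3g 1/s^2, %d vortex regions, "
                     "window fraction %.2f", name, qf.q_thresh, n_regions,
                     win.period_fraction)

            # --- larval simulation (analytic provider) ----------------------
            res = run_simulation(provider, params=config.larva, config=sim_cfg)
            opath = outdir / f"outcomes_{name}.csv"
            res.to_csv(opath)
            stage_out["outcomes"] = str(opath)
            summary["settlement_pct"][name] = res.settlement_fraction
            unresolved_pct = res.fractions()["unresolved"]
            if unresolved_pct > 5.0:
                log.warning("simulate %s: %.1f%% of agents unresolved at "
                            "max_time", name, unresolved_pct)
            pp = res.per_phase_fractions()
            pp["substrate"] = name
            per_phase_frames.append(pp)
            log.info("simulate %s: %d agents, %.2f%% settled (%.1f s)",
                     name, res.n_agents, res.settlement_fraction,
                     time.time() - t0)
            manifest.outputs[name] = stage_out

        # --- cross-substrate statistics ------------------------------------
        per_phase = pd.concat(per_phase_frames, ignore_index=True)
        pp_path = outdir / "per_phase_settlement.csv"
        per_phase.to_csv(pp_path, index=False)
        manifest.outputs["per_phase_settlement"] = str(pp_path)
        if len(config.substrates) >= 2 and config.sim.n_phases >= 2:
            per_phase["prop"] = per_phase["settled_pct"] / 100.0
            anova = anova_tukey(per_phase, "prop", ["substrate"], transform=True)
            apath = outdir / "anova_settlement.json"
            apath.write_text(json.dumps(anova.to_dict(), indent=2, default=str))
            manifest.outputs["anova"] = str(apath)
            summary["anova"] = anova.to_dict()

        spath = outdir / "summary.json"
        spath.write_text(json.dumps(summary, indent=2, default=str))
        manifest.outputs["summary"] = str(spath)
    except Exception as exc:
        log.error("pipeline stage failed: %s", exc)
        raise RuntimeError(f"pipeline failed during substrate processing: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    manifest.finished = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest.to_json(outdir / "manifest.json")
    return manifest


def make_fixtures(outdir, seed: int = 0) -> dict:
    """Write small deterministic fixtures exercising every reader.

    Produces a two-period flat field archive, a single-cavity ridged field
    archive, a 50-particle tracer frame stack, and a 12-agent outcome table.
    Returns a dict of paths and content hashes.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}

    flat = StokesLayerFlow(domain_height=8.0, domain_length=10.0)
    fld = flat.to_grid(dx=0.5, nt=16)
    # extend to two periods of stored samples
    t2 = np.concatenate([fld.t, fld.t + flat.forcing.T])
    from .flowfield import VelocityField
    fld2 = VelocityField(x=fld.x, y=fld.y, t=t2,
                         u=np.concatenate([fld.u, fld.u]),
                         v=np.concatenate([fld.v, fld.v]),
                         solid_mask=fld.solid_mask, forcing=fld.forcing,
                         substrate=fld.substrate, nu=fld.nu)
    p = outdir / "flat_field_2periods.h5"
    write_field(fld2, p)
    out["flat_field"] = str(p)

    ridged = RidgedCavityFlow(
        substrate=SubstrateProfile.ridged(2.5, n_ridges=1), domain_height=8.0)
    p = outdir / "ridged_field_1cavity.h5"
    write_field(ridged.to_grid(dx=0.25, nt=8), p)
    out["ridged_field"] = str(p)

    tracks = advect_tracers(flat, n=50, seed=seed, duration=0.5, dt=1.0 / 90.0)
    stack = render_frames(tracks, RenderOptics(noise_level=1.0), seed=seed)
    p = outdir / "tracer_stack.tif"
    stack.to_tiff(p)
    out["tracer_stack"] = str(p)
    p = outdir / "tracer_tracks.csv"
    tracks.to_csv(p)
    out["tracer_tracks"] = str(p)

    res = run_simulation(flat, config=SimConfig(n_positions=3, n_orientations=4,
                                                n_phases=1, seed_height=4.0,
                                                max_time=10.0))
    p = outdir / "outcomes_12agents.csv"
    res.to_csv(p)
    out["outcomes"] = str(p)

    hashes = {k: hashlib.sha256(Path(v).read_bytes()).hexdigest()[:12]
              for k, v in out.items()}
    (outdir / "fixtures.json").write_text(json.dumps(
        {"paths": out, "sha256_12": hashes, "seed": seed}, indent=2))
    return {"paths": out, "hashes": hashes}
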