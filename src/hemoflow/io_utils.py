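"""Configuration, file round-tripping, logging and the pipeline driver.

A single YAML config file with sections (geometry, rheology, solver,
waveform, stats, output) drives the end-to-end pipeline: generate geometry
-> simulate with both rheology models on the identical grid -> post-process
wall indices -> paired comparison.  Field snapshots go to legacy-VTK ASCII
structured grids (one file per stored timepoint plus an index manifest),
wall data and reports to CSV, and every run writes a JSON manifest with
config snapshot, seeds, file inventory and checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .geometry import StenosisSpec, build_geometry, generate_mesh
from .rheology import RheologyParams, calibrated_params
from .solver import SimulationConfig, FlowField, run_pulsatile_simulation
from .synth import coronary_waveform, synthetic_vessel, synthetic_cohort_flows
from . import indices as idx
from . import stats as st

__all__ = ["default_config", "load_config", "dump_config", "write_vtk",
           "read_vtk", "write_wall_csv", "read_wall_csv", "write_geometry_csv",
           "run_pipeline", "run_synthetic_cohort"]

log = logging.getLogger("hemoflow")


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


def default_config() -> dict:
    """Complete default configuration for the idealized-artery pipeline."""
    return {
        "geometry": {
            "D": 0.003, "DS": 0.40, "L_lesion": 0.003,
            "L_inlet": 0.015, "L_outlet": 0.030,
            # clinical reading (D_min = (1-DS) D): the idealized baseline
            # results are only consistent with this convention
            "mld_convention": "clinical", "n_axial": 384,
        },
        "rheology": {
            "mu_newtonian": 0.0035, "rho": 1060.0, "H": 0.45,
            "quemada_parameter_set": "calibrated",   # or "literature"
            "gamma_floor": 1e-3,
        },
        "solver": {
            "mode": "planar", "n_cycles": 3, "outputs_per_cycle": 64,
            "cycle_period": 0.8, "dt": None, "mean_inlet_flow": 0.83e-6,
            "outlet_resistance": 0.0, "resolution": 28, "wall_layers": 10,
        },
        "waveform": {
            "systolic_fraction": 0.44, "diastolic_dominance": 2.0,
            "baseline": 0.4,
        },
        "stats": {
            "fraction": 0.015, "reps": 10000, "seed": 0, "statistic": "median",
        },
        "output": {"write_vtk": False, "outdir": "hemoflow_run"},
    }


def _merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path) -> dict:
    """Read a YAML config and merge it over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(default_config(), user)


def dump_config(config: dict, path=None) -> str:
    text = yaml.safe_dump(config, sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


def rheology_from_config(config: dict, model: str) -> RheologyParams:
    rc = config["rheology"]
    common = dict(mu_newtonian=rc["mu_newtonian"], rho=rc["rho"], H=rc["H"],
                  gamma_floor=rc["gamma_floor"])
    if model == "newtonian":
        return RheologyParams(model="newtonian", **common)
    if rc.get("quemada_parameter_set", "calibrated") == "calibrated":
        return calibrated_params(model="quemada", **common)
    return RheologyParams(model="quemada", **common)


# ---------------------------------------------------------------------------
# legacy VTK ASCII structured grid (no VTK library in the environment)
# ---------------------------------------------------------------------------


def write_vtk(flow: FlowField, path, time_index: int = 0) -> None:
    """One stored timepoint of a FlowField as a legacy-VTK structured grid."""
    k = time_index
    Nx, Ny = flow.u.shape[1], flow.u.shape[2]
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(f"hemoflow {flow.mode} t={flow.times[k]:.9e}\n")
        fh.write("ASCII\nDATASET STRUCTURED_GRID\n")
        fh.write(f"DIMENSIONS {Nx} {Ny} 1\n")
        fh.write(f"POINTS {Nx * Ny} double\n")
        for j in range(Ny):
            for i in range(Nx):
                fh.write(f"{flow.x[i]:.9e} {flow.y[i, j]:.9e} 0.0\n")
        fh.write(f"POINT_DATA {Nx * Ny}\n")
        for name, arr in (("u", flow.u[k]), ("v", flow.v[k]), ("p", flow.p[k]),
                          ("mu", flow.mu[k]), ("gamma_dot", flow.gamma_dot[k])):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for j in range(Ny):
                for i in range(Nx):
                    fh.write(f"{arr[i, j]:.9e}\n")


def read_vtk(path) -> dict:
    """Parse a structured grid written by :func:`write_vtk`.

    Returns dict with 'points' (n, 3) and one (Nx, Ny) array per scalar.
    Raises ``ValueError`` naming the offending line on truncated/malformed
    input.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    try:
        if not lines[0].startswith("# vtk"):
            raise ValueError(f"{path}: line 1: not a VTK file")
        dims_line = next(ln for ln in lines if ln.startswith("DIMENSIONS"))
        Nx, Ny, _ = (int(t) for t in dims_line.split()[1:])
        ip = lines.index(next(ln for ln in lines if ln.startswith("POINTS")))
        npts = int(lines[ip].split()[1])
        pts = np.array([[float(t) for t in lines[ip + 1 + n].split()]
                        for n in range(npts)])
        out = {"points": pts, "dims": (Nx, Ny)}
        pos = ip + 1 + npts
        while pos < len(lines):
            if lines[pos].startswith("SCALARS"):
                name = lines[pos].split()[1]
                vals = np.array([float(lines[pos + 2 + n]) for n in range(npts)])
                out[name] = vals.reshape(Ny, Nx).T
                pos += 2 + npts
            else:
                pos += 1
        return out
    except (IndexError, StopIteration, ValueError) as err:
        if isinstance(err, ValueError) and str(err).startswith(str(path)):
            raise
        raise ValueError(f"{path}: truncated or malformed VTK file ({err})") from err


def write_flowfield(flow: FlowField, outdir) -> list:
    """All stored timepoints as VTK files plus an index manifest; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k in range(flow.n_times):
        p = outdir / f"field_{k:04d}.vtk"
        write_vtk(flow, p, time_index=k)
        paths.append(p)
    index = outdir / "fields_index.json"
    index.write_text(json.dumps(
        {"times": flow.times.tolist(), "files": [p.name for p in paths],
         "mode": flow.mode}, indent=1))
    paths.append(index)
    return paths


# ---------------------------------------------------------------------------
# wall / geometry CSV
# ---------------------------------------------------------------------------


def wall_dataframe(wall: idx.WallField) -> pd.DataFrame:
    df = pd.DataFrame({
        "x_m": wall.x, "s_m": wall.s,
        "taess_Pa": idx.time_average_ess(wall),
        "essg_Pa_per_mm": idx.compute_essg(wall),
        "osi": idx.compute_osi(wall),
        "area_w": wall.area,
        "wall_mu_mean_Pas": wall.wall_mu.mean(axis=0),
    })
    if wall.segment is not None:
        df["segment"] = wall.segment
    return df


def write_wall_csv(wall: idx.WallField, path) -> None:
    """WallField static indices + full signed ESS series, full precision."""
    df = wall_dataframe(wall)
    for k, t in enumerate(wall.times):
        df[f"ess_t{k}"] = wall.ess[k]
    df.to_csv(path, index=False, float_format="%.17g")


def read_wall_csv(path) -> pd.DataFrame:
    # pandas' fast float parser is not correctly rounded; the wall CSV
    # contract is an exact round-trip
    return pd.read_csv(path, float_precision="round_trip")


def write_geometry_csv(geom, path, spec: Optional[StenosisSpec] = None) -> None:
    spec = spec or geom.spec
    with open(path, "w") as fh:
        if spec is not None:
            fh.write(f"# D={spec.D} DS={spec.DS} L_lesion={spec.L_lesion} "
                     f"L_inlet={spec.L_inlet} L_outlet={spec.L_outlet} "
                     f"mld_convention={spec.mld_convention}\n")
        pd.DataFrame({"x_m": geom.x, "r_m": geom.r}).to_csv(
            fh, index=False, float_format="%.17g")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: dict, outdir=None) -> dict:
    """Geometry -> two rheology runs -> indices -> paired comparison.

    Returns the run manifest (also written to ``manifest.json``); any stage
    failure aborts with the stage name, leaving a partial manifest on disk.
    """
    t_start = time.time()
    outdir = Path(outdir or config["output"]["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config, "started": time.strftime("%Y-%m-%d %H:%M:%S"),
                "stages": [], "files": {}}

    def fail(stage, err):
        manifest["failed_stage"] = stage
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err

    def done(stage):
        manifest["stages"].append(stage)
        log.info("stage %s done (%.1f s elapsed)", stage, time.time() - t_start)

    gc = config["geometry"]
    try:
        spec = StenosisSpec(D=gc["D"], DS=gc["DS"], L_lesion=gc["L_lesion"],
                            L_inlet=gc["L_inlet"], L_outlet=gc["L_outlet"],
                            mld_convention=gc["mld_convention"])
        geom = build_geometry(spec, n_axial=gc["n_axial"])
        sc = config["solver"]
        generate_mesh(geom, resolution=sc["resolution"], wall_layers=sc["wall_layers"])
        write_geometry_csv(geom, outdir / "geometry.csv", spec)
        manifest["files"]["geometry.csv"] = _checksum(outdir / "geometry.csv")
    except Exception as err:
        fail("generate-geometry", err)
    done("generate-geometry")

    sc = config["solver"]
    simcfg = SimulationConfig(
        n_cycles=sc["n_cycles"], outputs_per_cycle=sc["outputs_per_cycle"],
        cycle_period=sc["cycle_period"], dt=sc["dt"],
        mean_inlet_flow=sc["mean_inlet_flow"],
        outlet_resistance=sc["outlet_resistance"], mode=sc["mode"],
        resolution=sc["resolution"], wall_layers=sc["wall_layers"],
        seed=config["stats"]["seed"])
    wc = config["waveform"]
    waveform = coronary_waveform(
        T=sc["cycle_period"], mean_flow=sc["mean_inlet_flow"],
        systolic_fraction=wc["systolic_fraction"],
        diastolic_dominance=wc["diastolic_dominance"], baseline=wc["baseline"])

    flows, walls = {}, {}
    for model in ("newtonian", "quemada"):
        try:
            rheo = rheology_from_config(config, model)
            flow = run_pulsatile_simulation(geom, rheo, waveform, simcfg)
            wall = idx.compute_wall_field(flow, geom, spec)
            flows[model], walls[model] = flow, wall
            write_wall_csv(wall, outdir / f"wall_{model}.csv")
            manifest["files"][f"wall_{model}.csv"] = _checksum(outdir / f"wall_{model}.csv")
            if config["output"].get("write_vtk"):
                for p in write_flowfield(flow, outdir / f"fields_{model}"):
                    manifest["files"][str(p.relative_to(outdir))] = _checksum(p)
            manifest[f"diagnostics_{model}"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in flow.diagnostics.items()}
        except Exception as err:
            fail(f"simulate-{model}", err)
        done(f"simulate-{model}")

    try:
        table = idx.segment_table(walls["newtonian"], walls["quemada"])
        table.to_csv(outdir / "segment_table.csv", float_format="%.6f")
        manifest["files"]["segment_table.csv"] = _checksum(outdir / "segment_table.csv")
        lbv = idx.lbv_summary(flows["quemada"])
        manifest["lbv"] = {"mean_lbv": lbv["mean_lbv"], "peak_lbv": lbv["peak_lbv"],
                           "peak_time": lbv["peak_time"]}
        manifest["low_ess_area_pct"] = {
            m: idx.low_ess_area_fraction(walls[m]) for m in walls}
    except Exception as err:
        fail("postprocess", err)
    done("postprocess")

    try:
        stc = config["stats"]
        rep = st.compare_fields(
            idx.time_average_ess(walls["newtonian"]),
            idx.time_average_ess(walls["quemada"]),
            index_name="time-averaged ESS", fraction=stc["fraction"],
            reps=stc["reps"], seed=stc["seed"], statistic=stc["statistic"])
        (outdir / "comparison.txt").write_text(rep.summary() + "\n")
        pd.DataFrame([rep.to_dict()]).to_csv(outdir / "comparison.csv", index=False)
        manifest["files"]["comparison.csv"] = _checksum(outdir / "comparison.csv")
        manifest["comparison"] = rep.to_dict()
    except Exception as err:
        fail("compare", err)
    done("compare")

    manifest["elapsed_s"] = time.time() - t_start
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    manifest["files"]["manifest.json"] = "self"
    return manifest


def run_synthetic_cohort(n_vessels: int = 16, n_axial: int = 48,
                         resolution: int = 10, wall_layers: int = 4,
                         n_cycles: int = 2, outputs_per_cycle: int = 32,
                         amplitude: float = 0.1) -> pd.DataFrame:
    """Paired Newtonian/Quemada runs on the 16-vessel synthetic cohort.

    Vessels use seeds 1..n_vessels; per-vessel mean inlet flows are seeded
    draws from Normal(0.83, 0.44) mL/s truncated at 0.2 (the cohort scale of
    patient coronary flow).  Axisymmetric tubes with smooth seeded lumen
    perturbations stand in for the imaging-derived patient reconstructions;
    grid and cycle counts are deliberately coarse (qualitative cohort-level
    checks, not per-vessel accuracy).  Returns one row per vessel with the
    paired index summaries.
    """
    flows_q = synthetic_cohort_flows(n=n_vessels)
    rows = []
    for k in range(n_vessels):
        seed = k + 1
        vessel = synthetic_vessel(seed=seed, amplitude=amplitude, n_axial=n_axial)
        geom = vessel.geometry
        generate_mesh(geom, resolution=resolution, wall_layers=wall_layers)
        cfg = SimulationConfig(
            n_cycles=n_cycles, outputs_per_cycle=outputs_per_cycle,
            mean_inlet_flow=flows_q[k], mode="axisymmetric",
            resolution=resolution, wall_layers=wall_layers, seed=seed)
        waveform = coronary_waveform(T=cfg.cycle_period, mean_flow=flows_q[k])
        row = {"seed": seed, "mean_flow_mL_s": flows_q[k] * 1e6}
        for model in ("newtonian", "quemada"):
            rheo = (RheologyParams(model="newtonian") if model == "newtonian"
                    else calibrated_params())
            flow = run_pulsatile_simulation(geom, rheo, waveform, cfg)
            wall = idx.compute_wall_field(flow, geom)
            row[f"median_taess_{model}"] = float(
                np.median(idx.time_average_ess(wall)))
            row[f"low_ess_area_{model}"] = idx.low_ess_area_fraction(wall)
            if model == "quemada":
                s = idx.lbv_summary(flow)
                row["mean_lbv"] = s["mean_lbv"]
                row["peak_lbv"] = s["peak_lbv"]
                row["peak_lbv_nadir_dist_s"] = idx.peak_lbv_nadir_distance(flow)
        rows.append(row)
    return pd.DataFrame(rows).set_index("seed")
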