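"""End-to-end orchestration: build -> relax -> equilibrate -> produce ->
analyze, for one run or for the standard four-condition comparison
(no robot / static robot / slow rotation / fast rotation)."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import scene_from_config
from .engine import Engine, InstabilityError
from .observables import (ObservableSeries, bending_stiffness,
                          lipid_lateral_diffusion, msd, penetrated_series,
                          pore_area_series, stretching_modulus)
from .params import RunConfig, config_to_dict, __version__
from .system import Trajectory, write_trajectory_xyz
from .forcefield import BeadKind

#: the four study conditions and their rotation frequencies (1/tau)
CONDITIONS = {
    "no_robot": {"robot_enabled": False, "rotation_frequency": 0.0},
    "static": {"robot_enabled": True, "robot_static": True},
    "f15000": {"robot_enabled": True, "robot_static": False,
               "rotation_frequency": 1.0 / 15000.0},
    "f5000": {"robot_enabled": True, "robot_static": False,
              "rotation_frequency": 1.0 / 5000.0},
}


def run_one(cfg: RunConfig, equil_steps: int = 0,
            minimize_steps: int = 300) -> tuple[Trajectory, dict]:
    """Build the configured scene and run it; returns (trajectory, info).

    ``equil_steps`` are integrated before the recorded production phase
    (with the robot held static so every condition starts from the same
    relaxed contact geometry).
    """
    sysm = scene_from_config(cfg)
    eng = Engine(sysm, cfg.forcefield, cfg.protocol)
    if minimize_steps:
        eng.minimize(minimize_steps)
    if equil_steps:
        was_static = cfg.protocol.robot_static
        cfg.protocol.robot_static = True
        eng.run(equil_steps, frame_interval=max(equil_steps, 1),
                sample_interval=max(equil_steps // 10, 1))
        cfg.protocol.robot_static = was_static
        # production clock starts after equilibration
        eng.state.time = 0.0
        eng.state.step = 0
        eng.system.images[:] = 0
        if eng.system.rigid_group is not None:
            eng.drive_robot(0.0)
    traj, obs = eng.run(cfg.protocol.n_steps)
    info = {
        "observables": obs.as_dict(),
        "final_temperature": eng.kinetic_temperature(),
        "n_beads": sysm.n_beads,
    }
    return traj, info


def analyze_run(traj: Trajectory, temperature: float = 1.1,
                pore_cell: float = 2.0, pore_threshold: float = 0.25,
                margin: float = 1.0) -> list[ObservableSeries]:
    """Standard per-trajectory series: pore area, penetrated count,
    transmembrane cargo MSD and box area."""
    out = [pore_area_series(traj, cell=pore_cell,
                            threshold_fraction=pore_threshold),
           penetrated_series(traj, margin=margin)]
    k0 = traj.frames[0].kinds
    cargo = k0 == BeadKind.CARGO
    if cargo.any() and len(traj) > 2:
        out.append(msd(traj, cargo, axis_mask=(0, 0, 1)))
        out[-1].name = "cargo_msd_z"
    areas = traj.box_areas
    out.append(ObservableSeries("box_area", traj.times, areas,
                                units="sigma^2"))
    return out


def series_to_frame(series: list[ObservableSeries],
                    replica: int | None = None) -> pd.DataFrame:
    rows = []
    for s in series:
        rep = replica if replica is not None else s.replica
        for t, v in zip(s.times, s.values):
            rows.append((s.name, t, v, s.units, rep))
    return pd.DataFrame(rows, columns=["series", "time", "value", "units",
                                       "replica"])


def _file_digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def pipeline(cfg: RunConfig, outdir: str | Path,
             conditions: list[str] | None = None,
             replicas: int = 1, equil_steps: int = 0,
             write_xyz: bool = True) -> dict:
    """Run the configured conditions and write the report bundle.

    Per condition and replica: an observable CSV (and optionally the
    extended-XYZ trajectory); at the end a summary table and a manifest.
    Partial results survive a failing stage; the failure is recorded in
    the manifest and re-raised.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if conditions is None:
        conditions = list(CONDITIONS)
    unknown = set(conditions) - set(CONDITIONS)
    if unknown:
        raise ValueError(f"unknown condition(s): {sorted(unknown)}")
    t_start = time.time()
    summary_rows = []
    failures = []
    outputs = {}
    for cond in conditions:
        for rep in range(replicas):
            ccfg = RunConfig(
                forcefield=replace(cfg.forcefield),
                protocol=replace(cfg.protocol, **CONDITIONS[cond],
                                 seed=cfg.protocol.seed + rep),
                units=cfg.units, builder=dict(cfg.builder))
            tag = f"{cond}_r{rep}"
            try:
                traj, info = run_one(ccfg, equil_steps=equil_steps)
            except InstabilityError as err:
                failures.append({"condition": cond, "replica": rep,
                                 "error": str(err)})
                if err.trajectory is not None and write_xyz:
                    write_trajectory_xyz(err.trajectory,
                                         outdir / f"{tag}_partial.xyz")
                continue
            series = analyze_run(traj, temperature=ccfg.protocol.temperature)
            df = series_to_frame(series, replica=rep)
            csv_path = outdir / f"{tag}.csv"
            df.to_csv(csv_path, index=False)
            outputs[tag] = {"csv": csv_path.name,
                            "csv_sha256": _file_digest(csv_path)}
            if write_xyz:
                xyz_path = outdir / f"{tag}.xyz"
                write_trajectory_xyz(traj, xyz_path)
                outputs[tag]["xyz"] = xyz_path.name
            by_name = {s.name: s for s in series}
            summary_rows.append({
                "condition": cond, "replica": rep,
                "final_pore_area": by_name["pore_area"].values[-1],
                "final_penetrated": by_name["penetrated_count"].values[-1],
                "mean_pore_area": float(np.mean(by_name["pore_area"].values)),
                "final_temperature": info["final_temperature"],
                "n_beads": info["n_beads"],
            })
    summary = pd.DataFrame(summary_rows)
    summary.to_csv(outdir / "summary.csv", index=False)
    manifest = {
        "code_version": __version__,
        "seed": cfg.protocol.seed,
        "replicas": replicas,
        "conditions": conditions,
        "equil_steps": equil_steps,
        "config": config_to_dict(cfg),
        "outputs": outputs,
        "failures": failures,
        "wall_time_s": time.time() - t_start,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    if failures:
        raise InstabilityError(
            f"{len(failures)} run(s) failed; partial results in {outdir}")
    return manifest


def _one_membrane_run(cfg: RunConfig, seed: int, equil_steps: int,
                      production_steps: int, frame_interval: int):
    """One tensionless membrane-only run (build, relax, equilibrate,
    produce); returns (trajectory, scalar observables, n_beads)."""
    from .builder import build_bilayer

    ccfg = RunConfig(
        forcefield=replace(cfg.forcefield),
        protocol=replace(cfg.protocol, robot_enabled=False, cargo_count=0,
                         frame_interval=frame_interval, seed=seed,
                         n_steps=production_steps),
        units=cfg.units, builder=dict(cfg.builder))
    b = ccfg.builder
    # pre-seed thermal undulations (literature-range moduli guess) so
    # the slowest height modes start near equilibrium amplitude
    sysm = build_bilayer(b.get("nx", 20), b.get("ny", 20),
                         b.get("area_per_lipid", 1.2),
                         ccfg.protocol.box_z, seed,
                         ccfg.protocol.temperature,
                         undulation_spectrum=b.get("undulation_spectrum",
                                                   (10.0, 1.5)))
    eng = Engine(sysm, ccfg.forcefield, ccfg.protocol)
    eng.minimize(300)
    eng.run(equil_steps, frame_interval=max(equil_steps, 1),
            sample_interval=200)
    eng.state.time = 0.0
    eng.state.step = 0
    eng.system.images[:] = 0
    traj, obs = eng.run(production_steps, sample_interval=100)
    return traj, obs, sysm.n_beads


def calibration_run(cfg: RunConfig, equil_steps: int = 30_000,
                    production_steps: int = 200_000,
                    frame_interval: int = 500,
                    replicas: int = 1) -> dict:
    """Tensionless membrane runs and the three calibration numbers:
    bending stiffness, stretching modulus, lipid lateral diffusion.

    The bilayer is simulated without robot or cargo under the Langevin
    thermostat and the zero-tension barostat; elasticity comes from the
    production-phase height spectrum and area fluctuations, diffusion
    from the in-plane head-bead MSD.

    With ``replicas > 1``, independent seeds are pooled: the slowest
    undulation mode decorrelates over hundreds of tau, so independent
    starts reduce the estimator variance far faster than one long run.
    Spectra and area series are pooled across replicas; the diffusion
    coefficient is averaged.
    """
    T = cfg.protocol.temperature
    base = cfg.protocol.seed
    trajs, obss, n_beads = [], [], 0
    for r in range(replicas):
        traj, obs, n_beads = _one_membrane_run(
            cfg, base + 1009 * r, equil_steps, production_steps,
            frame_interval)
        trajs.append(traj)
        obss.append(obs)

    # pooled spectrum: concatenate frames (times shifted to stay
    # strictly increasing)
    pooled = Trajectory()
    t0 = 0.0
    for traj in trajs:
        for fr in traj.frames:
            fr.time = t0 + fr.time
            pooled.frames.append(fr)
        t0 = pooled.frames[-1].time + 1.0
    kappa = bending_stiffness(pooled, n_cells=16, temperature=T)
    areas = np.concatenate([np.asarray(o.box_area) for o in obss])
    ka = stretching_modulus(areas, temperature=T,
                            window_length=len(obss[0].box_area))
    Ds = [lipid_lateral_diffusion(traj) for traj in trajs]
    D_mean = float(np.mean([d["D"] for d in Ds]))
    tension = np.concatenate([np.asarray(o.tension) for o in obss])
    blocks = [b.mean() for b in np.array_split(tension, 10 * replicas)]
    tension_se = float(np.std(blocks) / np.sqrt(len(blocks)))
    temp = np.concatenate([np.asarray(o.kinetic_temperature) for o in obss])
    return {
        "kappa": kappa, "K_A": ka,
        "D_lipid": {"D": D_mean,
                    "per_replica": [float(d["D"]) for d in Ds]},
        "mean_temperature": float(temp.mean()),
        "mean_tension": float(tension.mean()),
        "tension_se": tension_se,
        "n_frames": len(pooled),
        "n_beads": n_beads,
        "replicas": replicas,
    }
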