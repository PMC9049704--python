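"""File formats: run configurations (YAML), trajectory/PMF tables (CSV),
stage summaries (JSON), bead-model structures (PDB via biotite), and melt
curves (CSV).

All CSV outputs carry a comment header line with the configuration hash and
master seed so a result can be traced back to the exact inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from biotite.structure import Atom, array as atom_array
from biotite.structure.io.pdb import PDBFile

from .asmd import ASMDConfig, PMFProfile, StageEnsemble
from .dynamics import SteeringSchedule, ThermostatParams
from .melt import MeltCurve
from .systems import (ForceProvider, ParticleSystem, make_analytic_system,
                      make_hairpin_system)

_ROLE_TO_ATOM = {"backbone": "CA", "sidechain": "CB", "donor_h": "HN",
                 "acceptor_o": "O", "anchor": "CA", "bead": "CA", "solvent": "OW"}
_ROLE_TO_ELEMENT = {"backbone": "C", "sidechain": "C", "donor_h": "H",
                    "acceptor_o": "O", "anchor": "C", "bead": "C", "solvent": "O"}


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    text = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "system" not in cfg:
        raise ValueError("config must be a mapping with a 'system' section")
    return cfg


def build_from_config(cfg: dict) -> tuple[ParticleSystem, ForceProvider, ASMDConfig]:
    """Instantiate system, force provider and run configuration from a
    parsed config mapping."""
    sys_cfg = cfg["system"]
    kind = sys_cfg.get("kind", "hairpin")
    if kind == "hairpin":
        system, provider = make_hairpin_system(
            sequence=sys_cfg.get("sequence", "SWTWEGNKWTWK"),
            mutations=sys_cfg.get("mutations", []))
        anchor = provider.backbone_index[1]
        pulled = provider.backbone_index[12]
    else:
        system, provider = make_analytic_system(kind, **sys_cfg.get("params", {}))
        anchor, pulled = 0, 1

    sched_cfg = dict(cfg.get("schedule", {}))
    if "spring_k" not in sched_cfg:
        raise ValueError("schedule.spring_k is a mandatory config field")
    schedule = SteeringSchedule(
        anchor_particle=sched_cfg.pop("anchor_particle", anchor),
        pulled_particle=sched_cfg.pop("pulled_particle", pulled),
        **sched_cfg)
    thermostat = ThermostatParams(**cfg.get("thermostat", {}))
    asmd_cfg = cfg.get("asmd", {})
    config = ASMDConfig(schedule=schedule, thermostat=thermostat, **asmd_cfg)
    return system, provider, config


def _header(cfg_hash: str, seed: int) -> str:
    return f"# config_hash={cfg_hash} seed={seed}\n"


def write_pmf_csv(profile: PMFProfile, path: str | Path,
                  cfg_hash: str = "none", seed: int = 0) -> None:
    df = pd.DataFrame({"r_ee": profile.r_grid, "delta_A": profile.delta_A})
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash, seed))
        df.to_csv(fh, index=False)


def read_pmf_csv(path: str | Path) -> PMFProfile:
    df = pd.read_csv(path, comment="#")
    return PMFProfile(r_grid=df["r_ee"].to_numpy(),
                      delta_A=df["delta_A"].to_numpy())


def write_stages_json(ensembles: Sequence[StageEnsemble], path: str | Path,
                      cfg_hash: str = "none", seed: int = 0) -> None:
    payload = {
        "config_hash": cfg_hash,
        "seed": seed,
        "stages": [{
            "stage_index": e.stage_index,
            "boundaries": list(e.boundaries),
            "final_works": e.final_works.tolist(),
            "selected_index": e.selected_index,
            "work_spread": e.work_spread,
            "qc_flag": bool(e.qc_flag),
            "delta_A_stage": float(e.je_curve[-1]),
        } for e in ensembles],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def write_stage_work_csv(ensemble: StageEnsemble, path: str | Path,
                         cfg_hash: str = "none", seed: int = 0) -> None:
    """Per-stage work curves: one row per logged point per trajectory."""
    rows = []
    for i, t in enumerate(ensemble.trajectories):
        rows.append(pd.DataFrame({
            "traj": i, "time": t.times, "r_center": t.restraint_center,
            "r_ee": t.r_ee, "work": t.work}))
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash, seed))
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def write_stage_frames_csv(ensemble: StageEnsemble, path: str | Path,
                           cfg_hash: str = "none", seed: int = 0) -> None:
    """Flat-table coordinate dump: traj, frame, time, r_ee, work, then
    x0,y0,z0,x1,... for every particle."""
    rows = []
    for i, t in enumerate(ensemble.trajectories):
        if t.frames is None:
            raise ValueError("ensemble has no stored frames")
        flat = t.frames.reshape(len(t.times), -1)
        df = pd.DataFrame(flat, columns=[f"{ax}{k}" for k in range(flat.shape[1] // 3)
                                         for ax in ("x", "y", "z")])
        df.insert(0, "work", t.work)
        df.insert(0, "r_ee", t.r_ee)
        df.insert(0, "time", t.times)
        df.insert(0, "frame", np.arange(len(t.times)))
        df.insert(0, "traj", i)
        rows.append(df)
    with open(path, "w") as fh:
        fh.write(_header(cfg_hash, seed))
        pd.concat(rows, ignore_index=True).to_csv(fh, index=False)


def write_bead_pdb(system: ParticleSystem, path: str | Path) -> None:
    """Write a bead model as HETATM records with 1-based residue numbering."""
    atoms = []
    for i, lab in enumerate(system.particle_labels):
        atoms.append(Atom(
            coord=system.positions[i],
            atom_name=_ROLE_TO_ATOM.get(lab.role, "X"),
            res_id=lab.residue,
            res_name="BEA",
            chain_id="A",
            element=_ROLE_TO_ELEMENT.get(lab.role, "C"),
            hetero=True,
        ))
    arr = atom_array(atoms)
    pdb = PDBFile()
    pdb.set_structure(arr)
    pdb.write(str(path))


def read_bead_pdb(path: str | Path) -> tuple[np.ndarray, list[int], list[str]]:
    """Read a bead-model PDB; returns positions, residue ids and atom names."""
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=1)
    return (np.asarray(arr.coord, dtype=float), arr.res_id.tolist(),
            arr.atom_name.tolist())


def read_melt_csv(path: str | Path) -> dict[str, list[MeltCurve]]:
    """Melt-curve CSV with columns temperature_C, signal_mdeg and optional
    replicate and name columns; returns replicate lists keyed by name."""
    df = pd.read_csv(path, comment="#")
    required = {"temperature_C", "signal_mdeg"}
    if not required <= set(df.columns):
        raise ValueError(f"melt CSV needs columns {sorted(required)}")
    if "name" not in df.columns:
        df["name"] = "curve"
    if "replicate" not in df.columns:
        df["replicate"] = 1
    out: dict[str, list[MeltCurve]] = {}
    for (name, rep), sub in df.groupby(["name", "replicate"]):
        sub = sub.sort_values("temperature_C")
        out.setdefault(str(name), []).append(MeltCurve(
            temperatures=sub["temperature_C"].to_numpy(),
            signal=sub["signal_mdeg"].to_numpy(),
            replicate=str(rep)))
    return out
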