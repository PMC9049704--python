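"""Adaptive steered molecular dynamics driver.

The reaction coordinate is split into contiguous stages.  In each stage an
ensemble of constant-velocity pulling trajectories is launched from a single
parent configuration with Maxwell–Boltzmann-randomized velocities; the
free-energy increment is estimated from the nonequilibrium work by the
Jarzynski equality,

    ΔA = −k_BT · ln ⟨exp(−W/k_BT)⟩,

evaluated in the log domain so large works cannot overflow.  The ensemble is
then contracted: the trajectory whose final work lies closest to the
Jarzynski average seeds the next stage.  Stage curves are chained with
offset continuity and the assembled potential of mean force is reported
relative to its minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB
from .dynamics import (SteeringSchedule, ThermostatParams, TrajectoryRecord,
                       end_to_end, maxwell_boltzmann_velocities, run_smd_ensemble)
from .systems import ForceProvider, ParticleSystem


@dataclass
class ASMDConfig:
    schedule: SteeringSchedule
    thermostat: ThermostatParams
    n_stages: int = 20
    n_traj_per_stage: int = 100
    master_seed: int = 0
    work_spread_qc: float = 5.0     # kcal mol⁻¹, flag stages spreading beyond this

    def __post_init__(self):
        if self.n_stages < 1 or self.n_traj_per_stage < 1:
            raise ValueError("need at least one stage and one trajectory per stage")

    @property
    def temperature(self) -> float:
        return self.thermostat.temperature


@dataclass
class StageEnsemble:
    stage_index: int
    boundaries: tuple[float, float]
    trajectories: list[TrajectoryRecord]
    je_r: np.ndarray          # restraint-center grid within the stage
    je_curve: np.ndarray      # Jarzynski estimate vs r, 0 at the stage start
    selected_index: int
    work_spread: float
    qc_flag: bool = False

    @property
    def final_works(self) -> np.ndarray:
        return np.array([t.final_work for t in self.trajectories])


@dataclass
class PMFProfile:
    r_grid: np.ndarray
    delta_A: np.ndarray       # kcal mol⁻¹, min-subtracted
    stage_of_point: np.ndarray = field(default=None)

    def at(self, r_values) -> np.ndarray:
        return delta_A_at(self, r_values)


def partition_stages(r_start: float, r_end: float, n_stages: int
                     ) -> list[tuple[float, float]]:
    """Evenly partition [r_start, r_end] into contiguous stage windows."""
    if r_end <= r_start:
        raise ValueError("r_end must exceed r_start")
    if n_stages < 1:
        raise ValueError("n_stages must be ≥ 1")
    edges = np.linspace(r_start, r_end, n_stages + 1)
    return [(float(edges[i]), float(edges[i + 1])) for i in range(n_stages)]


def jarzynski_average(final_works: Sequence[float], temperature: float) -> float:
    """Exponential work average −k_BT·ln⟨e^{−βW}⟩, overflow-safe.

    Satisfies min(W) ≤ result ≤ mean(W) (Jensen's inequality).
    """
    works = np.asarray(final_works, dtype=float)
    if works.size == 0:
        raise ValueError("need at least one work value")
    if not np.all(np.isfinite(works)):
        raise ValueError("work values must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (KB * temperature)
    w_min = works.min()
    return float(w_min - np.log(np.mean(np.exp(-beta * (works - w_min)))) / beta)


def jarzynski_stderr(final_works: Sequence[float], temperature: float,
                     n_boot: int = 200, seed: int = 0) -> float:
    """Bootstrap standard error of the Jarzynski estimate."""
    works = np.asarray(final_works, dtype=float)
    if works.size < 2:
        return 0.0
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, works.size, size=(n_boot, works.size))
    est = np.array([jarzynski_average(works[row], temperature) for row in idx])
    return float(est.std(ddof=1))


def _je_curve(work_matrix: np.ndarray, temperature: float) -> np.ndarray:
    """Jarzynski estimate at every logged point from the running works of all
    trajectories; work_matrix has shape (n_traj, n_points)."""
    beta = 1.0 / (KB * temperature)
    w_min = work_matrix.min(axis=0)
    return w_min - np.log(np.mean(np.exp(-beta * (work_matrix - w_min)), axis=0)) / beta


def select_seed_trajectory(ensemble: StageEnsemble) -> int:
    """Index of the trajectory whose final work is closest to the stage's
    Jarzynski average; exact ties go to the lowest index."""
    works = ensemble.final_works
    if works.size == 0:
        raise ValueError("empty ensemble")
    target = ensemble.je_curve[-1]
    return int(np.argmin(np.abs(works - target)))


def work_spread(ensemble: StageEnsemble) -> float:
    """max − min of the final works within a stage (QC metric; the reference
    protocol requires this to stay below 5 kcal mol⁻¹)."""
    works = ensemble.final_works
    if works.size == 0:
        raise ValueError("empty ensemble")
    return float(works.max() - works.min())


def resample_velocities(system: ParticleSystem, temperature: float,
                        seed: int) -> ParticleSystem:
    """Return a copy with Maxwell–Boltzmann velocities; positions unchanged."""
    if temperature < 0:
        raise ValueError("temperature must be ≥ 0")
    out = system.copy()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    out.velocities = maxwell_boltzmann_velocities(out.masses, temperature, rng)
    return out


def trajectory_seed(master_seed: int, stage_index: int, replica_index: int) -> int:
    """Deterministic per-trajectory seed derived from (master, stage, replica)."""
    ss = np.random.SeedSequence([int(master_seed), int(stage_index),
                                 int(replica_index)])
    return int(ss.generate_state(1)[0])


def run_asmd(system: ParticleSystem, provider: ForceProvider, config: ASMDConfig,
             record_positions: bool = True, record_stride: int = 10,
             preequil_time: float | None = None,
             ) -> tuple[PMFProfile, list[StageEnsemble]]:
    """Run the full staged protocol and assemble the PMF.

    ``preequil_time`` (ps) holds the restraint at the first stage boundary
    before pulling begins; by default 10 ps are used when the system's
    initial end-to-end distance differs from ``r_start`` by more than
    0.5 Å, otherwise no hold.
    """
    sched = config.schedule
    thermo = config.thermostat
    windows = partition_stages(sched.r_start, sched.r_end, config.n_stages)

    r0 = float(end_to_end(system.positions, sched.anchor_particle,
                          sched.pulled_particle))
    if preequil_time is None:
        preequil_time = 10.0 if abs(r0 - sched.r_start) > 0.5 else 0.0

    current = system.copy()
    ensembles: list[StageEnsemble] = []
    offset = 0.0
    grid_parts: list[np.ndarray] = []
    pmf_parts: list[np.ndarray] = []
    stage_parts: list[np.ndarray] = []

    for j, window in enumerate(windows):
        seeds = [trajectory_seed(config.master_seed, j, i)
                 for i in range(config.n_traj_per_stage)]
        trajs = run_smd_ensemble(
            current, provider, sched, thermo, window, seeds,
            resample_temperature=config.temperature,
            record_stride=record_stride,
            record_positions=record_positions,
            hold_time=preequil_time if j == 0 else 0.0,
        )
        work_matrix = np.stack([t.work for t in trajs])
        je = _je_curve(work_matrix, config.temperature)
        ens = StageEnsemble(
            stage_index=j,
            boundaries=window,
            trajectories=trajs,
            je_r=trajs[0].restraint_center,
            je_curve=je,
            selected_index=0,
            work_spread=float(work_matrix[:, -1].max() - work_matrix[:, -1].min()),
        )
        ens.selected_index = select_seed_trajectory(ens)
        ens.qc_flag = ens.work_spread >= config.work_spread_qc
        ensembles.append(ens)

        sel = trajs[ens.selected_index]
        if record_positions:
            current = current.copy()
            current.positions = sel.final_positions.copy()
        else:
            raise ValueError("run_asmd requires record_positions=True to chain stages")

        start = 0 if j == 0 else 1   # drop the duplicated boundary point
        grid_parts.append(ens.je_r[start:])
        pmf_parts.append(offset + je[start:])
        stage_parts.append(np.full(len(je) - start, j))
        offset += je[-1]

    r_grid = np.concatenate(grid_parts)
    delta_A = np.concatenate(pmf_parts)
    delta_A = delta_A - delta_A.min()
    profile = PMFProfile(r_grid=r_grid, delta_A=delta_A,
                         stage_of_point=np.concatenate(stage_parts))
    return profile, ensembles


def delta_A_at(profile: PMFProfile, r_values: Sequence[float]) -> np.ndarray:
    """Linear interpolation of the PMF at requested r_ee values (relative to
    the profile minimum)."""
    r_values = np.atleast_1d(np.asarray(r_values, dtype=float))
    lo, hi = profile.r_grid[0], profile.r_grid[-1]
    if np.any(r_values < lo - 1e-9) or np.any(r_values > hi + 1e-9):
        raise ValueError(f"requested r_ee outside the profile span [{lo}, {hi}]")
    return np.interp(r_values, profile.r_grid, profile.delta_A)
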