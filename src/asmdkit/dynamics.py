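"""Langevin dynamics and constant-velocity steered pulling.

The integrator is BAOAB (kick – drift – Ornstein–Uhlenbeck – drift – kick);
with zero friction and zero temperature it reduces to velocity Verlet.  The
steering potential is a harmonic restraint U_s = ½k(r_ee − c(t))² on the
end-to-end distance between a fixed anchor particle and a pulled particle,
with the restraint center moving at constant velocity, c(t) = r_j + v·t.
External work is accumulated on every integrator step by trapezoidal
quadrature of dW/dt = k·v·(c(t) − r_ee(t)).

Ensembles of independent replicas are propagated in a single batched pass
(positions of shape ``(n_replicas, n_particles, 3)``); each replica draws
its thermal noise from its own seeded generator, so results are identical
whether replicas run batched or one at a time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB, KCAL_TO_INTERNAL
from .systems import ForceProvider, ParticleSystem


class IntegrationError(RuntimeError):
    """Raised when the integrator detects a blow-up (non-finite forces or a
    restraint energy above the configured bound, signalling an unstable
    timestep)."""


@dataclass
class SteeringSchedule:
    """Constant-velocity harmonic steering along the end-to-end coordinate.

    ``coordinate`` selects what the restraint acts on: the Euclidean
    anchor–pulled ``distance`` (the peptide pulling coordinate), or the
    ``projection`` of the anchor→pulled vector onto ``axis``.  The 1D
    benchmark systems use the projection so their free-energy profile is
    exactly the bare potential, free of the 2k_BT·ln r Jacobian entropy the
    radial coordinate carries.
    """

    anchor_particle: int
    pulled_particle: int
    r_start: float                    # Å
    r_end: float                      # Å
    pull_velocity: float = 1e-3       # Å/ps (1 Å ns⁻¹)
    spring_k: float = 7.2             # kcal mol⁻¹ Å⁻²
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    coordinate: str = "distance"      # "distance" | "projection"

    def __post_init__(self):
        if self.r_end <= self.r_start:
            raise ValueError("r_end must exceed r_start")
        if self.spring_k <= 0:
            raise ValueError("spring_k must be positive")
        if self.pulled_particle == self.anchor_particle:
            raise ValueError("pulled and anchor particles must differ")
        if self.coordinate not in ("distance", "projection"):
            raise ValueError("coordinate must be 'distance' or 'projection'")
        axis = np.asarray(self.axis, dtype=float)
        self.axis = tuple(axis / np.linalg.norm(axis))


@dataclass
class ThermostatParams:
    temperature: float = 300.0   # K
    friction: float = 5.0        # ps⁻¹
    timestep: float = 0.002      # ps
    rng_seed: int = 0

    def __post_init__(self):
        if self.temperature < 0 or self.friction < 0 or self.timestep <= 0:
            raise ValueError("require temperature ≥ 0, friction ≥ 0, timestep > 0")


@dataclass
class TrajectoryRecord:
    """One nonequilibrium pulling trajectory: logged frames plus the work
    series W(t) aligned to them."""

    times: np.ndarray                 # (F,) ps
    r_ee: np.ndarray                  # (F,) Å
    work: np.ndarray                  # (F,) kcal mol⁻¹, starts at 0
    seed: int
    frames: np.ndarray | None = None  # (F, n, 3) Å, optional
    restraint_center: np.ndarray = field(default=None)  # (F,) Å
    final_velocities: np.ndarray | None = None  # (n, 3) Å/ps

    @property
    def final_work(self) -> float:
        return float(self.work[-1])

    @property
    def final_positions(self) -> np.ndarray:
        if self.frames is None:
            raise ValueError("trajectory was recorded without coordinate frames")
        return self.frames[-1]


def end_to_end(positions: np.ndarray, anchor: int, pulled: int) -> np.ndarray:
    """Euclidean distance between the anchor and pulled particles (the
    pulling reaction coordinate r_ee)."""
    if anchor == pulled:
        raise ValueError("anchor and pulled indices must differ")
    positions = np.asarray(positions, dtype=float)
    d = positions[..., pulled, :] - positions[..., anchor, :]
    return np.sqrt(np.sum(d * d, axis=-1))


def _baoab_coeffs(thermostat: ThermostatParams, masses: np.ndarray):
    dt, gamma, temp = thermostat.timestep, thermostat.friction, thermostat.temperature
    c1 = np.exp(-gamma * dt)
    # velocity variance of the OU step: k_BT(1 − c1²)/m, in (Å/ps)²
    sigma_v = np.sqrt(KB * temp * KCAL_TO_INTERNAL * (1.0 - c1**2) / masses)
    return c1, sigma_v


def maxwell_boltzmann_velocities(masses: np.ndarray, temperature: float,
                                 rng: np.random.Generator) -> np.ndarray:
    """Velocities drawn component-wise with variance k_BT/m (Å/ps)²."""
    masses = np.asarray(masses, dtype=float)
    sigma = np.sqrt(KB * temperature * KCAL_TO_INTERNAL / masses)
    return rng.standard_normal((len(masses), 3)) * sigma[:, None]


def langevin_step(system: ParticleSystem, provider: ForceProvider,
                  thermostat: ThermostatParams, n_steps: int = 1,
                  fixed: Sequence[int] = ()) -> ParticleSystem:
    """Advance a system by ``n_steps`` BAOAB updates and return the result.

    The input system is not modified.  Particles listed in ``fixed`` are held
    in place with zero velocity.  Deterministic given ``thermostat.rng_seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be ≥ 1")
    out = system.copy()
    rng = np.random.default_rng(thermostat.rng_seed)
    pos = out.positions
    vel = out.velocities
    masses = out.masses[:, None]
    c1, sigma_v = _baoab_coeffs(thermostat, masses)
    dt = thermostat.timestep
    fixed = np.asarray(list(fixed), dtype=int)

    def clamp():
        if len(fixed):
            pos[fixed] = system.positions[fixed]
            vel[fixed] = 0.0

    _, forces = provider.energy_forces(pos)
    for _ in range(n_steps):
        if not np.all(np.isfinite(forces)):
            raise IntegrationError("non-finite forces")
        vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
        pos += 0.5 * dt * vel
        vel *= c1
        vel += sigma_v * rng.standard_normal(pos.shape)
        pos += 0.5 * dt * vel
        clamp()
        _, forces = provider.energy_forces(pos)
        vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
        clamp()
    return out


def run_smd_ensemble(system: ParticleSystem, provider: ForceProvider,
                     schedule: SteeringSchedule, thermostat: ThermostatParams,
                     stage_window: tuple[float, float],
                     seeds: Sequence[int],
                     resample_temperature: float | None = None,
                     record_stride: int = 10,
                     record_positions: bool = True,
                     hold_time: float = 0.0,
                     restraint_energy_bound: float = 1e4,
                     ) -> list[TrajectoryRecord]:
    """Propagate an ensemble of replicas through one pulling window.

    All replicas start from the system's current coordinates.  If
    ``resample_temperature`` is given, each replica's velocities are freshly
    drawn from the Maxwell–Boltzmann distribution using its own seed;
    otherwise the system's stored velocities are reused.  ``hold_time``
    keeps the restraint center parked at the window start before pulling
    begins (restrained pre-equilibration); no work is logged during the hold.
    """
    r_j, r_j1 = stage_window
    if r_j1 < r_j:
        raise ValueError("stage window must be ordered")
    B = len(seeds)
    n = system.n_particles
    dt = thermostat.timestep
    k = schedule.spring_k
    v = schedule.pull_velocity
    anchor, pulled = schedule.anchor_particle, schedule.pulled_particle

    pos = np.repeat(system.positions[None], B, axis=0)
    rngs = [np.random.default_rng(np.random.SeedSequence(int(s))) for s in seeds]
    if resample_temperature is not None:
        vel = np.stack([maxwell_boltzmann_velocities(system.masses,
                                                     resample_temperature, rng)
                        for rng in rngs])
    else:
        vel = np.repeat(system.velocities[None], B, axis=0)
    vel[:, anchor] = 0.0

    masses = system.masses[None, :, None]
    c1, sigma_v = _baoab_coeffs(thermostat, masses)
    anchor_pos = system.positions[anchor].copy()

    n_hold = int(round(hold_time / dt))
    n_pull = int(round((r_j1 - r_j) / v / dt)) if r_j1 > r_j else 0
    # exact center schedule: lands on r_j1 precisely; the effective pulling
    # velocity differs from the nominal one only by timestep rounding
    c_sched = np.linspace(r_j, r_j1, n_pull + 1)
    v_eff = (r_j1 - r_j) / (n_pull * dt) if n_pull else 0.0

    axis = np.asarray(schedule.axis, dtype=float)
    use_projection = schedule.coordinate == "projection"

    def spring_force_and_g(pos, c):
        d = pos[:, pulled, :] - pos[:, anchor, :]
        if use_projection:
            r = d @ axis
            u = np.broadcast_to(axis, d.shape)
        else:
            r = np.sqrt(np.sum(d * d, axis=-1))
            u = d / r[:, None]
        f_mag = -k * (r - c)           # along +u on pulled particle
        g = k * v_eff * (c - r)        # dW/dt during pulling
        if np.any(0.5 * k * (r - c) ** 2 > restraint_energy_bound):
            raise IntegrationError("restraint energy exceeded blow-up bound; "
                                   "timestep is likely unstable")
        return u * f_mag[:, None], g, r

    def total_forces(pos, c):
        _, forces = provider.energy_forces(pos)
        if not np.all(np.isfinite(forces)):
            raise IntegrationError("non-finite forces")
        fs, g, r = spring_force_and_g(pos, c)
        forces[:, pulled, :] += fs
        forces[:, anchor, :] = 0.0
        return forces, g, r

    work = np.zeros(B)
    t = 0.0
    times, r_log, w_log, c_log, frames = [], [], [], [], []

    def log(r, c_now):
        times.append(t)
        r_log.append(r.copy())
        w_log.append(work.copy())
        c_log.append(c_now)
        if record_positions:
            frames.append(pos.copy())

    chunk = 256

    def noise_block(m):
        return np.stack([rng.standard_normal((m, n, 3)) for rng in rngs], axis=0)

    # restrained hold at the window start (no pulling, no work)
    forces, g, r = total_forces(pos, r_j)
    for start in range(0, n_hold, chunk):
        m = min(chunk, n_hold - start)
        xi = noise_block(m)
        for s in range(m):
            vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
            pos += 0.5 * dt * vel
            vel *= c1
            vel += sigma_v * xi[:, s]
            pos += 0.5 * dt * vel
            pos[:, anchor] = anchor_pos
            vel[:, anchor] = 0.0
            forces, g, r = total_forces(pos, r_j)
            vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
            vel[:, anchor] = 0.0

    log(r, r_j)
    step_index = 0
    for start in range(0, n_pull, chunk):
        m = min(chunk, n_pull - start)
        xi = noise_block(m)
        for s in range(m):
            c_new = c_sched[step_index + 1]
            g_old = g
            vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
            pos += 0.5 * dt * vel
            vel *= c1
            vel += sigma_v * xi[:, s]
            pos += 0.5 * dt * vel
            pos[:, anchor] = anchor_pos
            vel[:, anchor] = 0.0
            forces, g, r = total_forces(pos, c_new)
            vel += 0.5 * dt * forces * KCAL_TO_INTERNAL / masses
            vel[:, anchor] = 0.0
            work += 0.5 * dt * (g_old + g)
            step_index += 1
            t = step_index * dt
            if step_index % record_stride == 0 or step_index == n_pull:
                log(r, c_new)

    times = np.asarray(times)
    r_arr = np.stack(r_log, axis=1)          # (B, F)
    w_arr = np.stack(w_log, axis=1)
    c_arr = np.asarray(c_log)
    records = []
    for i in range(B):
        records.append(TrajectoryRecord(
            times=times.copy(),
            r_ee=r_arr[i],
            work=w_arr[i],
            seed=int(seeds[i]),
            frames=(np.stack([f[i] for f in frames]) if record_positions else None),
            restraint_center=c_arr.copy(),
            final_velocities=vel[i].copy(),
        ))
    return records


def run_smd_segment(system: ParticleSystem, provider: ForceProvider,
                    schedule: SteeringSchedule, thermostat: ThermostatParams,
                    stage_window: tuple[float, float], seed: int,
                    **kwargs) -> TrajectoryRecord:
    """Single steered trajectory through one stage window (batch of one)."""
    return run_smd_ensemble(system, provider, schedule, thermostat,
                            stage_window, [seed], **kwargs)[0]


def kinetic_energy(velocities: np.ndarray, masses: np.ndarray) -> float:
    """Total kinetic energy in kcal mol⁻¹."""
    v2 = np.sum(np.asarray(velocities) ** 2, axis=-1)
    return float(np.sum(0.5 * masses * v2) / KCAL_TO_INTERNAL)
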