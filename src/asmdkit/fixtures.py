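"""Deterministic synthetic-input generators with known ground truth.

Every generator is a pure function of its parameters and seed, so fixtures
are regenerated bitwise-identically at test time instead of being shipped
as data files.  Kinds: planted hydrogen-bond configurations, staged work
ensembles with planted observables, sigmoidal CD melt curves, and
coarse-grained hairpin unfolding pathways (including the transient
nonnative 5–12 approach near r_ee ≈ 8.6 Å seen in the salt-bridge-swap
mechanism)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .asmd import StageEnsemble, _je_curve, partition_stages, select_seed_trajectory
from .dynamics import TrajectoryRecord, end_to_end
from .melt import MeltCurve
from .observables import AtomGroup, HBondCriterion
from .systems import (HairpinForceField, MutationSpec, ParticleSystem,
                      make_hairpin_system)


@dataclass
class PlantedHBondConfig:
    positions: np.ndarray
    donors: AtomGroup
    acceptors: AtomGroup
    true_count: int


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def _vector_at_angle(u: np.ndarray, angle_deg: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit vector at the given angle from u, random azimuth."""
    w = np.cross(u, _random_unit(rng))
    n = np.linalg.norm(w)
    while n < 1e-8:
        w = np.cross(u, _random_unit(rng))
        n = np.linalg.norm(w)
    w /= n
    a = np.radians(angle_deg)
    return np.cos(a) * u + np.sin(a) * w


def gen_planted_hbond_config(n_bonds: int, n_decoys: int,
                             criterion: HBondCriterion | None = None,
                             seed: int = 0) -> PlantedHBondConfig:
    """Donor/hydrogen/acceptor triples with exactly ``n_bonds`` satisfying
    the geometric criterion (margin ≥ 0.1 Å and 5°) and ``n_decoys``
    violating it with the same margin.  Triples live in well-separated cells
    so no cross-cell pair can bond accidentally."""
    if n_bonds < 0 or n_decoys < 0:
        raise ValueError("counts must be non-negative")
    criterion = criterion or HBondCriterion()
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    cell = 6.0 * criterion.distance_cutoff + 6.0
    positions, d_idx, h_idx, a_idx = [], [], [], []

    def add_triple(k, bonded):
        center = np.array([float(k * cell), 0.0, 0.0])
        u = _random_unit(rng)
        if bonded:
            dist = rng.uniform(1.5, criterion.distance_cutoff - 0.1)
            ang = rng.uniform(0.0, max(criterion.angle_cutoff - 5.0, 0.0))
        elif rng.random() < 0.5:
            dist = rng.uniform(criterion.distance_cutoff + 0.1,
                               criterion.distance_cutoff + 2.0)
            ang = rng.uniform(0.0, 180.0)
        else:
            dist = rng.uniform(1.5, criterion.distance_cutoff - 0.1)
            ang = rng.uniform(criterion.angle_cutoff + 5.0, 175.0)
        d = center
        a = center + dist * u
        h = d + 1.0 * _vector_at_angle(u, ang, rng)
        d_idx.append(len(positions)); positions.append(d)
        h_idx.append(len(positions)); positions.append(h)
        a_idx.append(len(positions)); positions.append(a)

    for k in range(n_bonds):
        add_triple(k, bonded=True)
    for k in range(n_decoys):
        add_triple(n_bonds + k, bonded=False)

    positions = (np.array(positions) if positions else np.zeros((0, 3)))
    donors = AtomGroup("planted_donors", np.array(d_idx, dtype=int),
                       hydrogens=np.array(h_idx, dtype=int))
    acceptors = AtomGroup("planted_acceptors", np.array(a_idx, dtype=int))
    return PlantedHBondConfig(positions, donors, acceptors, true_count=n_bonds)


@dataclass
class StagedWorkFixture:
    ensembles: list[StageEnsemble]
    observable_values: np.ndarray      # (n_stages, n_traj) planted scalars
    work_means: np.ndarray             # (n_stages,)
    hbond_groups: tuple[AtomGroup, AtomGroup] | None = None
    planted_counts: list[int] | None = None


def gen_staged_work_ensemble(n_stages: int, n_traj: int,
                             work_mean_per_stage: float | Sequence[float] = 2.0,
                             spread: float = 1.0, seed: int = 0,
                             temperature: float = 300.0,
                             planted_counts: Sequence[int] | None = None,
                             n_points: int = 11,
                             qc_threshold: float = 5.0,
                             r_start: float = 4.0, stage_width: float = 2.0,
                             ) -> StagedWorkFixture:
    """Synthetic stage ensembles without any dynamics.

    Final works are drawn uniformly in mean ± spread/2 and accumulate
    linearly within the stage.  A planted scalar observable (one value per
    trajectory) is attached for weighted-average checks.  If
    ``planted_counts`` gives one hydrogen-bond count per stage, every frame
    of that stage is a planted configuration realizing exactly that count,
    so counting observables recover a known step profile."""
    if spread < 0:
        raise ValueError("spread must be non-negative")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    means = np.broadcast_to(np.asarray(work_mean_per_stage, dtype=float),
                            (n_stages,)).copy()
    windows = partition_stages(r_start, r_start + n_stages * stage_width, n_stages)

    if planted_counts is not None:
        if len(planted_counts) != n_stages:
            raise ValueError("need one planted count per stage")
        max_count = max(planted_counts)

    obs = rng.normal(0.0, 1.0, size=(n_stages, n_traj))
    ensembles = []
    groups = None
    for j, window in enumerate(windows):
        r_grid = np.linspace(window[0], window[1], n_points)
        finals = means[j] + (rng.uniform(-0.5, 0.5, size=n_traj) * spread
                             if spread > 0 else np.zeros(n_traj))
        ramp = np.linspace(0.0, 1.0, n_points)
        works = finals[:, None] * ramp[None, :]

        frames_proto = None
        if planted_counts is not None:
            cfg = gen_planted_hbond_config(
                planted_counts[j], (max_count - planted_counts[j]) + 2,
                seed=int(rng.integers(2**31)))
            frames_proto = cfg.positions
            groups = (cfg.donors, cfg.acceptors)

        trajs = []
        for i in range(n_traj):
            trajs.append(TrajectoryRecord(
                times=np.linspace(0.0, 1.0, n_points),
                r_ee=r_grid.copy(),
                work=works[i],
                seed=int(seed) * 1000 + j * n_traj + i,
                frames=(np.repeat(frames_proto[None], n_points, axis=0)
                        if frames_proto is not None else None),
                restraint_center=r_grid.copy(),
            ))
        je = _je_curve(works, temperature)
        ens = StageEnsemble(
            stage_index=j, boundaries=window, trajectories=trajs,
            je_r=r_grid, je_curve=je, selected_index=0,
            work_spread=float(finals.max() - finals.min()),
        )
        ens.selected_index = select_seed_trajectory(ens)
        ens.qc_flag = ens.work_spread >= qc_threshold
        ensembles.append(ens)
    return StagedWorkFixture(ensembles=ensembles, observable_values=obs,
                             work_means=means, hbond_groups=groups,
                             planted_counts=(list(planted_counts)
                                             if planted_counts is not None else None))


def gen_sigmoid_melt(midpoint: float, width: float = 5.0,
                     upper: float = 100.0, lower: float = 0.0,
                     noise_sigma: float = 0.0, seed: int = 0,
                     t_min: float = 5.0, t_max: float = 90.0,
                     step: float = 1.0) -> MeltCurve:
    """Logistic melt curve sampled on a regular temperature grid.

    signal(T) = lower + (upper − lower)/(1 + exp((T − midpoint)/width)),
    plus i.i.d. Gaussian noise of standard deviation ``noise_sigma`` (same
    units as the signal).  With upper = 100 and lower = 0 the noise-free
    curve crosses 50% exactly at the midpoint."""
    if width <= 0:
        raise ValueError("width must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    temps = np.arange(t_min, t_max + 0.5 * step, step)
    signal = lower + (upper - lower) / (1.0 + np.exp((temps - midpoint) / width))
    if noise_sigma > 0:
        signal = signal + rng.normal(0.0, noise_sigma, size=temps.shape)
    return MeltCurve(temperatures=temps, signal=signal)


@dataclass
class HairpinPathwayFixture:
    ensembles: list[StageEnsemble]
    system: ParticleSystem
    provider: HairpinForceField
    bridge_peak_r: float


def _extended_positions(system: ParticleSystem, spacing: float = 3.6) -> np.ndarray:
    """Fully extended chain along z preserving each particle's offset from
    its residue's backbone bead."""
    labels = system.particle_labels
    backbone_pos = {}
    for i, lab in enumerate(labels):
        if lab.role == "backbone":
            backbone_pos[lab.residue] = system.positions[i]
    out = np.zeros_like(system.positions)
    for i, lab in enumerate(labels):
        b_new = np.array([0.0, 0.0, (lab.residue - 1) * spacing])
        offset = system.positions[i] - backbone_pos[lab.residue]
        # keep sidechain/H/O offsets but fold them to ±y so the chain is thin
        if lab.role != "backbone":
            offset = np.array([0.0, np.linalg.norm(offset), 0.0])
        out[i] = b_new + offset
    return out


def gen_hairpin_pathway(mutations: Sequence[MutationSpec | str] = (),
                        n_stages: int = 8, n_traj: int = 10,
                        r_end: float = 36.0, points_per_stage: int = 6,
                        jitter: float = 0.05, seed: int = 0,
                        bridge: bool = True, bridge_peak_r: float = 8.6,
                        bridge_min_dist: float = 2.8, bridge_width: float = 1.5,
                        work_mean_per_stage: float = 2.0, work_spread: float = 1.0,
                        temperature: float = 300.0) -> HairpinPathwayFixture:
    """Constructed unfolding pathway of the coarse-grained hairpin.

    Frames interpolate between the native hairpin and a fully extended
    chain, with per-bead Gaussian jitter.  With ``bridge=True`` the
    residue-12 sidechain transiently approaches the residue-5 sidechain
    with closest approach ``bridge_min_dist`` around r_ee ≈ ``bridge_peak_r``
    (Gaussian window of width ``bridge_width``), emulating the nonnative
    Glu5–Lys12 contact channel; whether that geometry is stabilizing is
    decided by the force field of the requested mutant, not by the fixture.
    Synthetic stage works follow the staged-work generator's conventions.
    """
    system, provider = make_hairpin_system(mutations=mutations)
    rng = np.random.default_rng(np.random.SeedSequence(int(seed)))
    labels = system.particle_labels
    p_native = system.positions
    p_ext = _extended_positions(system)
    anchor = provider.backbone_index[1]
    pulled = provider.backbone_index[12]
    s5 = provider.sidechain_index[5]
    s12 = provider.sidechain_index[12]
    r_native = float(end_to_end(p_native, anchor, pulled))
    r_ext = float(end_to_end(p_ext, anchor, pulled))

    def frame_at(r: float) -> np.ndarray:
        # solve the interpolation fraction whose end-to-end distance is r
        v0 = p_native[pulled] - p_native[anchor]
        v1 = p_ext[pulled] - p_ext[anchor]
        a = np.sum((v1 - v0) ** 2)
        b = 2.0 * np.sum(v0 * (v1 - v0))
        c = np.sum(v0**2) - r**2
        disc = max(b * b - 4 * a * c, 0.0)
        f = np.clip((-b + np.sqrt(disc)) / (2 * a), 0.0, 1.0)
        pos = (1.0 - f) * p_native + f * p_ext
        if bridge:
            g = np.exp(-0.5 * ((r - bridge_peak_r) / bridge_width) ** 2)
            d_vec = pos[s12] - pos[s5]
            d = np.linalg.norm(d_vec)
            d_new = (1.0 - g) * d + g * bridge_min_dist
            pos[s12] = pos[s5] + d_vec / d * d_new
        return pos

    windows = partition_stages(r_native, r_end, n_stages)
    ensembles = []
    for j, window in enumerate(windows):
        r_grid = np.linspace(window[0], window[1], points_per_stage)
        finals = work_mean_per_stage + rng.uniform(-0.5, 0.5, n_traj) * work_spread
        ramp = np.linspace(0.0, 1.0, points_per_stage)
        works = finals[:, None] * ramp[None, :]
        trajs = []
        for i in range(n_traj):
            frames = np.stack([frame_at(r) for r in r_grid])
            frames = frames + rng.normal(0.0, jitter, size=frames.shape)
            r_meas = end_to_end(frames, anchor, pulled)
            trajs.append(TrajectoryRecord(
                times=np.linspace(0.0, 1.0, points_per_stage),
                r_ee=np.asarray(r_meas),
                work=works[i],
                seed=int(seed) * 1000 + j * n_traj + i,
                frames=frames,
                restraint_center=r_grid.copy(),
            ))
        je = _je_curve(works, temperature)
        ens = StageEnsemble(stage_index=j, boundaries=window, trajectories=trajs,
                            je_r=r_grid, je_curve=je, selected_index=0,
                            work_spread=float(finals.max() - finals.min()))
        ens.selected_index = select_seed_trajectory(ens)
        ensembles.append(ens)
    return HairpinPathwayFixture(ensembles=ensembles, system=system,
                                 provider=provider, bridge_peak_r=bridge_peak_r)
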