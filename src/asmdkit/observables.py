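"""Work-weighted structural observables along the pulling coordinate.

Each trajectory contributes to an ensemble average with weight
exp(−W_i(t)/k_BT) given its accumulated pulling work, so configurations
that required anomalously large work are discounted exactly as in the
free-energy estimate.  Observables provided: geometric hydrogen-bond
counts (donor–acceptor distance ≤ 3.0 Å and donor→H / donor→acceptor angle
≤ 40° by default), residue-pair nonbonded interaction energies, optimal
superposition RMSD, and representative-structure extraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import KB
from .asmd import StageEnsemble
from .systems import ForceProvider, ParticleSystem


@dataclass
class HBondCriterion:
    distance_cutoff: float = 3.0   # Å, inclusive
    angle_cutoff: float = 40.0     # degrees, inclusive (donor→H vs donor→acceptor)

    def __post_init__(self):
        if self.distance_cutoff <= 0 or self.angle_cutoff <= 0:
            raise ValueError("cutoffs must be positive")


@dataclass
class AtomGroup:
    """Named particle index set; donor groups carry one hydrogen index per
    donor atom."""

    name: str
    indices: np.ndarray
    hydrogens: np.ndarray | None = None
    role: str = "peptide"

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=int)
        if len(set(self.indices.tolist())) != len(self.indices):
            raise ValueError("group indices must be unique")
        if self.hydrogens is not None:
            self.hydrogens = np.asarray(self.hydrogens, dtype=int)
            if len(self.hydrogens) != len(self.indices):
                raise ValueError("each donor needs exactly one hydrogen index")


@dataclass
class ObservableSeries:
    r_grid: np.ndarray
    values: np.ndarray
    name: str
    n_traj: int = 0
    stage_of_point: np.ndarray = field(default=None)

    def __post_init__(self):
        if len(self.r_grid) != len(self.values):
            raise ValueError("grid and values must align")


def weighted_average(values: Sequence[float], works: Sequence[float],
                     temperature: float) -> float:
    """Σ v_i e^{−βW_i} / Σ e^{−βW_i}, stabilized in the log domain.

    Equals the arithmetic mean when all works are equal, and is always
    bounded by min(values) and max(values).
    """
    values = np.asarray(values, dtype=float)
    works = np.asarray(works, dtype=float)
    if values.size == 0:
        raise ValueError("empty input")
    if values.shape != works.shape:
        raise ValueError("values and works must have equal length")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    beta = 1.0 / (KB * temperature)
    logw = -beta * (works - works.min())
    w = np.exp(logw)
    return float(np.sum(values * w) / np.sum(w))


def count_hbonds(positions: np.ndarray, donors: AtomGroup, acceptors: AtomGroup,
                 criterion: HBondCriterion | None = None) -> int:
    """Count (donor, acceptor) pairs satisfying the geometric criterion.

    A pair is hydrogen bonded when the donor–acceptor distance is within the
    distance cutoff (inclusive) and the angle between the donor→hydrogen and
    donor→acceptor vectors is at most the angle cutoff.  Pairs where donor
    and acceptor are the same particle are excluded.
    """
    criterion = criterion or HBondCriterion()
    if donors.hydrogens is None:
        raise ValueError("donor group lacks attached hydrogens")
    positions = np.asarray(positions, dtype=float)
    d_pos = positions[donors.indices]          # (D, 3)
    h_pos = positions[donors.hydrogens]
    a_pos = positions[acceptors.indices]       # (A, 3)

    da = a_pos[None, :, :] - d_pos[:, None, :]     # (D, A, 3)
    dist = np.linalg.norm(da, axis=-1)
    dh = h_pos - d_pos                             # (D, 3)
    dh_norm = np.linalg.norm(dh, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.einsum("dac,dc->da", da, dh) / (dist * dh_norm[:, None])
    cosang = np.clip(cosang, -1.0, 1.0)
    angle = np.degrees(np.arccos(cosang))

    ok = (dist <= criterion.distance_cutoff) & (angle <= criterion.angle_cutoff)
    same = donors.indices[:, None] == acceptors.indices[None, :]
    ok &= ~same
    return int(np.count_nonzero(ok))


def _stitch_series(ensembles: Sequence[StageEnsemble], per_stage_values,
                   name: str) -> ObservableSeries:
    grid_parts, val_parts, stage_parts = [], [], []
    for ens, vals in zip(ensembles, per_stage_values):
        start = 0 if not grid_parts else 1
        grid_parts.append(ens.je_r[start:])
        val_parts.append(np.asarray(vals)[start:])
        stage_parts.append(np.full(len(vals) - start, ens.stage_index))
    return ObservableSeries(
        r_grid=np.concatenate(grid_parts),
        values=np.concatenate(val_parts),
        name=name,
        n_traj=len(ensembles[0].trajectories),
        stage_of_point=np.concatenate(stage_parts),
    )


def hbond_series(ensembles: Sequence[StageEnsemble],
                 groups: tuple[AtomGroup, AtomGroup],
                 criterion: HBondCriterion | None = None,
                 temperature: float = 300.0) -> ObservableSeries:
    """Work-weighted average hydrogen-bond count ⟨N_H(S_1, S_2)⟩ on the
    stitched stage grid."""
    donors, acceptors = groups
    per_stage = []
    for ens in ensembles:
        n_pts = len(ens.je_r)
        vals = np.empty(n_pts)
        counts = np.array([[count_hbonds(t.frames[p], donors, acceptors, criterion)
                            for t in ens.trajectories] for p in range(n_pts)])
        works = np.stack([t.work for t in ens.trajectories], axis=1)  # (F, B)
        for p in range(n_pts):
            vals[p] = weighted_average(counts[p], works[p], temperature)
        per_stage.append(vals)
    return _stitch_series(ensembles, per_stage,
                          name=f"N_H({donors.name},{acceptors.name})")


def hairpin_intrapeptide_groups(provider) -> tuple[AtomGroup, AtomGroup]:
    """Donor and acceptor groups (S_P, S_P) for a coarse-grained hairpin:
    backbone amide donors with their hydrogen beads, and carbonyl-oxygen
    acceptor beads."""
    donor_res = sorted(provider.donor_h_index)
    donors = AtomGroup(
        "S_P_donors",
        indices=np.array([provider.backbone_index[r] for r in donor_res]),
        hydrogens=np.array([provider.donor_h_index[r] for r in donor_res]))
    acceptors = AtomGroup(
        "S_P_acceptors",
        indices=np.array([provider.acceptor_o_index[r]
                          for r in sorted(provider.acceptor_o_index)]))
    return donors, acceptors


def pair_interaction_energy(positions: np.ndarray, system: ParticleSystem,
                            res_a: int, res_b: int,
                            provider: ForceProvider) -> float:
    """Nonbonded (electrostatic + contact + excluded-volume) energy between
    all particles of two residues, via the provider's term-resolved query."""
    idx_a = system.residue_particles(res_a)
    idx_b = system.residue_particles(res_b)
    return float(provider.pair_energy(positions, idx_a, idx_b))


def pair_energy_series(ensembles: Sequence[StageEnsemble], system: ParticleSystem,
                       pair: tuple[int, int], provider: ForceProvider,
                       temperature: float = 300.0) -> ObservableSeries:
    """Work-weighted residue-pair interaction energy along the pull."""
    res_a, res_b = pair
    idx_a = system.residue_particles(res_a)
    idx_b = system.residue_particles(res_b)
    per_stage = []
    for ens in ensembles:
        frames = np.stack([t.frames for t in ens.trajectories])   # (B, F, n, 3)
        energies = provider.pair_energy(frames, idx_a, idx_b)     # (B, F)
        works = np.stack([t.work for t in ens.trajectories])      # (B, F)
        vals = np.array([weighted_average(energies[:, p], works[:, p], temperature)
                         for p in range(frames.shape[1])])
        per_stage.append(vals)
    return _stitch_series(ensembles, per_stage, name=f"E_pair({res_a},{res_b})")


def kabsch_rmsd(reference_coords: np.ndarray, coords: np.ndarray,
                selection: Sequence[int] | None = None) -> float:
    """Minimal RMSD over rigid rotations and translations (Kabsch/SVD).

    ``selection`` restricts the superposition and the deviation to a subset
    of matched atoms (e.g. backbone indices).
    """
    ref = np.asarray(reference_coords, dtype=float)
    mov = np.asarray(coords, dtype=float)
    if selection is not None:
        sel = np.asarray(selection, dtype=int)
        ref, mov = ref[sel], mov[sel]
    if ref.shape != mov.shape or ref.ndim != 2 or ref.shape[1] != 3:
        raise ValueError("coordinate arrays must be matched (m, 3) sets")
    if len(ref) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    h = mov_c.T @ ref_c
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    # proper rotation (flip the smallest singular direction if improper),
    # then the deviation of the explicitly rotated coordinates — avoids the
    # catastrophic cancellation of the trace formula near zero RMSD
    rot = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    resid = mov_c @ rot.T - ref_c
    return float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))


def representative_structure(ensemble: StageEnsemble, at_r_ee: float) -> np.ndarray:
    """Coordinates nearest the requested r_ee, taken from the stage's
    selected (closest-to-Jarzynski-work) trajectory; ties go to the earlier
    frame."""
    lo, hi = ensemble.boundaries
    if not (min(lo, ensemble.je_r.min()) - 1e-9 <= at_r_ee
            <= max(hi, ensemble.je_r.max()) + 1e-9):
        raise ValueError(f"r_ee {at_r_ee} outside stage span ({lo}, {hi})")
    traj = ensemble.trajectories[ensemble.selected_index]
    if traj.frames is None:
        raise ValueError("trajectory has no stored frames")
    # nominal coordinate (restraint center) indexes frames deterministically;
    # fall back to the measured r_ee for imported trajectories without one
    coord = traj.restraint_center if traj.restraint_center is not None else traj.r_ee
    gaps = np.abs(coord - at_r_ee)
    return traj.frames[int(np.argmin(gaps))]
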