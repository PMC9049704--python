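"""Simulatable model systems.

Two families are provided:

* analytic single-bead benchmark potentials (flat, harmonic, double well)
  whose free-energy profile along the pulling coordinate is known in closed
  form, used as oracles for the staged nonequilibrium estimator; and
* a coarse-grained Gō-like model of the 12-residue tryptophan-zipper
  β-hairpin trpzip1 (sequence SWTWEGNKWTWK) with the six single-point
  mutations E5L, K8L, W2S, W4S, W9S and W11S applied as declarative
  parameter edits (charge zeroing, contact weakening).

Every system is paired with a :class:`ForceProvider` that returns the
potential energy and forces for a configuration, plus a term-resolved
nonbonded energy query between two particle subsets.  Providers accept
batched position arrays of shape ``(..., n_particles, 3)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .constants import COULOMB_K

WT_SEQUENCE = "SWTWEGNKWTWK"

#: native Trp–Trp hydrophobic contact pairs (1-based residue indices)
TRP_CONTACT_PAIRS = ((2, 11), (4, 9))

#: native cross-strand backbone hydrogen bonds as (donor residue, acceptor
#: residue); the wild-type hairpin starts the pull with five of them
NATIVE_HBOND_PAIRS = ((1, 12), (2, 11), (3, 10), (4, 9), (5, 8))

#: residue pairs whose nonbonded interaction energy is tracked along the pull
TRACKED_RESIDUE_PAIRS = ((2, 11), (4, 9), (5, 7), (5, 8), (5, 12), (8, 10))

_MUTATION_SITES = frozenset({2, 4, 5, 8, 9, 11})

# approximate sidechain masses (amu) by one-letter code; backbone bead is
# the N-Cα-C=O unit
_SIDECHAIN_MASS = {
    "S": 31.0, "W": 130.0, "T": 45.0, "E": 73.0, "G": 1.0,
    "N": 58.0, "K": 72.0, "L": 57.0,
}
_BACKBONE_MASS = 56.0


@dataclass(frozen=True)
class ParticleLabel:
    """Residue index (1-based) plus a role tag for one particle."""

    residue: int
    role: str  # backbone | sidechain | donor_h | acceptor_o | anchor | bead | solvent


@dataclass
class BondTerm:
    pair: tuple[int, int]
    r0: float          # equilibrium length, Å
    k: float           # stiffness, kcal mol⁻¹ Å⁻²; U = ½ k (r − r0)²


@dataclass
class ContactTerm:
    """Gō-like native contact: 12–10 well U(r) = ε(5(r0/r)¹² − 6(r0/r)¹⁰)."""

    pair: tuple[int, int]
    depth: float       # well depth ε, kcal mol⁻¹ (U(r0) = −ε)
    r0: float          # native distance, Å


@dataclass
class ParticleSystem:
    """Positions, velocities, masses, charges and topology of a system."""

    positions: np.ndarray       # (n, 3) Å
    velocities: np.ndarray      # (n, 3) Å/ps
    masses: np.ndarray          # (n,) amu
    charges: np.ndarray         # (n,) e
    particle_labels: list[ParticleLabel]
    bonded_terms: list[BondTerm] = field(default_factory=list)
    contact_terms: list[ContactTerm] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.velocities = np.asarray(self.velocities, dtype=float)
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        n = len(self.positions)
        if not (len(self.velocities) == len(self.masses) == len(self.charges)
                == len(self.particle_labels) == n):
            raise ValueError("per-particle arrays must all have equal length")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        for term in self.bonded_terms:
            i, j = term.pair
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise ValueError(f"bonded pair {term.pair} references invalid particles")

    @property
    def n_particles(self) -> int:
        return len(self.positions)

    def copy(self) -> "ParticleSystem":
        return ParticleSystem(
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            masses=self.masses.copy(),
            charges=self.charges.copy(),
            particle_labels=list(self.particle_labels),
            bonded_terms=list(self.bonded_terms),
            contact_terms=list(self.contact_terms),
        )

    def residue_particles(self, residue: int) -> np.ndarray:
        """Indices of all particles belonging to a 1-based residue."""
        return np.array([i for i, lab in enumerate(self.particle_labels)
                         if lab.residue == residue], dtype=int)


class ForceProvider:
    """Contract: positions in, (energy, forces) out.

    ``energy_forces`` accepts positions of shape ``(..., n, 3)`` and returns
    energy of shape ``(...)`` (kcal mol⁻¹) and forces with the positions'
    shape (kcal mol⁻¹ Å⁻¹).  Forces are the negative gradient of the energy.
    ``pair_energy`` resolves the nonbonded energy between two particle
    subsets.
    """

    def energy_forces(self, positions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def energy(self, positions: np.ndarray) -> np.ndarray:
        return self.energy_forces(positions)[0]

    def pair_energy(self, positions: np.ndarray, idx_a: Sequence[int],
                    idx_b: Sequence[int]) -> np.ndarray:
        raise NotImplementedError


# ---------------------------------------------------------------------------
# analytic benchmark systems
# ---------------------------------------------------------------------------

class Analytic1DProvider(ForceProvider):
    """Single mobile bead on the z axis; particle 0 is a fixed anchor at the
    origin, particle 1 carries the 1D potential U(z)."""

    bead_index = 1

    def u(self, z):
        raise NotImplementedError

    def du(self, z):
        raise NotImplementedError

    def energy_forces(self, positions):
        positions = np.asarray(positions, dtype=float)
        z = positions[..., self.bead_index, 2]
        energy = self.u(z)
        forces = np.zeros_like(positions)
        forces[..., self.bead_index, 2] = -self.du(z)
        return np.asarray(energy, dtype=float), forces

    def pair_energy(self, positions, idx_a, idx_b):
        positions = np.asarray(positions, dtype=float)
        return np.zeros(positions.shape[:-2])


class FlatProvider(Analytic1DProvider):
    def u(self, z):
        return np.zeros_like(np.asarray(z, dtype=float))

    def du(self, z):
        return np.zeros_like(np.asarray(z, dtype=float))


class HarmonicProvider(Analytic1DProvider):
    def __init__(self, k: float, x0: float = 0.0):
        if k <= 0:
            raise ValueError("harmonic stiffness must be positive")
        self.k = float(k)
        self.x0 = float(x0)

    def u(self, z):
        return 0.5 * self.k * (np.asarray(z, dtype=float) - self.x0) ** 2

    def du(self, z):
        return self.k * (np.asarray(z, dtype=float) - self.x0)


class DoubleWellProvider(Analytic1DProvider):
    """U(z) = a((z − c)² − b²)² with minima at c ± b and barrier a·b⁴ at c."""

    def __init__(self, a: float, b: float, center: float = 0.0):
        if a <= 0 or b <= 0:
            raise ValueError("double-well barrier a·b⁴ must be positive")
        self.a = float(a)
        self.b = float(b)
        self.center = float(center)

    def u(self, z):
        s = np.asarray(z, dtype=float) - self.center
        return self.a * (s**2 - self.b**2) ** 2

    def du(self, z):
        s = np.asarray(z, dtype=float) - self.center
        return 4.0 * self.a * s * (s**2 - self.b**2)


def make_analytic_system(kind: str, mass: float = 12.0, z_init: float | None = None,
                         **params) -> tuple[ParticleSystem, ForceProvider]:
    """Build a single-bead 1D benchmark system embedded on the z axis.

    Particle 0 is the anchor (held fixed at the origin by the steering
    schedule); particle 1 is the mobile bead, so the end-to-end distance of
    the pair equals the bead's z coordinate for z > 0.
    """
    if kind == "flat":
        provider: Analytic1DProvider = FlatProvider()
        default_z = 1.0
    elif kind == "harmonic":
        provider = HarmonicProvider(k=params.pop("k", 2.0), x0=params.pop("x0", 0.0))
        default_z = provider.x0 if provider.x0 > 0 else 1.0
    elif kind == "double_well":
        provider = DoubleWellProvider(a=params.pop("a", 1.0), b=params.pop("b", 1.0),
                                      center=params.pop("center", 0.0))
        default_z = provider.center - provider.b
        if default_z <= 0:
            default_z = abs(default_z) or 1.0
    else:
        raise ValueError(f"unknown analytic system kind: {kind!r}")
    if params:
        raise ValueError(f"unrecognized parameters: {sorted(params)}")
    z0 = default_z if z_init is None else float(z_init)
    system = ParticleSystem(
        positions=np.array([[0.0, 0.0, 0.0], [0.0, 0.0, z0]]),
        velocities=np.zeros((2, 3)),
        masses=np.array([mass, mass]),
        charges=np.zeros(2),
        particle_labels=[ParticleLabel(1, "anchor"), ParticleLabel(2, "bead")],
    )
    return system, provider


def analytic_pmf(provider: ForceProvider, grid: np.ndarray,
                 temperature: float = 300.0) -> np.ndarray:
    """Exact free-energy profile of a 1D single-bead system on ``grid``.

    For a single particle in one dimension the potential of mean force along
    position is the potential itself up to an additive constant, independent
    of temperature; the profile is returned relative to its minimum.
    """
    if not isinstance(provider, Analytic1DProvider):
        raise TypeError("analytic_pmf requires a single-particle 1D provider")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) < 0):
        raise ValueError("grid must be a sorted 1D array")
    u = provider.u(grid)
    return u - u.min()


# ---------------------------------------------------------------------------
# coarse-grained hairpin
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MutationSpec:
    """Single-point mutation as a declarative parameter edit."""

    site: int
    from_aa: str
    to_aa: str

    def __post_init__(self):
        if self.site not in _MUTATION_SITES:
            raise ValueError(f"mutation site must be one of {sorted(_MUTATION_SITES)}")
        if self.to_aa not in {"L", "S"}:
            raise ValueError("supported replacement residues are L and S")

    @classmethod
    def parse(cls, text: str) -> "MutationSpec":
        """Parse compact notation like ``K8L`` or ``W11S``."""
        return cls(site=int(text[1:-1]), from_aa=text[0], to_aa=text[-1])

    def __str__(self) -> str:
        return f"{self.from_aa}{self.site}{self.to_aa}"


@dataclass
class HairpinParams:
    """Tunable coarse-grained force-field parameters.

    The hairpin model has no published coarse-grained parameterization; the
    defaults below are model choices documented in the methods note and are
    all overridable.
    """

    bond_k: float = 10.0           # kcal mol⁻¹ Å⁻², chain and sidechain bonds
    attach_k: float = 60.0         # kcal mol⁻¹ Å⁻², H/O attachment bonds
    angle_k: float = 4.0           # kcal mol⁻¹ Å⁻², i→i+2 backbone stiffness bonds
    trp_depth: float = 2.0         # Trp–Trp contact well, kcal mol⁻¹
    ser_depth: float = 0.4         # serine-level replacement depth
    hbond_contact_depth: float = 6.0  # effective H···O well of a native hydrogen
                                      # bond (includes implicit sheet cohesion)
    strand_contact_depth: float = 4.0  # cross-strand backbone cohesion wells
    epsilon_r: float = 10.0        # relative permittivity (implicit solvent)
    distance_dependent_dielectric: bool = False  # if True, ε_eff = ε_r · r
    repulsion_eps: float = 0.05    # excluded-volume prefactor, kcal mol⁻¹
    repulsion_sigma: float = 3.0   # Å
    strand_rise: float = 3.3       # Å per residue along a strand
    strand_sep: float = 4.7        # Å between strands; native r_ee
    charge_sites: dict = field(default_factory=lambda: {5: -1.0, 8: +1.0, 12: +1.0})
    contact_depths: dict = field(default_factory=dict)  # pair -> depth

    def __post_init__(self):
        if not self.contact_depths:
            self.contact_depths = {p: self.trp_depth for p in TRP_CONTACT_PAIRS}


def wild_type_params() -> HairpinParams:
    return HairpinParams()


def apply_mutation(params: HairpinParams, spec: MutationSpec,
                   sequence: str = WT_SEQUENCE) -> HairpinParams:
    """Return a new parameter set with one mutation applied."""
    if sequence[spec.site - 1] != spec.from_aa:
        raise ValueError(
            f"mutation {spec} inconsistent with sequence: position {spec.site} "
            f"is {sequence[spec.site - 1]}")
    new = replace(params, charge_sites=dict(params.charge_sites),
                  contact_depths=dict(params.contact_depths))
    if spec.from_aa in ("E", "K") and spec.to_aa == "L":
        new.charge_sites[spec.site] = 0.0
    elif spec.from_aa == "W" and spec.to_aa == "S":
        for pair in TRP_CONTACT_PAIRS:
            if spec.site in pair:
                new.contact_depths[pair] = params.ser_depth
    else:
        raise ValueError(f"unsupported mutation {spec}")
    return new


def revert_mutation(params: HairpinParams, spec: MutationSpec,
                    reference: HairpinParams | None = None) -> HairpinParams:
    """Undo a mutation by restoring the wild-type value of the edited terms."""
    reference = reference or wild_type_params()
    new = replace(params, charge_sites=dict(params.charge_sites),
                  contact_depths=dict(params.contact_depths))
    if spec.from_aa in ("E", "K"):
        new.charge_sites[spec.site] = reference.charge_sites.get(spec.site, 0.0)
    else:
        for pair in TRP_CONTACT_PAIRS:
            if spec.site in pair:
                new.contact_depths[pair] = reference.contact_depths[pair]
    return new


def _native_geometry(params: HairpinParams):
    """Ideal two-strand antiparallel hairpin with r_ee = strand_sep (4.7 Å).

    Strand 1 holds residues 1–6 at x = 0 running up the z axis; strand 2
    holds residues 7–12 at x = strand_sep running back down, so residue pairs
    (i, 13−i) face each other at equal z.  Sidechain beads sit at +y; donor
    hydrogens (residues 1–5) and acceptor carbonyl oxygens (residues 8–12)
    point into the inter-strand gap so that the five native hydrogen bonds
    satisfy the 3.0 Å / 40° geometric criterion with margin.
    """
    rise, sep = params.strand_rise, params.strand_sep
    positions, labels = [], []
    backbone, sidechain = {}, {}
    donor_h, acceptor_o = {}, {}

    for res in range(1, 13):
        if res <= 6:
            b = np.array([0.0, 0.0, (res - 1) * rise])
            inward = np.array([1.0, 0.0, 0.0])
        else:
            b = np.array([sep, 0.0, (12 - res) * rise])
            inward = np.array([-1.0, 0.0, 0.0])
        backbone[res] = len(positions)
        positions.append(b)
        labels.append(ParticleLabel(res, "backbone"))
        sidechain[res] = len(positions)
        positions.append(b + np.array([0.0, 2.0, 0.0]))
        labels.append(ParticleLabel(res, "sidechain"))
        if any(res == d for d, _ in NATIVE_HBOND_PAIRS):
            donor_h[res] = len(positions)
            positions.append(b + 1.0 * inward)
            labels.append(ParticleLabel(res, "donor_h"))
        if any(res == a for _, a in NATIVE_HBOND_PAIRS):
            acceptor_o[res] = len(positions)
            positions.append(b + 2.0 * inward)
            labels.append(ParticleLabel(res, "acceptor_o"))
    return (np.array(positions), labels, backbone, sidechain, donor_h, acceptor_o)


class HairpinForceField(ForceProvider):
    """Gō-like coarse-grained force field for the 12-residue hairpin.

    Terms: harmonic bonds (chain, backbone–sidechain, backbone–H/O),
    12–10 native-contact wells (Trp–Trp pairs and the cross-strand zipper),
    screened Coulomb between charged sidechains, and a soft r⁻¹² excluded
    volume between all remaining non-bonded, non-same-residue pairs.
    """

    def __init__(self, system: ParticleSystem, params: HairpinParams,
                 wildtype_params: HairpinParams | None = None):
        self.params = params
        self.wildtype_params = wildtype_params or wild_type_params()
        self._labels = system.particle_labels
        n = system.n_particles
        self._n = n

        self._bond_i = np.array([t.pair[0] for t in system.bonded_terms], dtype=int)
        self._bond_j = np.array([t.pair[1] for t in system.bonded_terms], dtype=int)
        self._bond_r0 = np.array([t.r0 for t in system.bonded_terms])
        self._bond_k = np.array([t.k for t in system.bonded_terms])

        self._con_i = np.array([t.pair[0] for t in system.contact_terms], dtype=int)
        self._con_j = np.array([t.pair[1] for t in system.contact_terms], dtype=int)
        self._con_eps = np.array([t.depth for t in system.contact_terms])
        self._con_r0 = np.array([t.r0 for t in system.contact_terms])

        q = system.charges
        charged = np.nonzero(q)[0]
        qi, qj = [], []
        for a in range(len(charged)):
            for b in range(a + 1, len(charged)):
                qi.append(charged[a])
                qj.append(charged[b])
        self._q_i = np.array(qi, dtype=int)
        self._q_j = np.array(qj, dtype=int)
        self._q_prod = q[self._q_i] * q[self._q_j] if len(qi) else np.zeros(0)

        bonded = {tuple(sorted(p)) for p in zip(self._bond_i, self._bond_j)}
        contact = {tuple(sorted(p)) for p in zip(self._con_i, self._con_j)}
        ri, rj = [], []
        for a in range(n):
            for b in range(a + 1, n):
                if (a, b) in bonded or (a, b) in contact:
                    continue
                if self._labels[a].residue == self._labels[b].residue:
                    continue
                ri.append(a)
                rj.append(b)
        self._rep_i = np.array(ri, dtype=int)
        self._rep_j = np.array(rj, dtype=int)

        # all pair terms concatenated in a fixed order, with a signed
        # incidence matrix so force scatter is a single matrix product
        self._all_i = np.concatenate([self._bond_i, self._con_i, self._q_i, self._rep_i])
        self._all_j = np.concatenate([self._bond_j, self._con_j, self._q_j, self._rep_j])
        nb, nc, nq = len(self._bond_i), len(self._con_i), len(self._q_i)
        self._sl_bond = slice(0, nb)
        self._sl_con = slice(nb, nb + nc)
        self._sl_q = slice(nb + nc, nb + nc + nq)
        self._sl_rep = slice(nb + nc + nq, len(self._all_i))
        incidence = np.zeros((len(self._all_i), n))
        incidence[np.arange(len(self._all_i)), self._all_j] = 1.0
        incidence[np.arange(len(self._all_i)), self._all_i] -= 1.0
        self._incidence_t = np.ascontiguousarray(incidence.T)  # (n, P)

    # -- internals ---------------------------------------------------------

    def _pair_geom(self, positions, i, j):
        d = positions[..., j, :] - positions[..., i, :]
        r = np.sqrt(np.sum(d * d, axis=-1))
        return d, r

    def _coulomb(self, r, q_prod):
        p = self.params
        if p.distance_dependent_dielectric:
            e = COULOMB_K * q_prod / (p.epsilon_r * r**2)
            dedr = -2.0 * e / r
        else:
            e = COULOMB_K * q_prod / (p.epsilon_r * r)
            dedr = -e / r
        return e, dedr

    def _repulsion(self, r):
        p = self.params
        x = (p.repulsion_sigma / r) ** 12
        e = p.repulsion_eps * x
        dedr = -12.0 * e / r
        return e, dedr

    @staticmethod
    def _contact_1210(r, eps, r0):
        s12 = (r0 / r) ** 12
        s10 = (r0 / r) ** 10
        e = eps * (5.0 * s12 - 6.0 * s10)
        dedr = eps * (-60.0 * s12 + 60.0 * s10) / r
        return e, dedr

    def energy_forces(self, positions):
        positions = np.asarray(positions, dtype=float)
        d, r = self._pair_geom(positions, self._all_i, self._all_j)

        e = np.empty_like(r)
        dedr = np.empty_like(r)
        sl = self._sl_bond
        e[..., sl] = 0.5 * self._bond_k * (r[..., sl] - self._bond_r0) ** 2
        dedr[..., sl] = self._bond_k * (r[..., sl] - self._bond_r0)
        sl = self._sl_con
        e[..., sl], dedr[..., sl] = self._contact_1210(r[..., sl], self._con_eps,
                                                      self._con_r0)
        sl = self._sl_q
        e[..., sl], dedr[..., sl] = self._coulomb(r[..., sl], self._q_prod)
        sl = self._sl_rep
        e[..., sl], dedr[..., sl] = self._repulsion(r[..., sl])

        energy = np.sum(e, axis=-1)
        # pair force on particle j is −dE/dr · d̂; incidence matrix carries the
        # +j / −i bookkeeping in one contraction
        pair_f = (-dedr / r)[..., None] * d
        forces = np.matmul(self._incidence_t, pair_f)
        return energy, forces

    def pair_energy(self, positions, idx_a, idx_b):
        """Nonbonded (contact + Coulomb + excluded-volume) energy between two
        disjoint particle subsets; symmetric in its arguments."""
        positions = np.asarray(positions, dtype=float)
        set_a, set_b = set(int(i) for i in idx_a), set(int(i) for i in idx_b)
        if set_a & set_b:
            raise ValueError("pair_energy requires disjoint particle subsets")

        def crossing(i_arr, j_arr):
            return np.array([
                k for k in range(len(i_arr))
                if (i_arr[k] in set_a and j_arr[k] in set_b)
                or (i_arr[k] in set_b and j_arr[k] in set_a)], dtype=int)

        energy = np.zeros(positions.shape[:-2])
        sel = crossing(self._con_i, self._con_j)
        if len(sel):
            _, r = self._pair_geom(positions, self._con_i[sel], self._con_j[sel])
            e, _ = self._contact_1210(r, self._con_eps[sel], self._con_r0[sel])
            energy = energy + np.sum(e, axis=-1)
        sel = crossing(self._q_i, self._q_j)
        if len(sel):
            _, r = self._pair_geom(positions, self._q_i[sel], self._q_j[sel])
            e, _ = self._coulomb(r, self._q_prod[sel])
            energy = energy + np.sum(e, axis=-1)
        sel = crossing(self._rep_i, self._rep_j)
        if len(sel):
            _, r = self._pair_geom(positions, self._rep_i[sel], self._rep_j[sel])
            e, _ = self._repulsion(r)
            energy = energy + np.sum(e, axis=-1)
        return energy


def make_hairpin_system(sequence: str = WT_SEQUENCE,
                        mutations: Sequence[MutationSpec | str] = (),
                        params: HairpinParams | None = None,
                        ) -> tuple[ParticleSystem, HairpinForceField]:
    """Build the coarse-grained hairpin and its force field.

    The wild-type model carries charges −1 on the Glu5 sidechain and +1 on
    the Lys8 and Lys12 sidechains, native hydrophobic Trp–Trp contacts
    2–11 and 4–9, and a cross-strand hydrogen-bond zipper realized both as
    donor/acceptor bead geometry (for counting) and as native contacts (for
    mechanics).  Mutations edit the parameter set: E5L/K8L zero the site
    charge, W→S weakens the affected Trp contact to a serine-level depth.
    """
    if len(sequence) != 12:
        raise ValueError("hairpin sequence must have 12 residues")
    params = params or wild_type_params()
    wt_params = params
    specs = [MutationSpec.parse(m) if isinstance(m, str) else m for m in mutations]
    for spec in specs:
        params = apply_mutation(params, spec, sequence)

    positions, labels, backbone, sidechain, donor_h, acceptor_o = _native_geometry(params)
    n = len(positions)
    masses = np.zeros(n)
    charges = np.zeros(n)
    for i, lab in enumerate(labels):
        aa = sequence[lab.residue - 1]
        if lab.role == "backbone":
            masses[i] = _BACKBONE_MASS
        elif lab.role == "sidechain":
            masses[i] = max(_SIDECHAIN_MASS.get(aa, 57.0), 12.0)
        elif lab.role == "donor_h":
            masses[i] = 1.0
        else:  # acceptor_o
            masses[i] = 16.0
    for res, q in params.charge_sites.items():
        charges[sidechain[res]] = q

    def native_r0(i, j):
        return float(np.linalg.norm(positions[i] - positions[j]))

    bonds = []
    for res in range(1, 12):
        i, j = backbone[res], backbone[res + 1]
        bonds.append(BondTerm((i, j), native_r0(i, j), params.bond_k))
    # weak i→i+2 bonds act as bending stiffness (angle-term surrogate)
    for res in range(1, 11):
        i, j = backbone[res], backbone[res + 2]
        bonds.append(BondTerm((i, j), native_r0(i, j), params.angle_k))
    for res in range(1, 13):
        i, j = backbone[res], sidechain[res]
        bonds.append(BondTerm((i, j), native_r0(i, j), params.bond_k))
    for res, h in donor_h.items():
        bonds.append(BondTerm((backbone[res], h), 1.0, params.attach_k))
    for res, o in acceptor_o.items():
        bonds.append(BondTerm((backbone[res], o), 2.0, params.attach_k))

    contacts = []
    for pair in TRP_CONTACT_PAIRS:
        i, j = sidechain[pair[0]], sidechain[pair[1]]
        contacts.append(ContactTerm((i, j), params.contact_depths[pair], native_r0(i, j)))
    # the hydrogen bond itself: an H···O well that also keeps the donor→H
    # vector aligned with the donor→acceptor direction
    for d_res, a_res in NATIVE_HBOND_PAIRS:
        i, j = donor_h[d_res], acceptor_o[a_res]
        contacts.append(ContactTerm((i, j), params.hbond_contact_depth, native_r0(i, j)))
    # cross-strand backbone cohesion (native register i ↔ 13−i)
    for res in range(1, 7):
        i, j = backbone[res], backbone[13 - res]
        contacts.append(ContactTerm((i, j), params.strand_contact_depth,
                                    native_r0(i, j)))

    system = ParticleSystem(
        positions=positions,
        velocities=np.zeros((n, 3)),
        masses=masses,
        charges=charges,
        particle_labels=labels,
        bonded_terms=bonds,
        contact_terms=contacts,
    )
    provider = HairpinForceField(system, params, wildtype_params=wt_params)
    provider.backbone_index = dict(backbone)
    provider.sidechain_index = dict(sidechain)
    provider.donor_h_index = dict(donor_h)
    provider.acceptor_o_index = dict(acceptor_o)
    return system, provider


def residue_charge_map(system: ParticleSystem) -> dict[int, float]:
    """Net charge per residue (1-based), for quick inspection."""
    out: dict[int, float] = {}
    for q, lab in zip(system.charges, system.particle_labels):
        if q:
            out[lab.residue] = out.get(lab.residue, 0.0) + float(q)
    return out
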