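"""Langevin integrator and steered-pulling work accumulation."""

import numpy as np
import pytest

from asmdkit.constants import KB
from asmdkit.dynamics import (SteeringSchedule, ThermostatParams, end_to_end,
                              kinetic_energy, langevin_step,
                              maxwell_boltzmann_velocities, run_smd_ensemble,
                              run_smd_segment)
from asmdkit.systems import (ForceProvider, ParticleLabel, ParticleSystem,
                             make_analytic_system)


class _FreeProvider(ForceProvider):
    def energy_forces(self, positions):
        positions = np.asarray(positions, dtype=float)
        return np.zeros(positions.shape[:-2]), np.zeros_like(positions)


def _free_system(n, rng):
    return ParticleSystem(
        positions=rng.normal(0, 1, (n, 3)),
        velocities=np.zeros((n, 3)),
        masses=np.full(n, 12.0),
        charges=np.zeros(n),
        particle_labels=[ParticleLabel(1, "bead")] * n,
    )


class TestEndToEnd:
    def test_axis_aligned(self):
        pos = np.array([[0.0, 0, 0], [0, 0, 4.0]])
        assert end_to_end(pos, 0, 1) == pytest.approx(4.0)

    def test_pythagorean(self):
        pos = np.array([[0.0, 0, 0], [3.0, 4.0, 0]])
        assert end_to_end(pos, 0, 1) == pytest.approx(5.0)

    def test_random_pair_matches_direct_formula(self, rng):
        pos = rng.normal(0, 10, (5, 3))
        expected = np.sqrt(((pos[3] - pos[1]) ** 2).sum())
        assert end_to_end(pos, 1, 3) == pytest.approx(expected)

    def test_identical_indices_rejected(self):
        with pytest.raises(ValueError):
            end_to_end(np.zeros((2, 3)), 1, 1)


class TestLangevinStep:
    def test_symplectic_limit_conserves_energy(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=0.0, z_init=1.0)
        thermo = ThermostatParams(temperature=0.0, friction=0.0, timestep=1e-3)
        out = langevin_step(system, provider, thermo, n_steps=10_000, fixed=[0])
        e0 = provider.energy(system.positions) + kinetic_energy(
            system.velocities, system.masses)
        e1 = provider.energy(out.positions) + kinetic_energy(
            out.velocities, out.masses)
        assert abs(e1 - e0) < 1e-4

    def test_equipartition_on_flat_potential(self, rng):
        # 100 free particles, 10⁵ total particle-steps of thermostatted motion
        system = _free_system(100, rng)
        provider = _FreeProvider()
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002,
                                  rng_seed=7)
        ke_per_dof = []
        cur = system
        for block in range(20):
            thermo = ThermostatParams(temperature=300.0, friction=5.0,
                                      timestep=0.002, rng_seed=block)
            cur = langevin_step(cur, provider, thermo, n_steps=50)
            ke_per_dof.append(kinetic_energy(cur.velocities, cur.masses)
                              / (3 * cur.n_particles))
        target = 0.5 * KB * 300.0
        mean = np.mean(ke_per_dof[2:])  # discard equilibration blocks
        assert mean == pytest.approx(target, rel=0.05)

    def test_same_seed_is_bitwise_identical(self, rng):
        system = _free_system(5, rng)
        provider = _FreeProvider()
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002,
                                  rng_seed=42)
        a = langevin_step(system, provider, thermo, n_steps=200)
        b = langevin_step(system, provider, thermo, n_steps=200)
        assert np.array_equal(a.positions, b.positions)
        assert np.array_equal(a.velocities, b.velocities)


class TestMaxwellBoltzmann:
    def test_variance_matches_temperature(self):
        rng = np.random.default_rng(0)
        masses = np.full(10_000, 12.0)
        v = maxwell_boltzmann_velocities(masses, 300.0, rng)
        ke_per_dof = kinetic_energy(v, masses) / (3 * len(masses))
        target = 0.5 * KB * 300.0
        se = target * np.sqrt(2.0 / (3 * len(masses)))
        assert abs(ke_per_dof - target) < 3 * se


class TestSMDSegment:
    def _schedule(self, **kw):
        base = dict(anchor_particle=0, pulled_particle=1, r_start=1.0, r_end=2.0,
                    pull_velocity=0.05, spring_k=100.0, coordinate="projection")
        base.update(kw)
        return SteeringSchedule(**base)

    def test_flat_quasistatic_work_is_zero(self):
        system, provider = make_analytic_system("flat", z_init=1.0)
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002)
        rec = run_smd_segment(system, provider,
                              self._schedule(pull_velocity=0.02), thermo,
                              (1.0, 2.0), seed=3, record_stride=50)
        assert abs(rec.final_work) < 0.1

    def test_harmonic_slow_pull_matches_potential_difference(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=1.0, z_init=1.0)
        thermo = ThermostatParams(temperature=0.0, friction=5.0, timestep=0.002)
        rec = run_smd_segment(system, provider,
                              self._schedule(pull_velocity=0.02), thermo,
                              (1.0, 2.0), seed=0, record_stride=50)
        # U(2) − U(1) = 1.0 for the overdamped zero-temperature pull
        assert rec.final_work == pytest.approx(1.0, abs=0.05)

    def test_zero_length_window(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=1.0, z_init=1.0)
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002)
        rec = run_smd_segment(system, provider, self._schedule(), thermo,
                              (1.0, 1.0), seed=0)
        assert rec.final_work == 0.0
        assert len(rec.times) == 1

    def test_anchor_particle_never_moves(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=1.0, z_init=1.0)
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002)
        rec = run_smd_segment(system, provider, self._schedule(), thermo,
                              (1.0, 2.0), seed=5, record_stride=20)
        anchor_coords = rec.frames[:, 0, :]
        assert np.all(anchor_coords == system.positions[0])

    def test_work_series_starts_at_zero_and_is_continuous(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=1.0, z_init=1.0)
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002)
        sched = self._schedule()
        rec = run_smd_segment(system, provider, sched, thermo, (1.0, 2.0),
                              seed=5, record_stride=1)
        assert rec.work[0] == 0.0
        assert np.all(np.diff(rec.times) > 0)
        dt = thermo.timestep
        max_ext = np.abs(rec.r_ee - rec.restraint_center).max() + 0.1
        bound = sched.spring_k * sched.pull_velocity * dt * max_ext
        assert np.abs(np.diff(rec.work)).max() <= bound + 1e-12

    def test_conservative_identity_at_zero_temperature(self):
        # T = 0, friction = 0: work equals ΔU + residual spring energy + ΔKE
        system, provider = make_analytic_system("harmonic", k=2.0, x0=0.0, z_init=1.0)
        thermo = ThermostatParams(temperature=0.0, friction=0.0, timestep=1e-3)
        sched = self._schedule()
        rec = run_smd_segment(system, provider, sched, thermo, (1.0, 2.0),
                              seed=0, record_stride=100)
        zf = rec.frames[-1][1, 2]
        total_f = (0.5 * 2.0 * zf**2 + 0.5 * sched.spring_k * (zf - 2.0) ** 2
                   + kinetic_energy(rec.final_velocities, system.masses))
        total_0 = 0.5 * 2.0 * 1.0**2
        assert rec.final_work == pytest.approx(total_f - total_0, abs=1e-3)

    def test_ensemble_matches_individual_runs(self):
        system, provider = make_analytic_system("harmonic", k=2.0, x0=1.0, z_init=1.0)
        thermo = ThermostatParams(temperature=300.0, friction=5.0, timestep=0.002)
        sched = self._schedule()
        batch = run_smd_ensemble(system, provider, sched, thermo, (1.0, 1.5),
                                 seeds=[11, 22, 33], resample_temperature=300.0,
                                 record_stride=25)
        for seed, rec_b in zip([11, 22, 33], batch):
            rec_s = run_smd_ensemble(system, provider, sched, thermo, (1.0, 1.5),
                                     seeds=[seed], resample_temperature=300.0,
                                     record_stride=25)[0]
            assert np.array_equal(rec_b.work, rec_s.work)
            assert np.array_equal(rec_b.frames, rec_s.frames)

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            SteeringSchedule(0, 0, r_start=1.0, r_end=2.0)
        with pytest.raises(ValueError):
            SteeringSchedule(0, 1, r_start=2.0, r_end=1.0)
        with pytest.raises(ValueError):
            SteeringSchedule(0, 1, r_start=1.0, r_end=2.0, spring_k=0.0)
        with pytest.raises(ValueError):
            ThermostatParams(timestep=0.0)
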