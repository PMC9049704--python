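"""Staged nonequilibrium pulling in a harmonic well with an exact answer.

A single bead in U(z) = ½k(z−2)² is dragged from z = 0.5 to 3.5 Å by a
stiff moving restraint; per-stage Jarzynski averaging plus closest-work
contraction reassembles the free-energy profile, which for this system must
equal U(z) up to a constant.
"""

import numpy as np

from asmdkit import (ASMDConfig, SteeringSchedule, ThermostatParams,
                     analytic_pmf, make_analytic_system, run_asmd)

system, provider = make_analytic_system("harmonic", k=2.0, x0=2.0, z_init=0.5)
schedule = SteeringSchedule(anchor_particle=0, pulled_particle=1,
                            r_start=0.5, r_end=3.5, pull_velocity=0.05,
                            spring_k=100.0, coordinate="projection")
config = ASMDConfig(schedule=schedule,
                    thermostat=ThermostatParams(temperature=300.0, friction=5.0,
                                                timestep=0.002),
                    n_stages=10, n_traj_per_stage=50, master_seed=1)

profile, ensembles = run_asmd(system, provider, config)
exact = analytic_pmf(provider, profile.r_grid)
err = np.abs(profile.delta_A - exact).max()

print("stage ΔA increments (kcal/mol):",
      [f"{e.je_curve[-1]:+.3f}" for e in ensembles])
print(f"max |ΔA_estimated − U(z)| over the grid: {err:.3f} kcal/mol")
print("Each increment is the per-stage Jarzynski estimate; the total profile")
print("matches the planted potential to well under k_B T (0.596 kcal/mol).")
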