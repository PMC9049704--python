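"""Mechanically unfold the coarse-grained trpzip1-like β-hairpin.

The Cα bead of residue 1 is held fixed while residue 12 is pulled along the
end-to-end distance; the run uses desk-scale staging (short range, fast
pull, small ensembles) so it finishes in ~20 s.  Work spreads per stage are
the protocol's quality-control metric.
"""

import numpy as np

from asmdkit import (ASMDConfig, SteeringSchedule, ThermostatParams,
                     delta_A_at, make_hairpin_system, run_asmd)
from asmdkit.observables import count_hbonds, hairpin_intrapeptide_groups

system, provider = make_hairpin_system()   # wild type SWTWEGNKWTWK
donors, acceptors = hairpin_intrapeptide_groups(provider)
print("native intrapeptide hydrogen bonds:",
      count_hbonds(system.positions, donors, acceptors))

schedule = SteeringSchedule(
    anchor_particle=provider.backbone_index[1],
    pulled_particle=provider.backbone_index[12],
    r_start=4.7, r_end=16.0, pull_velocity=0.2, spring_k=20.0)
config = ASMDConfig(schedule=schedule,
                    thermostat=ThermostatParams(temperature=300.0, friction=5.0,
                                                timestep=0.002),
                    n_stages=4, n_traj_per_stage=10, master_seed=7)

profile, ensembles = run_asmd(system, provider, config)
for r, a in zip([6.0, 9.0, 12.0, 16.0], delta_A_at(profile, [6.0, 9.0, 12.0, 16.0])):
    print(f"ΔA at r_ee = {r:4.1f} Å: {a:6.2f} kcal/mol")
print("per-stage work spreads (kcal/mol):",
      [f"{e.work_spread:.1f}" for e in ensembles])
print("The PMF rises as the hydrogen-bond zipper and Trp–Trp contacts rupture;")
print("spreads exceed the 5 kcal/mol QC bound at this deliberately fast pull.")
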