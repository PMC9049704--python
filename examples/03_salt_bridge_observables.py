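"""Work-weighted observables on the constructed unfolding pathway.

The pathway fixture interpolates the hairpin from native to extended with a
transient approach of the Lys12 sidechain to Glu5 near r_ee ≈ 8.6 Å.  Under
the K8L parameter set (Lys8 charge removed) the 5–12 electrostatic pair is
free to act as a nonnative salt bridge; under E5L (Glu5 neutralized) it
cannot form at all.
"""

import numpy as np

from asmdkit.fixtures import gen_hairpin_pathway
from asmdkit.observables import (hairpin_intrapeptide_groups, hbond_series,
                                 pair_energy_series)

for label, mutations in [("K8L", ["K8L"]), ("E5L", ["E5L"])]:
    fx = gen_hairpin_pathway(mutations=mutations, seed=5)
    series = pair_energy_series(fx.ensembles, fx.system, (5, 12), fx.provider)
    i_min = int(np.argmin(series.values))
    print(f"{label}: min E(5,12) = {series.values.min():7.2f} kcal/mol "
          f"at r_ee = {series.r_grid[i_min]:.1f} Å; "
          f"value at r_ee = {series.r_grid[-1]:.0f} Å: {series.values[-1]:6.2f}")

fx = gen_hairpin_pathway(seed=5)
groups = hairpin_intrapeptide_groups(fx.provider)
hb = hbond_series(fx.ensembles, groups)
print("H-bond count along the pull (every 6th grid point):",
      np.round(hb.values[::6], 1))
print("K8L gains a deep transient 5–12 stabilization (the nonnative salt")
print("bridge); E5L cannot form it, and the intrapeptide hydrogen bonds")
print("unzip monotonically as the hairpin extends.")
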