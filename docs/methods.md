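# Methods

## Unit system and constants

Å, ps, amu, kcal mol⁻¹ and elementary charges throughout;
k_B = 0.0019872 kcal mol⁻¹ K⁻¹ (so 300 K ≈ 0.5962 kcal mol⁻¹) and the
Coulomb constant 332.0636 kcal Å mol⁻¹ e⁻². One kcal mol⁻¹ equals exactly
418.4 amu Å² ps⁻², the factor used to convert forces into accelerations.

## Langevin dynamics

The integrator is BAOAB: half kick, half drift, an exact
Ornstein–Uhlenbeck velocity update with multiplier e^(−γΔt) and noise
variance k_BT(1 − e^(−2γΔt))/m, half drift, half kick. With γ = 0 and
T = 0 it reduces to velocity Verlet, which the suite checks through energy
conservation (drift < 1e−4 kcal mol⁻¹ over 10⁴ steps at Δt = 1 fs).
Defaults: T = 300 K, γ = 5 ps⁻¹, Δt = 2 fs. The anchor particle is held
fixed by clamping its position and velocity each substep. Replicas of an
ensemble propagate as one batched array; every replica draws noise from
its own counter-seeded generator, so batched and one-at-a-time execution
are bitwise identical.

## Steering and work

The restraint ½k(ξ − c(t))² acts either on the anchor–pulled *distance*
(the peptide coordinate) or on the axis *projection* of the anchor→pulled
vector. The benchmark systems use the projection: the radial coordinate of
a free bead carries a 2k_BT·ln r Jacobian entropy which would otherwise
appear in the measured profile, whereas the projection PMF is exactly the
bare potential. The restraint-center schedule is an exact linear grid from
r_j to r_{j+1}, so stage boundaries land on round numbers; the effective
velocity differs from the nominal one only by timestep rounding. Work is
accumulated by trapezoidal quadrature of dW/dt = k·v·(c − ξ) on *every*
integrator step; frames may be subsampled, the work never is. Stage
termination is time-based (duration Δr/v). A restraint energy above a
configurable bound (default 10⁴ kcal mol⁻¹) aborts the run as a timestep
instability.

Reference protocol values (1 Å ns⁻¹, 20 stages over 4→44 Å, 100
trajectories per stage, 300 K, γ = 5 ps⁻¹) are the configuration defaults.
Desk-scale runs in the tests and examples use shorter ranges, faster pulls
(0.05–0.2 Å ps⁻¹) and smaller ensembles so each run completes in seconds
to tens of seconds; at those speeds per-stage work spreads legitimately
exceed the 5 kcal mol⁻¹ QC bound on the hairpin, and the flag is reported
rather than suppressed. The steering spring constant is never implied by
the protocol, so it is a mandatory config field (default 7.2 kcal mol⁻¹ Å⁻²
in the API); benchmarks use a stiff 100 kcal mol⁻¹ Å⁻² spring so the
profile is measured at the restraint center with sub-0.1 Å smoothing.
The thermostat literature mixes vocabularies for damping ("decay period",
"damping time constant"); this implementation exposes a single friction
coefficient γ in ps⁻¹ and nothing else.

## Staged estimation and contraction

Per stage, the Jarzynski estimate is computed in the log domain (shift by
the minimum work) at every logged point from the running works of all
trajectories, giving a continuous within-stage curve that is 0 at the
stage start. Contraction picks argmin |W_i(final) − ΔA_stage|, ties to the
lowest index; the selected trajectory's final coordinates seed the next
stage and all velocities are re-randomized from the Maxwell–Boltzmann
distribution. Per-trajectory seeds derive deterministically from
(master_seed, stage, replica) via `numpy.random.SeedSequence`, so a rerun
with the same master seed is bitwise identical. Stage curves are chained
by offsetting each by the accumulated value at its left boundary
(continuity holds by construction); the minimum is subtracted only after
full assembly. If the system's initial end-to-end distance differs from
r_start by more than 0.5 Å, a 10 ps restrained hold at the first boundary
precedes pulling (no work is logged during the hold).

## The coarse-grained hairpin

The 12-residue hairpin is a bead model: one backbone and one sidechain
bead per residue, plus explicit donor-hydrogen beads on residues 1–5 and
acceptor-oxygen beads on residues 8–12 realizing the five native
cross-strand hydrogen bonds (1→12 … 5→8). The native geometry is an ideal
antiparallel two-strand hairpin with 3.3 Å rise, 4.7 Å strand separation
(hence native r_ee = 4.7 Å, matching the equilibrium minimum of the
solvated peptide), donor–acceptor distances of 2.7 Å and perfectly aligned
D→H vectors, so the geometric criterion is met with margin at the start.

Energy terms, with defaults:

| term | form | default |
|---|---|---|
| chain/sidechain bonds | ½k(r−r₀)² | k = 10 kcal mol⁻¹ Å⁻² |
| H/O attachment bonds | ½k(r−r₀)² | k = 60 |
| i→i+2 stiffness bonds | ½k(r−r₀)² | k = 4 (angle-term surrogate) |
| native contacts | ε(5(r₀/r)¹² − 6(r₀/r)¹⁰) | Trp–Trp ε = 2.0; Ser level 0.4; H···O ε = 6.0; cross-strand backbone ε = 4.0 |
| electrostatics | 332.0636·q₁q₂/(ε_r·r) | ε_r = 10; optional ε_eff = ε_r·r mode |
| excluded volume | ε_rep(σ/r)¹² | ε_rep = 0.05, σ = 3.0 Å |

Charges: −1 on the Glu5 sidechain, +1 on Lys8 and Lys12. Mutations are
declarative parameter edits — E5L and K8L zero the site charge, W→S drops
the affected Trp contact to the serine depth — and are exactly reversible
against the stored wild-type set. No all-atom parameterization of this
peptide at coarse-grained resolution exists, so every depth above is a
model choice, chosen so that the native basin is metastable over tens of
picoseconds at 300 K (3–5 of the 5 hydrogen bonds persist in unrestrained
equilibrium runs) while still unzipping under pulling; the H···O and
backbone cohesion wells absorb the sheet-packing and solvent-exclusion
stabilization that the bead model does not represent explicitly. They are
all exposed in `HairpinParams`.

## Observables

Hydrogen bonds are counted between a donor group (each donor carries one
hydrogen) and an acceptor group: inclusive cutoffs, donor–acceptor
distance ≤ 3.0 Å and angle between the D→H and D→A vectors ≤ 40°
(configurable; this is the common trajectory-analysis convention for "the
angle formed between them"), self-pairs excluded. Pair interaction
energies sum the provider's nonbonded terms (contacts, electrostatics,
excluded volume) between the particle sets of two residues and are
symmetric by construction. Both series are work-weighted per grid point
using the running work at that point; grid values between stored frames
use nearest-frame values. RMSD uses Kabsch superposition (SVD with a
propriety flip) computed from explicitly rotated residuals, which is
accurate to ~1e−12 Å near zero where the textbook trace formula loses
eight digits to cancellation; the tests cross-check it against an
independent quaternion-method implementation. Representative structures
come from the stage's selected trajectory, nearest frame by the nominal
(restraint-center) coordinate, earlier frame on ties.

## CD melt analysis

Mean molar ellipticity is [θ] = m·10⁶/(l·n·C) with m in millidegrees, l in
millimeters, n residues and C in µM — the unique constant consistent with
those units and the standard deg cm² dmol⁻¹ convention (the suite verifies
it against an explicit unit-conversion route). Replicates are averaged
before normalization. Normalization divides by the mean raw signal in the
5–8 °C window (×100); it is idempotent and fails loudly on a near-zero
baseline. T50 is the first downward crossing of 50%, linearly
interpolated, located on a 3-point median-filtered copy so single-point
noise cannot register as a crossing, with the raw curve retained; a curve
that never drops through 50% yields an explicit no-T50 result rather than
a number. This deliberately model-free summary matches the refusal to fit
two-state thermodynamics to visibly multi-state curves. Ranking sorts by
T50 descending and merges consecutive values within 0.4 °C (the replicate
standard-deviation scale) into tie groups.

## Synthetic fixtures

All fixtures are pure functions of their parameters and a seed.

* *Planted hydrogen-bond configurations* place donor/H/acceptor triples in
  cells separated far beyond the cutoff; bonded triples satisfy the
  criterion with ≥0.1 Å / 5° margin, decoys violate it with the same
  margin, so the true count is exact.
* *Staged work ensembles* draw final works uniformly in mean ± spread/2
  with linear accumulation, and can plant per-stage hydrogen-bond counts by
  building every frame from a planted configuration — the counting pipeline
  must then return an exact step profile.
* *Sigmoid melts* are logistic decays sampled at 5–90 °C in 1 °C steps
  (default width 5 °C, comparable to the broad measured transitions); with
  plateaus 100/0 the noise-free curve crosses 50% exactly at the midpoint.
* *Hairpin pathways* interpolate all beads from the native hairpin to an
  extended chain (solving for the interpolation fraction that realizes each
  requested r_ee), add per-bead Gaussian jitter, and optionally swing the
  residue-12 sidechain to a 2.8 Å approach of residue 5 inside a Gaussian
  window centered at r_ee = 8.6 Å — the constructed analogue of the
  transient nonnative 5–12 salt bridge observed in the K8L unfolding
  channel. The geometry is identical for every mutant; only the force
  field decides whether the approach is stabilizing, which is what the
  K8L-vs-E5L comparison tests. Because the approach is planted, these
  fixtures demonstrate the *energetic* consequence of the bridge, not its
  spontaneous formation; desk-scale Langevin runs of the bead model do not
  nucleate it on their own.

## What desk-scale results do and do not show

The analytic benchmarks validate the estimator end to end against exact
answers (harmonic recovery to ≤0.3 kcal mol⁻¹, a planted 1.0 kcal mol⁻¹
barrier to ±0.2, single-stage vs ten-stage agreement within Monte-Carlo
error). The hairpin model reproduces the qualitative phenomenology —
five native hydrogen bonds unzipping along the pull, Trp-contact and
salt-bridge sensitivity to the six mutations, the K8L-specific nonnative
bridge — but its parameters are effective, its solvent is implicit in two
numbers (ε_r and the excluded-volume term), and its absolute free energies
are not comparable to explicit-solvent all-atom values. Quantitative PMFs
for the real peptides require the reference explicit-solvent protocol
(100 trajectories × 20 stages per peptide), far outside a desk budget; the
force-provider contract exists so an external engine can be attached for
that purpose.
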