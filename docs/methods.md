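# Methods

This note documents the model, the numerical choices, the shipped default
parameter set and its rationale, what the synthetic-data generators emulate,
and the known limitations. Everything quantitative stated here is computed by
the test suite or the example scripts; nothing is asserted beyond what the
code measures.

## Units and dynamics

All quantities are non-dimensional: the INERT bead radius, the INERT–INERT
repulsive strength and the particle mass define the units of length, energy
and mass (σ_INERT = ε_R,INERT–INERT = m = 1). Time follows from
σ√(m/ε). Defaults: k_BT = 0.5, friction γ = 0.5, time step Δt = 5·10⁻³.

Langevin dynamics is integrated with a symmetric splitting:

    p ← p e^{−γΔt/2m} + f Δt/2 + η
    r ← r + p Δt/m
    p ← (p + f Δt/2) e^{−γΔt/2m} + η′

where each noise component is Gaussian with variance
m(1 − e^{−γΔt/m}) k_BT — the exact Ornstein–Uhlenbeck variance for a half
step. At γ = 0 the scheme reduces to velocity Verlet (tested: relative energy
drift < 10⁻⁴ over 10⁴ steps for a harmonic dimer); at finite γ it samples
the canonical distribution of a harmonic well to within the statistical
tests' resolution (equipartition within 3 SE at 10⁶ samples, KS p > 0.01).
Forces are recomputed once per step; noise is drawn per particle per
half-kick in particle-index order from a single seeded stream, which makes
whole runs bit-reproducible and checkpoint/resume bit-exact (tested).

## Potentials

* Nonbonded pairs: U = 4ε_R(σ_ij/r)¹² − 4ε_A(σ_ij/r)⁶ with σ_ij the mean of
  the two particle radii, truncated and shifted to zero at r_c = 2.5σ_ij.
  The cutoff is a numerical choice (configurable); at the densities simulated
  its effect is negligible, and the shift keeps the energy continuous.
* Tetrahedron edges: zero-rest-length harmonic springs U = k r²/2 on all six
  edges (complete graph on the four shell particles). The literal zero rest
  length is intentional: the cluster's finite size emerges from the balance
  between spring tension and shell-particle volume exclusion.
* Ring bonds: FENE, U = −½ k_F r_max² log[1 − (r/r_max)²], k_F = 30,
  r_max = 1.5 (standard bead–spring polymer values). Bonded pairs also keep
  their nonbonded repulsion, which sets the bond length near 0.97.
* Ring angles: U = ½ k_A(θ − θ₀)² on every consecutive triple with the
  regular-polygon rest angle θ₀ = π(1 − 2/N_ring); k_A = 10. cos θ is clamped
  into [−1, 1] and sin θ floored at 10⁻¹² for collinear degeneracies; forces
  are analytic gradients (finite-difference tested at 10⁻⁶ relative).
* Wall: one-body r⁻¹² terms at the six inner-box faces (ε_wall = σ_wall = 1,
  L_inner = 30), applied to motor particles only.

Energy evaluation is a fused O(N²) pass (numba) with minimum-image
displacements in the periodic outer box (L_outer = 34); the system never
exceeds ~150 particles, so neighbor lists are unnecessary.

## Default interaction parameters ("Motor II-like")

The published text specifies the model's qualitative interaction pattern but
not the numerical pair strengths, which are therefore configuration in this
package. The shipped defaults were chosen by short exploratory simulations to
satisfy the stated constraints, and are:

| interaction | value | role |
|---|---|---|
| TET–TET bond k | 150 | stiff cage; resists the deformations that release CENT |
| ε_R(TET–CENT) | 0.1 | CENT sits at low strain inside the tight cage |
| ε_A(CAT*–TET*) | 2.0 | fuel adsorbs at catalytic sites; cage stress catalyzes escape |
| ε_A(CAT1–CENT) | 2.0 | released C held at the site's middle particle (blocking group) |
| ε_A(CAT2/3–CENT) | 0.8 | secondary retention at the site |
| ε_A(SHUTTLE–BIND) | 0.8 | shuttle localizes at binding sites yet still hops |
| ε_R(SHUTTLE–CENT) | 5.0 | blocking group effectively excludes the shuttle |
| all other pairs | ε_R = 1, ε_A = 0 | volume exclusion only |

Geometry matters more than strength for fuel metastability. The reaction
coordinate r (CENT to shell center of mass) must satisfy r ≤ 0.25 in the
caged state and reach 0.8 only on escape, which forces a *tight* cage: the
shipped k = 150, ε_R(TET–CENT) = 0.1 combination equilibrates at edge length
≈ 0.95, holds the caged CENT at r ≈ 0.03–0.13, and gives a bulk FTC lifetime
of order 10³ time units at k_BT = 0.5 — long against the chemostat period
(0.5) yet short enough that decompositions are observed in desk-scale runs.
Softer or wider cages either eject the CENT mechanically (strain ≫ barrier)
or place the caged CENT beyond the r-thresholds altogether; both failure
modes were mapped empirically before fixing the defaults. Initial cluster
templates are regular tetrahedra at the equilibrium edge with the CENT at the
center.

The motor is built as a planar regular 30-gon of radius N/2π ≈ 4.77 (bead
spacing ≈ 1) with the 12-bead shuttle ring threaded perpendicular around the
inert bead at index 24; any interlocked pose (Gauss linking number ±1) is
acceptable since steady-state observables cannot depend on the initial pose.
Interlocking is maintained by volume exclusion alone — no bonded terms join
the rings — and is verified by recomputing the linking number. Clockwise is
defined as increasing large-ring index, consistent with the CAT2–CAT1–CAT3
ordering on the clockwise side of each binding site. Runs begin with 10⁴
pre-equilibration steps (no chemostat) before production.

## Chemostats

Every move_period = 100 MD steps, one trial is drawn uniformly from the six
options {insert, delete} × {FTC, ETC, C}, restricted to the shell between the
boxes. Working exclusively in the shifted chemical potential μ′ = μ − A⁰
removes any dependence on the standard-state volume; acceptance factors are

    delete: min[1, N e^{−β(ΔU + U⁰)} e^{−βμ′}]
    insert: min[1, (1/N′) e^{−β(ΔU − U⁰)} e^{+βμ′}]

with N the shell count of the species, U⁰ the copy's internal energy and ΔU
the total potential-energy change (computed by full re-evaluation; an
independent cross-energy check is tested). Under this convention an ideal
species equilibrates to a Poisson shell occupancy with mean e^{βμ′} — the
birth–death closed form the GCMC chain is tested against (total-variation
distance < 0.02 at 10⁶ sweeps). With μ′_FTC = 0.5 (β = 2) the shell mean e¹
scaled by the box/shell volume ratio 34³/(34³−30³) predicts ≈ 8.7 FTC in the
whole box; production runs measure ≈ 7.6–8.5, consistent with a small
interaction correction.

FTC and ETC insertions draw internal configurations from pre-generated
canonical reservoirs (default 10,000 members) sampled by single-particle
Metropolis displacements of one isolated cluster; each stored member carries
its internal energy, stored members are decorrelated by 20 sweeps, and FTC
members must still cage their CENT (r ≤ 0.25) — chains that escape restart
from the last valid member. Insertions are uniformly rotated (quaternion
SO(3)) and placed with the COM uniform over the shell; momenta of inserted
particles are Boltzmann-sampled, and momenta of deleted particles are
discarded (kinetic factors cancel for Boltzmann-sampled momenta).

Species identity for deletion is classification-based: a cluster is an FTC
only while r ≤ 0.25, an ETC only when its CENT is absent or escaped
(r ≥ 0.8); intermediates (0.25 < r < 0.8) are ineligible for either, and a
CENT is a deletable C only when free. A free C captured by an empty shell
(r ≤ 0.25) is re-associated at chemostat boundaries, so recombinations are
scored by the same hysteresis automaton as decompositions.

## Event detection and observables

Classification runs at every MD step (events are threshold-crossing-sensitive,
so subsampled frames are never used). The FTC/ETC label is latched with
two-threshold hysteresis (0.25 / 0.8): one DECOMPOSITION per completed
upward episode, flagged catalyzed when the cluster COM is within 2.0 of any
catalytic particle at the crossing instant; one RECOMBINATION per reverse
crossing. Blocking flags (free C within 1.2 of a site's CAT1) generate
ATTACH/CLEAVE events carrying r_tet,min — the distance from the implicated C
to the nearest tetrahedral shell — which later discriminates C-mediated from
cluster-mediated pathways (default split threshold 1.0, between the ~0.8
reaction-distance peak and the unmediated background).

Shuttle position is the index of the large-ring bead nearest the shuttle COM
(ties to the lowest index) — an intrinsically ring-local coordinate, so rigid
motion of the motor cannot create spurious cycles. Index increments are
unwrapped to (−15, +15]; each time the accumulated winding advances ±30 past
the last completed turn, a CW/CCW cycle is scored. The turn-crossing rule and
an endpoint-winding rule agree on net cycles; the former also defines the
per-direction counts. Bias, current and coupling follow the definitions in
the README, with undefined cases (no cycles, no catalyzed reactions) reported
as missing and excluded from replica averages.

## Eight-state model

Coarse states combine the shuttle's half-ring (the 15-bead arcs centred on
the two binding sites: indices 23–7 and 8–22; bead 7 belongs to the first
arc) with the two blocking flags. The state numbering is pinned by requiring
the far-cleavage transitions to be exactly 2→1, 3→4, 5→6, 8→7, which yields

    1=(1,0,0) 2=(1,0,1) 3=(1,1,1) 4=(1,1,0)
    5=(2,1,0) 6=(2,0,0) 7=(2,0,1) 8=(2,1,1)

(half, site-1 blocked, site-2 blocked). Geometry fixes the gating rule: the
catalytic site on a binding site's clockwise flank is the *close* site, so a
blocked close site forbids clockwise departure; ring moves with both sites
blocked are not edges of the graph, and transitions between unconnected
states (possible at finite Δt) are counted, reported and excluded from
estimation. The graph has 11 undirected edges and exactly four fundamental
cycles; the fully ratcheted cycle (1→2→7→6→5→4→1, found programmatically as
the unique two-ring-edge cycle avoiding both-blocked states and the
symmetric edge) requires one catalyzed attachment at each site per full
clockwise shuttle cycle, hence the maximum coupling of 1/2 that
`scripts/acceptance.py` reports.

Rates use the counting estimator k_AB = N_AB/(t_obs p_ss(A)) with
symmetry-equivalent transitions pooled; a pooled rate with zero source dwell
is reported missing rather than 0/0. Standard errors come from across-replica
scatter. Estimator consistency, the R-sign law (sign of net ring-edge flux
equals sign of the estimated affinity) and the detailed-balance limit R = 1
are all verified against exact Gillespie simulations of known generators.
Entropy production is computed as Σ_edges (net flux) × log(flux ratio) on
either the pooled graph or a pathway-resolved multigraph; the resolved model
never produces less entropy than the pooled one on the same data (tested),
the numerical face of the data-processing inequality.

## Synthetic-data generators

`fixtures` provides the oracles the analysis stack is tested against: exact
Gillespie trajectories on the eight-state graph (no discretization bias in
rate-recovery tests), ring-index walks with recorded true winding numbers,
Poisson event streams with labelled pathways and controlled r_tet,min
mixtures, and the closed-form Poisson occupancy of an ideal chemostatted
species. They emulate the *statistics* the estimators consume — not the
particle physics: passing estimator tests demonstrates correct analysis of
any trajectory with those statistics, while the physics of the particle model
itself is exercised separately by the scaled-down production run (fuel
metastability, motor catalysis, equilibrium symmetry).

## Problem sizes

Desk-scale defaults are deliberate: production-style checks use a single
replica of 10⁶ steps (t_obs = 5·10³) with ~50–100 particles, reservoirs of
10⁴ members, and estimator tests use Gillespie trajectories of t_obs ≈ 2·10⁴.
Headline motor statistics (bias/current/coupling curves vs μ′_FTC or γ) are
averages over many replicas of t_obs = 10⁶ in the original study design —
two orders of magnitude beyond the desk scale — so this package reports those
observables with per-replica standard errors and leaves replica counts to the
user's hardware. In the diffusion-limited default regime a full shuttle cycle
takes ~10⁴ time units, so short runs legitimately report bias/coupling as
missing.

## Known limitations

* The exact published pair-strength tables (Motor I/II) are not public in the
  available text; the defaults here reproduce the qualitative mechanism, not
  any specific printed rate values. Absolute chemical potentials are likewise
  out of reach — only μ′ is meaningful in this implementation.
* Insertion proposals are unbiased (no cavity bias); at strongly positive μ′
  the acceptance rate falls with density.
* Trajectory-level (fine-grained) entropy production of the particle dynamics
  is not computed; only Markov-model entropy rates are.
* The O(N²) force pass is tuned for ≲200 particles; larger boxes would need
  cell lists.
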