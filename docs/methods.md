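# Methods

## The model

`trisyn` simulates ion homeostasis at a glutamatergic tripartite synapse: a
presynaptic neuron and an astrocyte, each with a somatic and a small fixed
synaptic sub-compartment (presynaptic terminal / perisynaptic process), plus
a synaptic cleft and a shared, finite extracellular space (ECS).  The state
comprises 21 ordinary differential equations:

- molar amounts of Na⁺, K⁺, Cl⁻, Ca²⁺ and glutamate in the neuron and the
  astrocyte (10 states).  Na⁺/K⁺/Cl⁻ concentrations are shared between the
  somatic and synaptic compartments; Ca²⁺ and glutamate are confined to the
  synaptic sub-compartments;
- Hodgkin–Huxley gates m, h, n of the neuronal voltage-gated Na⁺ and K⁺
  channels (3 states);
- six vesicular glutamate pools: depot D, non-releasable N, readily
  releasable R and Ca²⁺-bound stages R₁, R₂, R₃ (6 states);
- the two somatic volumes W_n, W_a (2 states).

Everything else is algebraic.  Membrane potentials follow from the capacitor
relation V_i = (F/C_i) Σ z_X N_X^i, which includes a fixed amount of
impermeant intracellular anions (and astrocytic cations).  The ECS is closed
by conservation of volume (W_e = W_tot − W_n − W_a) and of each species'
total amount; the cleft ("fused") glutamate pool is the remainder of total
glutamate.  The unit system is mM / fmol / 10³ µm³ / ms / mV / pA / pF, in
which 1 fmol per 10³ µm³ is exactly 1 mM and no hidden conversion factors
are needed.

Transmembrane pathways: Goldman–Hodgkin–Katz (GHK) electrodiffusion for
voltage-gated and leak currents; the Na⁺/K⁺-ATPase (NKA) with a
Luo–Rudy-type voltage factor and Hill saturations in [Na⁺]ᵢ and [K⁺]ₑ — the
model's only energy-dependent process; KCC and NKCC1 as electroneutral
log-ratio cotransporters; the weakly rectifying astrocytic Kir4.1 channel
(vanishing at the Gibbs–Donnan condition); the 3:1 Na⁺/Ca²⁺ exchanger (NCX)
with an Eyring voltage dependence; and EAAT glutamate transporters carrying
1 Glu⁻ + 3 Na⁺ + 1 H⁺ in against 1 K⁺ (fixed trans-membrane proton ratio
0.66).  Volumes follow the osmotic pressure gradient linearly,
dW/dt = L_H₂O·RT·ΣΔ[X], with the impermeant ions included in the osmolyte
sum so the calibrated baseline is a genuine volume equilibrium.

Energy deprivation (ED) multiplies the pump by a smooth U-shaped waveform
that descends from 1 to a floor P_min between t_start and t_end; a
square-wave current of amplitude I_stim can be injected into the neuronal
Na⁺ equation; any pathway can be scaled by a blockade factor in [0, 1]
inside scheduled windows.

## Calibration

Everything the model does not tabulate is derived from the baseline resting
state (neuron at −65.5 mV, astrocyte at −80 mV, standard intracellular and
CSF-like extracellular composition; the package default ECS composition is
[Na⁺]ₑ = 152, [K⁺]ₑ = 3, [Cl⁻]ₑ = 135 mM, baseline cleft Ca²⁺ 1.8 mM and
cleft glutamate 0.1 µM):

1. **Impermeant ions** from five linear rest conditions: the two capacitor
   relations, osmotic balance of each soma against the ECS, and global
   electroneutrality.  The neuron carries only impermeant anions
   (≈302.01 fmol at the default baseline).
2. **Vesicle-cycle closure.**  The Ca²⁺-catalysed un-priming rate of the
   releasable pool is not independently known; it is recovered from the
   requirement that the configured baseline pool occupancies be a stationary
   point of the cycle (1.62×10⁻² ms⁻¹ at the defaults, the same order as the
   catalysed priming rate).  With it, the full 21-state baseline residual is
   ~10⁻¹² fmol/ms.
3. **Leak permeabilities.**  Each species' amount equation is linear in its
   own GHK leak permeability, so the ten leaks are solved directly from
   RHS = 0 at baseline.  A negative solution would signal an inconsistent
   baseline and raises.  When the pump is rescaled (P_scale ≠ 1) the leaks
   are recomputed so the baseline state is unchanged — in practice only the
   Na⁺ and K⁺ leaks move, since no other baseline budget contains the pump.

Calibration is idempotent and purely algebraic (no iterative fitting), and
its full output (impermeants, conserved totals, leaks, residual norms) is
the JSON calibration report.

## Parameters that matter, and two derived choices

All channel/transporter strengths, half-saturations and vesicle rates are
literature values taken as given (see `TransportParams`, `VesicleParams`).
Two pieces are not fully specified by their sources and are fixed here by
the model's own benchmark behaviour; both are config-selectable:

- **Voltage-gated Ca²⁺ activation.**  Only the permeability of the channel
  is known.  The activation must be effectively zero at rest (the baseline
  Ca²⁺ budget balances NCX against the Ca²⁺ leak alone, to 0.1%), so a
  high-threshold instantaneous Boltzmann is used,
  a(V) = σ((V − V½)/k)² with V½ = +12 mV, k = 5 mV, pinned so the
  stimulated-burst benchmark (25 pA, 10 s, realistic ECS) yields its
  reference count of ~475 action potentials.  The count varies only between
  ~464 and ~487 across all admissible high-threshold variants.
- **ED waveform steepness β.**  The reference protocol fixes P_min, t_start
  and t_end but not the ramp steepness.  β = 1.7 min⁻¹ is identified from
  the recovery dichotomy the protocol is known to produce at the large ECS
  fraction: a 5-minute half-capacity deprivation drives a deep Na⁺ excursion
  yet recovers, while a 15-minute one tips permanently.  Steeper ramps
  (β ≳ 1.9) tip already at 5 minutes; shallower ones (β ≲ 1.6) make the
  excursion unrealistically mild and abolish the NCX sensitivity of the
  outcome.  The waveform's half-crossing shift
  log(1/P_min − 1)/β diverges as P_min → 0; below P_min = 5% the shift is
  held at its 5% value so onset/offset times stay put.

One printed formula is knowingly corrected: the delayed-rectifier K⁺ current
gates as **n²** (the exponent of the source model the rate functions come
from), not n⁴.  With n⁴ the GHK Na⁺ window current overwhelms the rectifier
at −32 mV and the neuron cannot fire repetitively at any stimulus amplitude,
contradicting the benchmark burst and every oscillatory phenomenon the model
is known to produce.  Similarly, the pump's voltage factor uses the genuine
(reciprocal) Luo–Rudy form — the calibrated Na⁺/K⁺/Cl⁻/Ca²⁺/glutamate leaks
then land within ~1% of their reference values, which the non-reciprocal
variant misses threefold.  The KCC cotransporter is implemented as a true
symport (K⁺ and Cl⁻ both move with the thermodynamic flux); this sign choice
is what reproduces the reference Cl⁻ leak permeability exactly.

## Numerics

- **Integration**: `scipy.integrate.solve_ivp` (LSODA) on a numba-compiled
  right-hand side (~2 µs/evaluation; the long deprivation scenarios need
  ~4×10⁶ steps because minutes of model time are spent firing).  A readable
  object-based RHS is kept as the reference implementation and the two are
  asserted equal to machine precision in the test suite.  Default
  rtol = 10⁻⁸ with per-state absolute tolerances scaled to baseline
  magnitudes (the state spans 13 orders of magnitude, from the smallest
  vesicle pool at 2×10⁻¹¹ fmol to 450 fmol of K⁺).  The time span is split
  at stimulus/blockade edges; output is sampled at 10 samples/ms inside
  stimulation windows (spike counting: upward 0 mV crossings, 2 ms
  refractory) and coarsely elsewhere.
- **GHK and gate-rate singularities** are evaluated by series/limit branches
  inside a switch width of 10⁻⁷ in the exponent/argument.
- **Conservation** of each species, of volume and of total charge is
  algebraic (the ECS is the closure), so drift along trajectories is zero to
  round-off by construction; the tests recompute the totals from
  trajectories to verify this.
- **Equilibria and continuation.**  Newton with central finite-difference
  Jacobians, per-state scaled steps and full row/column equilibration (the
  Jacobian's eigenvalues span 10⁻⁹…10¹ ms⁻¹).  Branches in the pump
  parameter are continued by adaptive natural continuation with secant
  predictors; around folds the branch is re-parametrized by its
  fastest-varying ion/volume coordinate and the fold located as the extremum
  of p along the branch (scalar minimization, accuracy ≪10⁻⁵ in p).  Hopf
  points are sign changes of the largest complex-pair real part, refined by
  bisection.
- **A quasi-neutral direction.**  The vesicle-pool chain is linear and
  homogeneous in the pools at fixed free glutamate and Ca²⁺, so the overall
  pool scale relaxes on a multi-hour timescale (|Re λ| ~ 10⁻⁹ ms⁻¹ — below
  finite-difference noise) and the exact equilibrium branch has poles in the
  pool sector where the chain determinant crosses zero.  Stability
  classification therefore ignores eigenvalues with |Re| < 10⁻⁸ ms⁻¹, fold
  parametrization avoids pool coordinates, and the continuation steps across
  the isolated pool-sector singularities (re-seeding pools at baseline),
  which recovers the quasi-static branch that simulations actually follow —
  verified against brute-force simulation bisection of the tipping point to
  within one percentage point.

## What the scenarios show — and known limitations

At the defaults the model is bistable at full energy: a physiological rest
state (−65.5/−80 mV) coexists with a depolarized pathological state near
−33 mV sustained by the Na⁺ window current.  The resting branch ends in a
saddle-node near 64% (realistic ECS, α_e = 20%) or 57% (large ECS, α_e =
80%) of baseline pump capacity — smaller extracellular spaces are more
vulnerable — and the pathological branch loses stability via a supercritical
Hopf bifurcation near 142% of capacity, which doubling the baseline pump
strength shifts left of 100% (verified by the bistability classification),
making deprivation survivable and producing the transient spiking seen
during recovery.  Blocking the
voltage-gated Na⁺ or K⁺ channel for ten minutes rescues the established
pathological state; blocking NCX during a borderline deprivation tips it.

Known limitations.  (i) The stimulated cleft-glutamate transient comes out
near 60% relative change where ~30% is expected: the transient is the
quasi-static solution of the gross EAAT/leak glutamate balance, so its
relative size is insensitive to the baseline cleft concentration and to the
gated-Ca²⁺ variant, and is set entirely by the given transporter parameters
(the physiological ≫ pathological ordering is reproduced, 59% vs ~1%).
(ii) The astrocytic reference leak permeabilities cannot all be recovered
from the documented baseline (discrepancies up to ~2×); the package prefers
an internally consistent calibration, without which the baseline would not
be an equilibrium at all.  (iii) No spatial diffusion, gap junctions, pH
dynamics or postsynaptic compartment; temperature is fixed; vesicle packing
is energy-independent by assumption.  (iv) The model's Ca²⁺ handling has no
buffers, so presynaptic Ca²⁺ during bursts is set by NCX thermodynamics at
the depolarized inter-spike potential rather than by channel gating.
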