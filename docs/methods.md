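# Methods

## The quantity being measured

Two closed oriented curves γ₁, γ₂ have an integer linking number given by the
Gauss double integral

    Lk = (1/4π) ∮∮ (r₁ − r₂) · (dr₁ × dr₂) / |r₁ − r₂|³ .

Protein chains are open, so `dimerlink` computes two related quantities for a
two-chain (domain-swapped dimer) complex, both over the Cα backbones traversed
N→C:

* **Gaussian entanglement G′** — the discretised double integral evaluated
  directly on the two *open* chains. Not a topological invariant, but cheap,
  deterministic, and strongly correlated with the closed-curve linking number
  for intertwined dimers.
* **Closure-averaged linking number G** — each chain is artificially closed
  into a loop; each closure pair yields a true integer linking number, and G
  is the average of those integers over all closure pairs.

Discretisation uses the midpoint rule: a polygonal curve contributes one
segment per bond, with midpoint mᵢ and bond vector bᵢ, and

    G′ = (1/4π) Σᵢ Σⱼ (mᵢ − mⱼ) · (bᵢ × bⱼ) / |mᵢ − mⱼ|³ ,

summed over all pairs with i from one curve and j from the other (never within
a curve). The kernel is scale-free, invariant under common rigid motions, and
changes sign when one curve's orientation is reversed. For two smooth closed
curves the sum converges to the integer linking number; on a 400-vertex Hopf
link the error is below 10⁻².

A pair of segment midpoints closer than 10⁻⁹ Å makes the kernel numerically
meaningless; the sum aborts with an error naming the pair rather than
returning an inflated value. Crystallographic geometry (bond length ≈ 3.8 Å,
steric exclusion ≥ ~4 Å between non-bonded Cα) never comes near this guard.

## Chain extraction and integrity filter

Only `ATOM` records with atom name `CA` are used; waters, heteroatoms and
non-polymer chains are ignored. Alternate locations resolve to the
highest-occupancy conformer (first wins a tie); residues are ordered by
residue number with insertion codes kept in file order. When a file holds more
than two polymer chains, the two with the most Cα atoms are taken (overridable).
Parsing is delegated to `gemmi`, so mmCIF input works as well, though PDB is
the supported dialect.

A structure with a hole in its backbone cannot give a reliable linking
estimate, and there is no defensible way to bridge a gap with invented
geometry. Chains with any consecutive-Cα distance strictly greater than 10 Å
are therefore rejected; exactly 10 Å passes. Missing residues are never
interpolated.

## Closure construction

Closing an open chain adds entanglement of its own unless the closure escapes
the complex. The construction treats the dimer's centre of mass (unweighted
mean over all Cα of both chains — the model is Cα-only throughout) as a
repeller:

1. From each terminus t, 25 artificial residues extend along the unit vector
   (t − com), spaced d̄ = 3.8 Å (the typical Cα–Cα distance), giving arm tips
   P and Q.
2. P and Q are joined by a semicircular arc of radius |P−Q|/2 lying in a plane
   through the P–Q axis, sampled with n′ = max(2, round(π·|P−Q|/2 / d̄))
   interior points so the arc spacing stays close to d̄.
3. Twelve closures per chain are generated by rotating the arc plane about the
   P–Q axis in 30° dihedral steps. Meridian 0 lies in the plane containing the
   centre of mass; this phase origin is arbitrary but fixed, making G fully
   deterministic.

All 12 × 12 = 144 closure pairs are evaluated with equal weight. Each raw
Gauss sum is rounded to the nearest integer (a single closure defines a true
integer linking number; the midpoint sum sits within ~10⁻³ of it on shipped
fixtures), and the maximum |raw − integer| residual is surfaced as a quality
metric with a warning above 0.2. An arc that grazes the partner curve within
the singularity guard invalidates only that closure pair: it is excluded from
the average, counted, and reported — closures *can* add spurious linking, and
an outlier average relative to G′ should be treated with suspicion rather than
silently absorbed.

## Cohort statistics

The packaged cohort table (110 non-redundant domain-swapped dimers, 33 of them
human, with published G′, G and chain length N per entry) drives the
statistics:

* **Threshold counts** use strict inequalities (G′ < −1, G′ > 1, G′ < 0), so
  boundary values fall in the middle class. Fractions are reported as integer
  percentages. Because the table stores G′ rounded to two decimals (four
  entries print as exactly 0), fractions recomputed from it can differ from
  values computed on unrounded data by a few percentage points.
* **Distribution width.** The empirical CDF F(x) = #{values ≤ x}/n, evaluated
  at the sorted sample points, is least-squares fitted with
  F(x) = ½[1 + erf((x − m)/Δ)]. The width parameter Δ (reported as
  `erf_width`) relates to the Gaussian standard deviation by σ = Δ/√2; both
  are exposed, and the headline width of the full cohort is Δ ≈ 0.85. A
  Gaussian fit to a 0.25-wide density histogram is also provided; it is
  bin-dependent and treated as qualitative.
* **Length trend.** |G′| against N with a centred 21-point running mean
  (truncated at the edges; a window larger than the table collapses to the
  global mean). The packaged cohort shows no growth of entanglement with chain
  length.

## Dissociation dynamics

Each chain becomes a bead-spring polymer: one bead of diameter σ per Cα,
harmonic bonds (stiffness k, rest length 1.5 σ) between consecutive beads, and
a purely repulsive WCA potential

    U(r) = 4ε[(σ/r)¹² − (σ/r)⁶] + ε   for r < 2^{1/6} σ,  else 0

between every non-bonded pair, inter- and intra-chain. With no attractions the
dimer dissociates, which mimics unfolding at high temperature. Initial
coordinates are the crystallographic (or synthetic) Cα positions, rescaled so
the mean bond length equals 1.5 σ; since the entanglement kernel is
scale-free, G′ at t = 0 equals the static value exactly.

Units are reduced: lengths in σ (= d̄/1.5 ≈ 2.53 Å), energies in ε = k_BT,
time in τ_sim = σ²γ/k_BT. The Langevin equation with unit bead mass and γ = 1
is integrated with the BAOAB splitting (velocity Verlet plus an exact
Ornstein–Uhlenbeck substep), which satisfies fluctuation–dissipation by
construction and keeps the stiff bond modes stable at dt = 0.01 τ_sim
(ω_max·dt ≈ 0.35). An explicitly overdamped first-order scheme was tried
first and rejected: at the step sizes it tolerates (the stiffest chain mode
needs ≈ 4k·dt/γ < 2, with substantial variance inflation well below that
bound) it is an order of magnitude more expensive for the same accuracy.
With m/γ = 1 τ_sim the dynamics is friction-dominated on every timescale of
interest; the free-diffusion mean-square displacement matches 6·(k_BT/γ)·t to
within ~1% at t = 100 τ_sim.

Numerical parameters: k = 300 ε/σ² keeps the rms bond fluctuation near 4 % of
the rest length (recorded configurations stay within 20 %); beads overlapping
below 0.05 σ have the WCA force clamped and counted (never observed in normal
runs); a trajectory whose coordinates become non-finite is dropped from the
ensemble and reported.

G′ is evaluated every `record_every` steps. The ensemble mean over `n_traj`
independent trajectories (seeds seed, seed+1, …) decays exponentially at long
times; `fit_decay` fits G*·exp(−t/τ) by nonlinear least squares after
discarding the first 100 recorded points (the early transient reflects fast
local rearrangement, not global unwinding; configurable). Uncertainties come
from 200 bootstrap resamples over trajectories. A trace indistinguishable from
zero after the transient is rejected as unidentifiable rather than fitted. G*
is the amplitude extrapolated to t = 0 and need not match the static G′: it
measures how much entanglement survives the fast transient.

## Synthetic fixtures

The generator produces geometry with *known* topology, not realistic protein
geometry (no secondary structure, no sterics beyond bond length):

* Hopf links, (1,k) torus links and separated coplanar circles carry exact
  linking numbers (−1, −k, 0 under the generator's orientation conventions),
  verified in the tests against an independent closed-form polygonal linking
  oracle (signed solid angles per segment quadrilateral), which is exact for
  polygons and never shares code with the midpoint kernel.
* `cut_hopf_dimer` removes 20 % of the vertices of each Hopf circle at the
  point farthest from the partner curve (for Hopf circles every point of one
  ring is equidistant from the other, so the cut site is fixed by convention
  at a definite vertex of each ring rather than by a degenerate argmax),
  yielding an open two-chain "dimer" with G′ ≈ −0.86 (radius chosen so bonds
  are 3.8 Å) whose closure average
  recovers G = −1 exactly — the fixture that exercises the whole per-structure
  pipeline end to end.
* `open_coil_pair` gives seeded, bit-reproducible persistent random walks with
  3.8 Å bonds and a mild self-avoidance bias.

Because these fixtures are smooth, loosely packed rings rather than compact
folded proteins, passing tests demonstrate correctness of the estimators and
integrator, not quantitative transfer of simulated timescales to real dimers:
the dissociation of a compact globular dimer is slower and its G′(t) transient
richer than for the ring fixtures.

## Problem sizes in the shipped tests

The test-suite and acceptance-script ensembles are deliberately modest — 80 to
180 beads, 8–20 trajectories, hundreds to a few thousand τ_sim — chosen so
the full decay (τ ≈ 140 τ_sim for the 80-bead ring dimer) is resolved with
comfortable margin while the whole suite stays quick. The 20 % cut width of
the ring dimer is likewise chosen so the fixture is both strongly entangled
(|G′| ≈ 0.86) and able to unthread within a few hundred τ_sim; narrower cuts
leave a reptation-like retraction through the partner ring that takes an
order of magnitude longer. The chain-length trend in the disentanglement time
is asserted on ring dimers of 50 vs 100 vertices (τ ≈ 250 vs ≈ 1000 τ_sim),
where a paired bootstrap orders the two with better than 95 % confidence.

## Known limitations

* The closure exclusion policy (dropping singular closure pairs) is a
  pragmatic choice; alternatives (closure at infinity, convex-hull closures,
  minimally-interfering closure) are out of scope.
* G′ depends on local detail near chain termini; the dynamical G* complements
  it but depends in turn on the chosen dynamics (excluded-volume Langevin
  here; attractive or all-atom dynamics would give different values).
* Simulated τ values are reported in τ_sim and are meaningful as relative
  quantities (e.g. across chain lengths); no attempt is made to map them to
  physical nanoseconds beyond the Stokes estimate in the unit definitions.
* The per-structure reference recomputation requires crystal-structure files
  that are not redistributed with the package.
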