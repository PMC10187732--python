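# Methods

## Model

Chains are bead-spring heteropolymers of N monomers drawn from a two-letter
alphabet: hydrophobic (H) and polar (P). Every bead has diameter
σ = 0.5 nm and mass 100 g/mol; solvent is implicit. Bonded neighbors
interact through a stiff harmonic spring

    U_b(r) = k_b (r − r0)²,    k_b = 2000 kcal/(mol nm²),  r0 = 0.38 nm.

The spring prefactor is absorbed into k_b (no ½). Bonds are stiff enough
that the alternative ½k convention changes single-chain observables by less
than their statistical error; a sensitivity check lives in the test suite's
dimer-histogram oracle, which pins the convention actually implemented.

Nonbonded pairs interact through an Ashbaugh–Hatch scaled Lennard-Jones
potential in which a pair hydropathy λ_ij ∈ [0, ∞) scales only the
attractive branch:

    U(r) = U_LJ(r) + (1 − λ_ij) ε          r ≤ 2^{1/6} σ
         = λ_ij U_LJ(r)                    2^{1/6} σ < r ≤ r_c
         = 0                               r > r_c

with U_LJ = 4ε[(σ/r)¹² − (σ/r)⁶] and ε = 0.2 kcal/mol. At λ = 0 this is
the purely repulsive WCA potential (good solvent); at λ = 1 it is full LJ
(poor solvent), with well depth ε = 0.336 k_BT at 300 K. The cutoff is
r_c = 4σ = 2 nm, unshifted; the truncated tail is below 1e−3 ε. Direct
1–2 bonded pairs are excluded from the nonbonded sum.

Hydropathies: λ_PP = 0 always, λ_HH = λ_H. The cross term defines the two
model variants:

* **HP** — λ_HP = 0: strong, localized attraction between H–H pairs only.
* **HP+** — λ_HP = λ_H/2: weaker attraction distributed over H–P contacts
  as well (the mean of λ_H and λ_P = 0).

## Dynamics

Langevin dynamics in the low-friction limit: friction γ = 0.1 g/(mol fs),
T = 300 K, timestep dt = 10 fs, BAOAB splitting. BAOAB was chosen for its
configurational accuracy at large timesteps with stiff bonds; at γ = 0 it
reduces exactly to velocity Verlet, which the energy-conservation test
exploits. Velocities are initialized from the Maxwell–Boltzmann
distribution. Given a seed, trajectories are bit-reproducible on the same
platform (a single compiled code path, one RNG stream).

Internal units: kcal/mol, nm, fs, g/mol; 1 kcal/mol = 4.184e−6 g nm²/fs².
k_B = 0.0019872041 kcal/(mol K).

Small systems (≤ 200 particles, and all biased two-chain runs) use an
all-pairs force loop; larger systems use a Verlet list built from a linked
cell list (skin 0.4 nm, rebuilt when any particle moves half a skin).
Both paths are cross-checked against a brute-force double-loop oracle to
1e−10 kcal/mol.

By default the first 10% of each single-chain production run is discarded
as equilibration; slab analyses discard the first 50% (slabs relax their
initial packing density over a few hundred thousand steps, see below).

## Sequence design

The composition X_P (fraction of polar monomers) is treated as a controlled
variable: a chain of length N carries exactly round(N·X_P) P monomers
(round-half-to-even for ties), placed uniformly at random per seed. The
study grid is N = 20 with X_P ∈ {0, 0.05, …, 1.0} (21 sequences). A
`patterned` variant places the minority species maximally evenly along the
chain, emulating highly patterned designs.

## Calibration

Each sequence's hydropathy is λ_H = a/(1 − X_P); the scaling factor a is
tuned so the single-chain ⟨R_g⟩ matches the purely hydrophobic reference
(X_P = 0, λ_H = 1). Because ⟨R_g(a)⟩ decreases monotonically with a, a
geometric bracket plus bisection suffices; the search stops when the
relative mismatch drops below 3% (mirroring the match quality of the
original study) or when the residual falls below its own block-averaged
standard error, whichever happens first. Per-evaluation runs default to
4e6 steps (40 ns); the full evaluation trace is returned so monotonicity
can be audited. The naive choice a = 1 (constant mean hydropathy) does
not hold ⟨R_g⟩ constant, which is why the root search exists at all.
Calibration is expected to fail for HP sequences with X_P ≥ 0.9 (one or
two H monomers cannot be made attractive enough); the failure is reported
as a bracketing error, not silently absorbed.

## Observables

* **R_g and shape**: per-frame gyration tensor of the unwrapped chain;
  R_g² is its trace, κ² = 1 − 3(λ1λ2 + λ2λ3 + λ3λ1)/(λ1+λ2+λ3)² from its
  eigenvalues. P(R_g) uses Scott-rule histogram bins.
* **τ_e**: the end-to-end vector ACF (FFT-based) is fitted to a stretched
  exponential exp[−(t/τ₀)^β]; τ_e = (τ₀/β)Γ(1/β) is the integral
  relaxation time.
* **Intrachain scaling ν**: least-squares slope of log √⟨R²(s)⟩ against
  log s for monomer separations s ∈ [3, N−1], excluding bond-scale
  stiffness. For the N = 20 reference chain the local slope is not
  constant over this window: it falls from ≈0.64 at s = 3 to a plateau of
  ≈0.47 at s ≈ 10–13 and rises again near s = N−1 (chain-end effect), so
  the single fitted exponent depends on the window; the default window is
  reported with its fit error, and the per-separation distances are
  available for any other choice.
* **Errors**: five contiguous equal blocks; SE = std(block means)/√5.
  Profile bins additionally take a per-frame-statistics floor, which
  stabilizes the five-block estimate.

## Two-chain interactions

The PMF w(r) along the chain–chain center-of-mass distance is sampled with
harmonic umbrella windows (default 0.4–6.0 nm every 0.2 nm, spring
5 kcal/(mol nm²), U_bias = ½k(d−d₀)²) in an open (non-periodic) box — the
PMF is an infinite-dilution quantity. Window histograms are combined by
self-consistent WHAM (tolerance 1e−8); the 4πr² Jacobian is divided out and
the curve shifted to zero over the outer 10% of the grid. Bins visited
only by the outermost spring tail are discarded before the shift — their
noise would otherwise tilt the whole curve. Per-point uncertainties come
from re-running WHAM on five contiguous sample blocks.

An independent rigid-conformation Mayer estimator cross-checks the
umbrella route: w(r) = −kT ln⟨exp(−ΔU/kT)⟩ over random pairs of
single-chain conformations and orientations at fixed COM distance, with
bootstrap errors and a Kish effective-sample-size diagnostic. The two
estimators agree within error wherever the Mayer weights are well
conditioned (ESS > 100); the rigid approximation deteriorates for deep
wells, which is why it serves as the oracle, not the production method.

B22 = −2π ∫ [e^{−w/kT} − 1] r² dr by trapezoidal quadrature; below the
smallest sampled distance the integrand is treated as a hard core. The
quadrature reproduces the hard-sphere and square-well closed forms to
1e−6 (relative).

## Phase behavior

Direct coexistence: chains packed as a dense z-central slab in an
elongated periodic box. The initial slab is packed at roughly 80% of the
reference dense-phase concentration (self-avoiding growth with a 0.8σ
minimum separation); it compacts to its equilibrium density within a few
hundred thousand steps. Concentration profiles are binned along z after
re-centering each frame on the largest cluster's center of mass (circular
mean, so slab drift and boundary wrapping do not smear the interface).
Mass concentration uses the 100 g/mol bead mass: 1 bead/nm³ = 166 mg/mL.

Coexistence concentrations come from a symmetric tanh fit
c(z) = (c_d+c_l)/2 − (c_d−c_l)/2·tanh((|z|−z₀)/d). A run is classified
**slab** when the fit converges, the dense plateau (2z₀) spans at least a
set number of interface widths, and the largest chain cluster holds ≥ 90%
of chains; **homogeneous** when the profile is flat within 3 SE per bin
(allowing a single moderate outlier among many bins); otherwise
**cluster**. Contradictory indicators set an `indeterminate` flag rather
than raising. The plateau-width rule defaults to 4 interface widths; at
the desk-scale geometry below, slabs are only ~3–6 nm thick against
~0.8 nm interfaces, so desk-scale classifications use 3 widths — at the
full 500-chain geometry the two choices agree.

Chains are clustered by inter-chain monomer contacts within 1.5σ
(minimum image, union–find over the chain contact graph); P(N_c) is the
chain-weighted probability of residing in a cluster of size N_c. The
threshold X_P* is reported as the largest grid composition classified as
a slab, with the grid spacing as its resolution.

## Problem sizes and what desk-scale runs can show

The study-scale campaign — 500 chains in a 10 × 10 × 75 nm box (and
40 nm cubic boxes for self-assembly) for 1 μs (1e8 steps) per state
point — is what the thresholds X_P* ≈ 0.45 (HP) and 0.70 (HP+) refer to;
it is available through `hpc coex` / `hpc scan` and takes hours per point
on one core. The packaged test suite instead runs a scaled-down geometry
(30 chains, 5 × 5 × 20 nm, 0.1–0.2 ns). At that scale:

* bulk coexistence of strongly slab-forming sequences (X_P well below
  X_P*) is robustly reproduced, including dense/dilute partitioning and
  near-complete largest-cluster occupancy;
* the *unscaled* model's loss of phase separation is visible when the
  composition is far above its threshold (λ_H = 1 at X_P = 0.75
  disintegrates within the run);
* precise threshold locations are *not* resolvable: a slab initialized
  just above X_P* is metastable over nanoseconds, so short runs
  overestimate X_P*. The tests therefore check the bracketing and
  ordering structure (slabs below threshold, disintegration far above,
  scaled thresholds far exceeding unscaled ones) rather than the exact
  values 0.45/0.70/0.1.

Single-chain quantities (R_g, κ², ν, calibration) are fully converged at
desk scale; 15–20 million steps give block errors of ~1% on ⟨R_g⟩.

## Known limitations

* The synthetic sequences emulate the statistical design (random placement
  at controlled composition), not any particular published string; results
  at a single random realization carry sequence-to-sequence scatter at
  high X_P where few H monomers remain.
* The Mayer oracle assumes rigid conformations drawn from the single-chain
  ensemble; it is biased where chain–chain contact deforms conformations
  (deep wells, small r).
* No electrostatics, no temperature-dependent hydropathies, no
  hydrodynamic interactions; condensed-phase material properties are out
  of scope.
* Kinetic temperature, not a configurational thermometer, is used for the
  thermostat check; at dt = 10 fs the BAOAB configurational bias on bond
  lengths is ≪ 1%.
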