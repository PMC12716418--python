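# Methods

## Scope and model

`eetscape` models excitation energy transfer (EET) in a chlorophyll network
extracted from a pigment–protein supercomplex. Excitations are assumed to be
localized single-pigment states (pairwise Förster level) or delocalized
within one subunit's pigment cluster (generalized Förster level); carotenoids
are counted in the inventory but excluded from the EET network, since their
transfer to chlorophylls is sub-picosecond and internal to each subunit.
Chlorophyll *c₂*–MGDG adducts are treated as ordinary Chl *c* chromophores
with a spectroscopically silent lipid tail.

## Pigment photophysics

* **Transition dipoles.** The Qy dipole sits on the central Mg and points
  along the N_B→N_D axis of the chlorin macrocycle — the standard geometric
  proxy when quantum-chemical transition densities are not computed. Default
  magnitudes are 4.0 D (Chl *a*) and 3.4 D (Chl *c*), literature-typical
  effective values; both are config-overridable, and all recovery-based
  checks in the test suite are ratio-based, so these absolute values are
  exposed choices rather than hidden calibrations.
* **Site energies.** Fixed per species: 663.5 nm (15 071.6 cm⁻¹) for Chl *a*
  and 633.5 nm (15 785.3 cm⁻¹) for Chl *c*, with optional per-pigment
  overrides (E = 10⁷/λ). Per-conformer quantum-chemical site energies are out
  of scope.
* **Lineshapes.** Area-normalized Gaussians in wavenumber, FWHM 250 cm⁻¹,
  Stokes shift 100 cm⁻¹ (emission red-shifted). These unstated-by-any-
  measurement defaults were chosen once to give room-temperature-like
  donor–acceptor overlaps; they are plain config parameters. The public
  `spectral_overlap` evaluates J = ∫F_D A_A dν by quadrature on a ±6σ grid;
  the rate engines use the equivalent closed-form Gaussian–Gaussian kernel so
  that cluster-level rates reduce *exactly* to pairwise rates for
  single-pigment clusters. The two agree to ~10⁻⁸ relative and are
  cross-checked in the tests.

## Rates

* **Coupling.** Ideal point dipole, V = f·5034·κ·μ₁μ₂/R³ cm⁻¹ (μ in Debye,
  R in Å, screening factor f, default 1.0); κ = d̂₁·d̂₂ − 3(d̂₁·R̂)(d̂₂·R̂).
  An extended-dipole scheme (±q monopoles along the Qy axis, default
  separation 8.7 Å) is available for close pairs. The 5034 constant and the
  1.18 ps⁻¹ rate prefactor ((2π)²c for V in cm⁻¹, J in cm) are verified
  against independent SI-unit evaluations in the test suite. Centers closer
  than 2 Å are rejected (dipole picture invalid).
* **Pair enumeration.** All chlorophyll pairs within 40 Å Mg–Mg (KD-tree);
  beyond that, point-dipole rates are far slower than the 20–25 ps display
  cutoffs. Both directions are stored, each with its own donor-emission /
  acceptor-absorption overlap, so downhill Chl *c*→Chl *a* transfer is faster
  than its uphill reverse.
* **Rate-map classes.** Time-constant intervals are half-open (a, b]:
  τ = 20 ps falls in the 10–20 ps class; τ > 20 ps is dropped from the map but
  retained in the network. Cluster-level display/routing uses a 25 ps cutoff,
  again retaining the full table for kinetics.
* **Generalized Förster.** Each subunit's chlorophylls form one exciton
  cluster (site energies on the diagonal, intra-subunit couplings off it).
  Donor thermal equilibration is assumed instantaneous: state weights are
  Boltzmann factors at T = 295 K (energies shifted by the minimum before
  exponentiation, which is exact). Exciton-state lineshapes reuse the site
  Gaussian width — no exchange narrowing, kept deliberately simple and
  configurable. The core's chlorophylls are pooled into a single acceptor
  supercluster by default (per-subunit splitting is available), matching how
  antenna→core transfer is usually reported; a single-chlorophyll linker
  subunit forms its own one-pigment cluster.

## Kinetics and routes

The cluster table defines a master equation dp/dt = K p (K[j,i] = k(i→j),
diagonal = −outflow) built from the *full* table including back-transfer,
plus an irreversible trap fed from the core at 1 ps⁻¹ by default — charge
separation is much faster than antenna transfer, so results are insensitive
to this value once it is fast. Eigen-decomposition yields lifetimes and
amplitudes; a near-defective K falls back to numerical propagation with a
warning. Mean first-passage times (MFPT) come from the standard linear
system over trap-reaching transient states.

A "route" is the directed path minimizing the sum of step time constants,
searched over edges with τ ≤ 25 ps (Dijkstra, lexicographic tie-break for
determinism). Whether a published "route average" means this path-sum or an
MFPT is genuinely ambiguous, and the two differ on reversible networks —
layer averages therefore always co-report both. On irreversible chains they
coincide (tested).

## Global DAS fitting

The delay × wavelength signal is modelled as Σ_k DAS_k(λ)·c_k(t) with
c_k = exponential ⊗ Gaussian IRF, evaluated analytically via the scaled
complementary error function (a separate exp·erfc branch handles late times,
where erfcx overflows). Lifetimes are shared across wavelengths and fitted in
log-space (they span four decades); amplitudes are profiled out linearly at
every iteration (variable projection). The IRF width and time zero are fixed
to the recorded instrument values by default and can float. Lifetimes within
a ratio of 1.2 trigger a degeneracy warning. Nonuniform (log-spaced) delay
grids are handled natively — kernels are analytic, nothing is resampled.
Parallel (DAS) parameterization only; sequential/target analysis is out of
scope.

## Synthetic study conditions

* **Layered antenna lattice.** Concentric layers (default 6) of subunits on
  radial fibers around a chlorophyll ring at the core radius (20 Å); layer
  spacing 25 Å, intra-subunit pigment spacing 10 Å, 4 pigments per subunit
  with a 25% Chl *c* fraction, dipoles along z with optional orientation
  noise. The geometry deliberately makes inter-fiber gaps (tens of Å of arc)
  much larger than inter-layer gaps along a fiber, reproducing the
  fiber-following route topology of layered antenna supercomplexes. It is
  *not* an atomistic mimic: protein scaffolds, realistic dipole orientations,
  and per-site energy disorder are absent, so absolute route constants test
  the machinery, not any particular organism.
* **Inventory fixture.** 48 subunits (12 core, 35 antenna, 1 linker) whose
  census enforces the published statistics it encodes: antenna totals of
  291 Chl *a*, 121 Chl *c* (9 as Chl *c₂*–MGDG on non-Lhcq/Lhcf subunits,
  putting 112/121 = 92.6% of Chl *c* in Lhcq/Lhcf subunits at 4–7 each) and
  224 carotenoids, with 96 further Chl *a* in the core + linker. Per-subunit
  counts within those constraints are a fixed, documented choice; coordinates
  are placeholder grids, so the fixture supports inventory statistics only.
* **TA cubes.** Four components at 0.16 / 2.8 / 62 / 5000 ps with
  sum-of-Gaussian spectra mirroring the qualitative signatures of
  antenna-to-core energy flow (sub-ps feeding, an opposite-sign transfer
  component, a dominant decay, a blue-shifted long-lived tail), 70-fs IRF,
  additive Gaussian noise at 1% of peak signal; 64 wavelengths (660–710 nm)
  and 120 delays (linear to 1 ps, log-spaced to 3 ns — spanning all four
  lifetimes within a realistic delay-stage window). Zero-noise cubes equal
  the analytic model bit-for-bit.

Because the generators are seeded pure functions, every number in the tests
and in `scripts/acceptance.py` is recomputed from scratch at run time.

## Numerical choices and degenerate inputs

Wavenumber (cm⁻¹) is the only internal energy unit; nm appears at I/O
boundaries. Symmetry of Hamiltonians is enforced to 10⁻⁹ cm⁻¹. Eigenvector
sign (gauge) freedom cannot affect rates (tested). Models with no antenna
subunits report averages as unavailable rather than zero; unreachable traps
give infinite MFPT; sources without an admissible route are excluded from
layer means with a warning, never silently.

## Known limitations

Quantum-chemical couplings (transition densities / TrEsp), Redfield-type
dynamics, vibronic lineshapes, spectral densities, carotenoid→Chl transfer,
chirp correction, and target analysis are all out of scope. Dipole-proxy
couplings with fixed species site energies reproduce rate *structure*
(orderings, route topology, class maps) faithfully but can deviate from
quantum-chemically parameterized rates by factors of a few for individual
close pairs; conclusions drawn from absolute per-pair time constants on real
structures should be checked against the configurable screening, dipole
strengths, and lineshape parameters.
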