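# Methods

`aceff` builds linear force fields for molecules in vacuum from the atomic
cluster expansion (ACE): a body-ordered, permutation- and O(3)-invariant
polynomial basis of atomic environments, fitted to total energies and
per-atom forces by regularized linear least squares, and evaluated with a
battery of property tests that go beyond mean errors.

## The model

The total energy is a sum of site energies,

    E(X) = Σ_i E_i,
    E_i  = E0(z_i) + Σ_B c_{z_i,B} B(env_i) + Σ_{p,n} c2_{p,n} Rp_n(r_ij),

where `env_i` is the set of displacement vectors r_ij to neighbors within
the outer cutoff r_out, `B` runs over the invariant basis, `E0` are
element-wise one-body energies, and the last term is a small auxiliary
two-body basis carrying short-range repulsion.  Everything is linear in the
coefficients, so fitting is a linear least-squares problem regardless of
body order.

**Construction of the invariant basis.**  Per element channel z, the
neighbor density of atom i is projected onto one-particle functions
φ_{znlm}(r) = R_n(|r|) Y_lm(r̂), giving the atomic base
A_{znlm} = Σ_{j: z_j=z} φ_{znlm}(r_ij) — one sum over neighbors.  Products
of ν entries of A are (ν+1)-body correlations; because the sum over
neighbors is done *before* the product ("density trick"), the cost per
basis function is O(1) in body order and linear in the neighbor count.  The
products are not rotation invariant; contracting their m indices with the
joint null space of the three total rotation generators (and keeping only
even total l, which is the exact parity condition for invariance under
improper rotations) yields the invariant B-functions.  Generator matrices
in the real-harmonic basis are obtained to machine precision by applying
the tangential differential operator −(e_a × u)·∇ to the analytic
harmonics and solving an interpolation system; no quadrature error enters.
Coefficient tensors are symmetrized over permutations of identical factor
slots (the A factors commute), orthonormalized, and sparsified at 1e−12.
Remaining linear dependencies among the B-functions are removed by a
pivoted (rank-revealing) QR factorization of their evaluation matrix on at
least 3× as many random environments as candidates, drawn with a fixed
seed (default 2021); seed and tolerance (1e−10 relative) are recorded in
the basis provenance so the basis identity is bit-reproducible.

**Truncation.**  Three parameters control the basis: the cutoff radius
r_out, the maximum correlation order ν^max, and per-order caps D_ν^max on
the modified polynomial degree D = Σ_t n_t + w_Y·l_t with w_Y = 2.
Defaults: ν^max = 4 for up to three distinct elements, 3 for four or more;
D_ν^max = {12, 10, 8, 8} for ν = 1..4.  l_max and n_max are implied by the
caps, not set independently.  These caps are deliberately modest — the
basis grows with an exponent ν in the degree budget — and are the main
accuracy/cost dial a user should turn.

**Radial machinery.**  R_n(r) = p_n(x(r)) f_cut(r) / N_n with

* transform x(r) = ((1 + r0)/(1 + r))^p, defaults p = 2, r0 = 2.5 Å:
  strictly monotone, finite at r = 0, steepest at short range so that close
  neighbors are resolved most finely;
* two-sided envelope f_cut = [(r − r_in)(r_out − r)]² (normalized to peak
  1), zero with zero slope at both cutoffs.  The inner cutoff r_in excludes
  the region where thermal data sets contain little or no data and where
  unconstrained high-degree polynomials would oscillate; its default is the
  minimum training-set pair distance minus 0.05 Å, clamped to ≥ 0.5 Å.
  Default r_out = 5.0 Å.
* polynomials seeded with p_0 = 1, p_1(x) = x and continued by twice-iterated
  Gram–Schmidt of x·p_{n−1} under the measure f_cut(r(x))² dx on the
  transform interval, evaluated with a 2000-point Gauss–Legendre rule and
  the analytic inverse r(x).  The normalization constants N_n make the
  *radial functions* (not the bare polynomials) an orthonormal set.  The
  constant p_0 is not a member of the radial basis; orthogonality is
  enforced among n ≥ 1 only, which is what lets p_1 = x hold exactly
  alongside an identity Gram matrix.  Polynomials are stored as Legendre
  series on the interval (stable to degree ≳ 10, where a bare three-term
  monomial recursion starts losing digits).
* the auxiliary pair basis repeats the construction with the one-sided
  envelope ((r_out − r)/r_out)², which is nonzero as r → 0 so the pair
  channel can carry short-range repulsion; default 6 functions per
  unordered element pair, fitted jointly with everything else in one
  linear system.  The pair basis shares r_out with the multibody basis
  (configurable).

**Radial basis is element-pair independent**: R does not depend on the
species at either end; species enter only through the density channels.

## Fitting

Observations are one energy row per configuration (weight w^E, units 1/eV)
and 3N force rows (weight w^F, units Å/eV), so residuals are
dimensionless.  Defaults w^E = w^F = 1 with per-configuration overrides.
The smoothness prior is diagonal, Γ_vv = Σ_t (n_t^p + w_Y l_t^p) (pair
entries n^p), a rough magnitude estimate of the p-th derivative of the
basis function; default p = 2 penalizes curvature, which is what matters
for extrapolation.  Two solvers:

* `lsqr_tychonov`: iterative LSQR on the augmented system [Ψ; λΓ],
  minimizing ‖Ψc − t‖² + λ²‖Γc‖²; fixed tolerances (atol = btol = 1e−14)
  and iteration cap (20·ncols + 2000) recorded in diagnostics;
* `rrqr`: column-pivoted QR of the preconditioned matrix ΨΓ⁻¹, truncating
  diagonal entries below λ, mapped back through Γ⁻¹.

The automatic default is RRQR when rows ≥ 1.2 × columns and LSQR+Tychonov
otherwise; RRQR gives the better-behaved solutions when the system is
comfortably overdetermined.

**One-body strategies.**  `isolated_atom` (supply per-element energies;
gives the correct dissociation limit and is the recommended choice),
`training_average` (mean per-atom training energy assigned to every
element; the fitted model then has zero-mean energy, which can lower test
errors on narrow thermal data but degrades extrapolation), and
`forces_only_shift` (fit to forces only, then add the single constant that
zeroes the mean signed training energy error).

**Identifiability.**  Total energies and forces cannot distinguish every
coefficient: for example, the ν = 1, l = 0 feature of a configuration with
center element z and neighbor channel z′ is the symmetric pair sum
Σ_{i∈z, j∈z′} R_n(r_ij), identical to the (z′, z) feature, so cross-element
ν = 1 coefficients are only determined up to that exchange.  Site energies
are not separately observable, and this is a property of the model class,
not a defect of the solver: predictions are unaffected, and the
regularized solvers return the minimum-norm representative.  Exact
coefficient-recovery studies therefore use a single-element basis, where
the configuration feature map is injective (verified: effective rank
equals the parameter count).

## Evaluation battery

* **Error metrics**: energy MAE/RMSE per atom (meV) and force-component
  MAE/RMSE (meV/Å), the conventions of the field's benchmark tables.
* **Relaxation**: BFGS on the analytic forces to a max-force tolerance
  (restarted up to three times), deterministic from a fixed start.
* **Normal modes**: central finite differences of the analytic forces with
  step h = 0.001 Å, symmetrized, mass-weighted with standard atomic
  masses, with rigid translations/rotations projected out before
  diagonalization.  Frequencies in cm⁻¹ via the conversion constant
  derived in `constants.py` from CODATA values; negative values flag
  imaginary frequencies.  h = 0.001 keeps the finite-difference truncation
  error near 0.005 cm⁻¹ (orientation-independent to ~0.01 cm⁻¹); forces
  are analytic, so the small step costs no precision.
* **Dihedral scans**: at each grid angle the rotating side of the molecule
  (connected component across the central bond, found from a
  covalent-radius bond graph) is rigidly turned to the target, then the
  geometry is relaxed under an equality constraint on the signed IUPAC
  dihedral (SLSQP; constraint held to 0.1°, points that miss it are
  flagged but the scan continues).  Energies are reported relative to the
  scan minimum.  The grid domain is the closed interval [−180°, 180°] so
  both periodic endpoints can be scanned.
* **Bond scans** are rigid: one atom slides along the bond direction, all
  other coordinates frozen — the bond-breaking extrapolation probe.
* **Langevin MD**: BAOAB splitting, bit-reproducible for a fixed seed,
  friction default 0.01 fs⁻¹, Maxwell–Boltzmann initial velocities with
  net momentum removed.  At zero friction and temperature the scheme
  reduces to velocity Verlet.  Per-step monitoring terminates and flags a
  run that hits a *hole* in the PES — the potential energy dropping more
  than a configurable offset (default 10 eV) below the starting value, any
  pair distance inside the model's inner cutoff, or a non-finite
  energy/force.  The offset is a package choice: holes manifest as
  collapse far below thermally reachable energies, so the exact floor is
  not critical, but it is explicit and configurable.  The sampling
  protocol helper (equilibrate, then samples at a fixed stride — defaults
  500 steps, 10 samples 200 steps apart) reproduces the standard
  temperature-extrapolation test harness.

## Synthetic data

The generator produces what the fits assume: thermally spread molecular
geometries with energy and force labels that are exact gradients of a
known analytic reference.

* **Fixtures**: an O–H diatomic, a bent water-like triatomic, a
  benzene-like C6H6 ring, and a 15-atom flexible ether chain with four
  named rotatable backbone dihedrals (the torsionally complex,
  druglike-molecule regime).
* **References**: Morse bonds + harmonic angles + cosine torsions (generic
  organic parameters: D_e = 4 eV, a = 2 Å⁻¹, k_θ = 3 eV rad⁻², threefold
  0.15 eV torsions minimized at the template geometry); plain harmonic
  bonds/tethers for closed-form normal-mode and statistical-mechanics
  checks; and *planted* linear ACE models with seeded random coefficients
  (scaled down by total degree so the planted surface is smooth) for exact
  recovery studies.
* **Sampling**: `gaussian_displace` (i.i.d. Cartesian perturbations at a
  stated standard deviation, rejecting draws with pair distances under
  0.6 Å — the near-equilibrium thermal regime, default σ = 0.05 Å ≈ a
  300–500 K vibrational amplitude) and `md_sample` (seeded Langevin MD on
  the reference, subsampled at a fixed stride — the barrier-crossing
  regime), plus a stratified multi-temperature wrapper (default 300/600/
  1200 K, equal counts per temperature).  Every dataset records generator,
  scale and seed in the per-frame metadata, and stored forces re-evaluate
  bitwise against stored positions.

What passing on these data shows: the basis, gradients, fitting and
evaluation machinery are correct to the stated tolerances.  What it does
not show: accuracy against electronic-structure labels — the references
have no charge transfer, no long-range electrostatics, no reactivity, and
far smoother anharmonicity than a real Born–Oppenheimer surface.

## Numerical choices and study sizes

All tolerances that define the artifact's behavior are fixed constants:
coupling sparsification 1e−12, null-space threshold 1e−8 (relative),
dependency pruning 1e−10 (relative) with seed 2021, LSQR atol/btol 1e−14.
The verification studies run at desk scale on one CPU: the three-element
ν^max = 4 invariance audit uses degree caps {8, 7, 7, 8} (806 basis
functions, total angular momentum up to 2 at ν = 4), the density-trick
oracle enumerates every ordered neighbor tuple for all products up to
ν = 4 at caps {4, 4, 4, 5}, planted-coefficient recovery uses 300 random
single-element clusters, and the equipartition check averages 40 000 BAOAB
steps of a harmonic trimer.  These sizes are the package's verification
conditions, chosen to exercise every code path with nontrivial angular
coupling while the full suite stays in the minutes range.

## Known limitations

Free boundary conditions only (no periodic images, no cell lists — the
O(N²) neighbor scan targets molecules); no virials/stress; no long-range
electrostatics or charge transfer; no basis sparsification beyond rank
pruning; dihedral constraints handle one dihedral per scan point; the
model archive stores coupling coefficients densely per function, which is
fine at desk scale but would want a binary container for bases beyond
~10⁴ functions.
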