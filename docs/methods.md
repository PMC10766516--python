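# Methods

This note documents the model, the numerical choices, and what the
synthetic-data machinery does and does not establish.

## Energy model

The density-functional term has the nonseparable meta-NGA form: a 40-term
joint polynomial in three bounded working variables multiplying the
spin-resolved LSDA exchange energy density, plus 9-term series in the
kinetic-energy working variable multiplying the LSDA correlation energy
density and the PBE gradient correction, plus a percentage X of supplied
single-determinant exchange.  Conventions:

- **Exchange energy density.**
  ε_xσ^LSDA = −(3/2)(3/4π)^{1/3} ρ_σ^{1/3} (per electron, spin-resolved), so
  ρ_σ ε_xσ integrates to the spin-scaled Dirac/Slater exchange energy.  The
  descriptor machinery reproduces the closed-form value for a uniform
  closed-shell fixture to 1e-10 (tested).
- **Correlation.**  ε_C^LSDA defaults to the Perdew–Wang 1992
  parameterization; VWN5 is selectable through
  `IngredientFunctions(correlation="vwn5")`.  The parent functional family
  does not restate which parameterization it inherits, so the choice is
  isolated behind one configuration switch.
- **Gradient correction.**  H^PBE uses β = 0.066725 and γ = (1 − ln 2)/π²,
  both exposed in configuration.  Its spin factor φ(ζ) and screening
  variable t are built from the total density.  The total gradient norm is
  taken as |∇ρ_α| + |∇ρ_β|, exact whenever the two spin gradients are
  parallel — in particular for all closed-shell species; for the synthetic
  open-shell species it is an upper bound.  This convention is forced by the
  feature set (per-spin gradient *norms*, not vectors).
- **Working variables.**
  u(s) = γ_x s²/(1 + γ_x s²) and v(ρ) = ω_x ρ^{1/3}/(1 + ω_x ρ^{1/3}).  The
  constants γ_x = 0.004 and ω_x = 2.5 are transcribed family values stored
  in `data/ingredient_constants.json`, not hard-coded defaults.
  w = (τ^unif − τ)/(τ^unif + τ) with τ_σ^unif = (3/10)(6π²)^{2/3} ρ_σ^{5/3}
  per spin channel (used in the exchange-like polynomial) and
  τ^unif = (3/10)(3π²)^{2/3} ρ^{5/3} for the total density (used in both
  correlation series, as the w(ρ, τ) notation of the form suggests).  For
  closed shells the two definitions coincide identically (tested).
- **Kinetic-energy density.**  τ_σ = ½ Σ_i |∇ψ_iσ|², the Minnesota-family
  convention; the ½ is the module constant `TAU_CONVENTION_FACTOR` so the
  no-½ convention can be selected.
- **Units.**  Atomic units internally; geometries are read in Å
  (1 Å = 1.8897259886 bohr); statistics in kcal/mol
  (627.509 kcal/mol per hartree).
- **Density floor.**  Points with ρ_σ < 1e-30 take the ρ → 0 limits
  (s = u = v = w = 0) to avoid division blow-ups.

Given the descriptor integrals, the energy is exactly linear in the 59
parameters (machine-precision assertion in the tests).  The coefficient-file
layout is fixed by the lexicographic (i, j, k) order of
`enumerate_a_indices`; any externally published coefficient table must be
permuted onto this order once.

## Quadrature

Atomic grids are a Gauss–Chebyshev (second kind) radial rule mapped to the
half line by r = R(1+x)/(1−x), times a spherical product angular rule
(Gauss–Legendre in cos θ × uniform in φ).  Multi-centre grids use the Becke
partition of unity with the cubic switching polynomial iterated three times;
the per-point atomic weights sum to one by construction.  The supported
angular sizes are the 2m² product rules plus 590 (realised as a 10 × 59
product) so the conventional (99, 590) preset exists by name; on that preset
electron counts of two-centre Gaussian fixtures are reproduced to better
than 1e-5 relative, and grid refinement reduces the quadrature error
monotonically on Gaussian fixtures.  Production-code pruned grids are out of
scope: only quadrature accuracy matters here, not cost.

## Dispersion

Zero-damped C6-only pair sum; the ½ prefactor of the ordered-pair sum is
implemented as a plain sum over unordered pairs (asserted equal to the
half-ordered sum against a brute-force double loop).  Distances convert
Å → bohr inside the r⁻⁶ kernel so C6 in hartree·bohr⁶ yields hartree; the
damping function runs on the Å scale of the R0 tables.  Pairs beyond 50 Å
are skipped (contribution < 1e-15 of typical terms; configurable).

Coordination numbers use the standard smooth counting function with
k1 = 16, k2 = 4/3 over covalent radii; pair C6 coefficients come from a
provider interface: a fixed-pair table (fixtures/tests) or Gaussian-weighted
interpolation (k3 = 4) over reference (CN, C6) points.  The shipped
`data/synthetic_d3_fixture.dat` covers H, C, N, O, Si, Ar with **synthetic**
coefficients of physically plausible magnitude generated by a smooth
combining rule; it is *not* the published D3 reference data, and no D3
reference implementation was available to validate against.  Every
dispersion test that needs numbers therefore tests structure (symmetry,
interpolation exactness at reference points, invariances, the damping
arithmetic), not literature values.  Dimer curves report the inter-fragment
interaction E(dimer) − E(A) − E(B), which decays to zero at large
separation.

Known physical limitations, inherited from the model class: no r⁻⁸ term, no
three-body term, no charge dependence of C6.

## Training

- **Loss.**  L = Σ_n R_n/I_n + λ(a+b+c) over training-role sets only, R_n
  the per-set RMSE in kcal/mol.  The regulariser couples coefficients
  adjacent in k within each (i, j) family of the a-block and adjacent
  indices of the b/c blocks.
- **Optimizer.**  The fit is a closed-form weighted ridge solve (each set's
  rows scaled by 1/√(I_n N_n), the regulariser as √λ·D rows, columns
  equilibrated) followed by an L-BFGS-B polish of the exact loss with
  analytic gradient (RMSE smoothed as √(MSE + 1e-30)) and seeded
  multi-start.  This is an algorithmic substitution for the original
  generalized-reduced-gradient choice with the same optimum contract: the
  returned parameters never have higher loss than the supplied initial
  point, and the result is deterministic given the configuration seed.
- **Range-parameter scan.**  s_r6 is scanned over [1.2, 2.1] at step 0.1,
  then the interval is halved around the incumbent until it falls below
  0.004 (so the selection resolution is well inside the 0.01 recovery
  tolerance).  The selection criterion is the pooled training MUE, not the
  loss; exact ties break toward smaller s_r6; the result never leaves the
  bounds.
- **Promotion rule.**  A validation set is promoted iff
  MUE > (1 + trigger) × panel, strictly, with trigger = 0.30; promoted sets
  receive the panel statistic as their inverse weight.  The two literature
  statistics involved (the top-five panel average that triggers promotion,
  and the 200-functional average that sets the new inverse weight) are
  collapsed into the single manifest field `reference_mue_mean`: both are
  externally supplied per-set scalars, and recomputing a 200-functional
  panel is out of scope.
- **Convergence.**  The loop stops when no promotion occurs and, if a
  density-refresh hook is installed, the pooled training MUE changed by
  less than 1e-3 kcal/mol between iterations; without a hook the fit is a
  deterministic fixed point, so "no promotion" already implies convergence
  and the loop terminates after a single iteration on a converged database.
  Iteration cap 50 (error carrying the last state).
- **Density refresh.**  The point where a self-consistent engine would
  recompute densities with the current trial functional is a caller-supplied
  hook; the default no-op is exactly correct for the analytic Gaussian
  fixtures, whose densities do not depend on the functional.

## Benchmark statistics

MUE/MAD, RMSE and MoM (the unweighted mean of per-set MADs) follow the
standard definitions.  WTMAD-2 weights each set by N_i × (overall mean
|ΔE| / set mean |ΔE|); WTMAD-1 weights each set by N_i and a magnitude-bin
weight; both are normalised by ΣN_i.  The literature constants of the
GMTKN55 scheme — overall mean |ΔE| = 56.84 kcal/mol and bins
[0, 7.5) → 10, [7.5, 75) → 1, [75, ∞) → 0.1 — are shipped as the `gmtkn55`
preset in `data/wtmad_presets.json`; the code implements only the algebra.

## Synthetic data: what it shows and what it does not

Species are sets of independently occupied, normalised s-Gaussian orbitals
(1–3 shells, exponents log-uniform on [0.08, 12] bohr⁻², mixed closed- and
open-shell occupations up to 2 e/spin, centres within ±1 Å), so all six
ingredient arrays are analytic and electron counts are exact by
construction.  Single-determinant exchange energies are drawn uniformly from
[−8, −0.2] hartree.  Reference values are planted-model predictions through
the *same* prediction path the trainer uses, plus i.i.d. Gaussian noise in
kcal/mol (heavier-tailed noise deferred); "hard" validation sets add a
systematic bias that the reference panel, emulating well-performing
published functionals, does not share, which is why their panel statistic is
computed from the noise alone.  Panel statistics are the planted-model MUE
× a configurable factor, floored at 0.1 kcal/mol so noiseless scenarios
remain decidable.  The default pool of 90 species gives a full-rank
58-column descriptor matrix (condition number ≈ 5 × 10⁶ after column
scaling, reported by the generator).

Passing planted-recovery tests therefore establishes the correctness of the
descriptor algebra, the linear-model plumbing, the optimizer and the loop
logic.  It does **not** establish chemical accuracy: real densities are not
sums of s-Gaussians, real reference values are not generated by any
functional of this form, real inverse weights encode curator judgement, and
the promotion dynamics on real data depend on genuine physics the synthetic
bias only caricatures.

Problem sizes throughout (90-species pools, 4–8 sets of 20–640 reactions,
25-point dimer scans, radial 40 × angular 50 fixture grids) are the
package's desk-scale defaults: large enough for full-rank recovery and
stable statistics, small enough that the full suite runs in seconds.

## Degenerate inputs and tie-breaks

Zero-density points return limit values; a dispersion-free database makes
the s_r6 objective flat and the scan returns the lower bound by the tie
rule; promotion uses strict inequality at the threshold; set ordering
everywhere follows the manifest, making logs deterministic.
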