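# Methods

This note records the models, algorithms, numerical choices and known
limitations of `erloc`.  Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`.

## Objective functions

Edmiston–Ruedenberg (ER) localization maximizes the orbital self-repulsion
energy `E = Σ_p (pp|pp)` over orthogonal rotations of one orbital set
(occupied or virtual); the solver minimizes `f = −E`.  Because the sums
`Σ_{pq} (pp|qq)` and `Σ_{pq} (pq|pq)` are rotation invariants, maximizing
self-repulsion is the same as minimizing the interorbital Coulomb or
exchange sums; the invariance of (self + interorbital Coulomb) and
(self + interorbital exchange) is asserted to 1e-9 in the tests.

Foster–Boys (FB) localization minimizes the summed second-moment variances
`f = Σ_p (⟨p|r²|p⟩ − |⟨p|r|p⟩|²)`.  Writing the variance sum as
`Tr Q − Σ_u Σ_p (U^u_pp)²`, with `Q` the (rotation-invariant) second-moment
trace and `U^u` the MO dipole matrices, shows FB has exactly the ER
functional form with the three dipole matrices in place of the Cholesky
vectors.  One gradient/Hessian engine (`ERState`) therefore serves both
objectives; FB carries the constant offset `Tr Q`.

## Rotations, gradient, Hessian

Rotations are parametrized `C → C·exp(κ)`, `κ = −κᵀ`, with unique
parameters `κ_pq`, `p > q`, in row-major lower-triangle order.  At `κ = 0`:

* gradient of `f = −E`:  `g_pq = 4[(pq|pp) − (pq|qq)]`;
* Hessian diagonal:  `H_pq,pq = 4[(pp|pp)+(qq|qq)−2(pp|qq)] − 16(pq|pq)`;
* Hessian transform `H·κ` from the once-per-macroiteration intermediates
  (below) plus the commutator term `+½[κ, A]` (with `A` the gradient matrix
  of `E`), which is the chart-curvature correction of the exponential
  parametrization.  With it the Hessian is the true second derivative of
  `f(exp(κ))` and an exactly symmetric bilinear form; without it one gets
  the directional derivative of the rotated-orbital gradient instead.  The
  finite-difference identities for both objects are asserted in the tests
  (gradients to 1e-6, Hessian products to 1e-5, diagonal vs unit-κ products
  to 1e-10).

All derivative formulas were re-derived from `E(κ) = Σ_p (pp|pp)[C exp(κ)]`
and locked to central-difference oracles; the exact-ERI quartic-transform
path (`exact_er_oracle`) provides the independent reference for every
Cholesky-based quantity.

## Cholesky decomposition of the ERIs

The ERI matrix over packed AO pairs `(αβ), α ≥ β` is positive semidefinite;
a greedy pivoted incomplete Cholesky factorization (largest residual
diagonal pivot, ties to the lowest pair index, stop at `D_max ≤ τ`)
guarantees every reconstructed element is within τ (Cauchy–Schwarz on the
residual Gram matrix).  No span/batch pre-screening is used: correctness
first, adequate at desk scale.  The packed AO factor is unpacked to full
symmetric matrices and half-transformed twice (`L_mo = Cᵀ L C`) per
macroiteration — never through a 4-index intermediate.  Defaults follow
standard practice for integral fidelity: `τ = 1e-8` au for tight work;
`τ = 1e-4` or `1e-2` barely changes occupied localities while shrinking
`N_J` severalfold (the vector-count monotonicity in τ is tested).

From `L_mo` the per-macroiteration intermediates are
`d[J]_p = L_mo[J]_pp`, `R_ab = Σ_J L[J]_ab d[J]_b`,
`Y_atb = Σ_J L[J]_at d[J]_b`, `Z_atb = Σ_J L[J]_ab L[J]_tb` and
`W_pq = Σ_J (L[J]_pq)²`; microiterations then cost O(n³) independent of
`N_J`.

## Trust-region solver

Each macroiteration: rebuild the state, stop if the max-abs gradient
element is ≤ `conv_tol` (default 1e-6 au, the same metric used for SCF),
else solve the step equations at trust radius `h`:

1. Newton attempt by Jacobi-preconditioned conjugate gradients with
   negative-curvature detection; accepted (μ = 0) only if the model stays
   convex along the Krylov path and the step stays inside `h`.
2. Otherwise the lowest eigenpair of the α-scaled augmented Hessian
   `[[0, αgᵀ],[αg, H]]` by Davidson microiterations, preconditioned with
   `(diag H − μ)`; the reduced basis is shared across α values (only one
   small dense diagonalization per α), and α is bracketed/bisected until
   `|κ| ∈ [0.9h, 1.1h]`.  By Hylleraas–Undheim–MacDonald the converged μ
   lies below the lowest Hessian eigenvalue, so `(H − μ)` is positive
   definite; the bound is verified against dense Hessian spectra in tests.
   Residual stop: `‖r‖ ≤ micro_rel_tol · ‖g‖` (default 1e-3); subspace
   capped at 30 with collapse-to-best restart.

An integer line search applies `exp(nκ)` while `f` strictly decreases
(cap 16); `n = 0` rejects the step and halves `h` without rebuilding the
state (the state depends only on C, which did not change).  The radius
update uses the actual/model reduction ratio with thresholds 0.25/0.75 and
factors 0.7×/1.2× — ordinary restricted-step constants — with `h` clamped
to `[1e-4, 10]` and `h₀ = 0.5`; the cap is a fixed conservative choice in
place of a norm-dependent formula.

**Minimum verification.**  A gradient-stationary point is accepted only
after a Davidson computation of the lowest Hessian eigenvalue.  Symmetric
molecules make this necessary: from a symmetry-adapted start the gradient
along symmetry-breaking rotations vanishes identically, and the iteration
would otherwise terminate on a saddle (water's σ-structured lone pairs are
the canonical example — the true ER maximum has symmetry-broken "rabbit
ear" lone pairs).  If the lowest eigenvalue is below `−1e-7·|diag H|_max`
the solver steps along that eigenvector (both signs tried, line-search
arbitrated, at most 12 such escapes) and resumes.  This is the g → 0 limit
of the augmented-Hessian mechanism, in which the bordered eigenvector loses
its head component and degenerates into the Hessian eigenproblem.

With this check, occupied ER energies from canonical *and* Foster–Boys
starts agree with an independent 2×2 Jacobi-sweep maximizer (fine-scan +
bounded refinement per pair, swept to 1e-10) to ~1e-9 hartree-equivalents
on the water/ammonia/ethane fixtures at τ = 1e-8 (≤ 1e-7 asserted);
convergence tails are near-quadratic and f decreases monotonically across
accepted macroiterations.

## Initial guesses

* *Cholesky orbitals*: pivoted Cholesky factorization of the one-particle
  density `D = C Cᵀ` followed by symmetric (Löwdin) S-orthonormalization —
  non-iterative, local by construction, span-preserving (projector drift
  ≤ 1e-10 asserted).  Löwdin is chosen because it minimally perturbs the
  pivoted vectors.
* *Foster–Boys orbitals*: the FB objective solved by the same trust-region
  machinery from a Cholesky-orbital start.

Defaults: occupied → FB (fewest ER macroiterations, typically 3–4 on the
fixtures), virtual → Cholesky orbitals.

## Locality diagnostics

`σ₂ᵖ = sqrt(Σ_u Var_u)` per orbital (bohr), with centroids; summarized by
σ₂ᵐᵃˣ (conservative, outlier-sensitive) and σ₂ᵃᵛᵍ.  Variances below
−1e-10 raise an integral-consistency error; tiny negatives are clamped to
zero.  Output orbitals are canonicalized: sorted by centroid
lexicographically on a 1e-6 bohr grid (ties keep input order), sign fixed
so each column's largest coefficient is positive — idempotent and
permutation/sign invariant.  The fourth-moment spread is out of scope (the
required integrals are not implemented).

## Integral engine and SCF

A McMurchie–Davidson engine over contracted spherical Gaussians (s/p/d)
supplies overlap, kinetic, nuclear-attraction, multipole-moment and
repulsion integrals.  ERIs are evaluated per signature-batched shell-pair
groups through Hermite E-coefficients and the Hermite Coulomb tensor, with
Cauchy–Schwarz screening at 1e-12 and a dense in-core packed pair matrix
for `n_ao ≤ 200` (larger systems fall back to on-demand pair-column
evaluation for the pivoted decomposition).  The Boys function uses the
regularized incomplete gamma form with a series branch below T = 1e-12
(agrees with the confluent-hypergeometric form to ~4e-14 relative).

The restricted HF solver uses a symmetric-orthogonalization core guess,
DIIS (depth 8), Coulomb/exchange builds through an internal τ = 1e-8
Cholesky factor, and converges the max-abs orthonormal-basis orbital
gradient to 1e-7 by default.  Near-linear dependencies are projected out at
eigenvalue ratio 1e-8 in the orthogonalizer; localization operates on
whatever MO set it receives.

Basis data: STO-3G (H/C/N/O) and cc-pVDZ (H/C/N/O) primitives are embedded
literature constants; the two deep s contractions and the p contraction of
C and N are the atomic Hartree–Fock orbitals recomputed in the primitive
set (their defining construction), which reproduces molecular RHF energies
to a few mEh (water/cc-pVDZ to 2e-4 mEh of the literature value).  Shell
metadata for cc-pV{D,T,Q}Z and aug- variants of H and B–Ne supports exact
basis-function counting.  Coordinates are bohr internally; XYZ input is Å
converted by 1.8897261254578281.

## Fixtures and what they do (and do not) show

Fixture geometries are idealized (standard bond lengths, tetrahedral
chains, planar sp² carboxyl); they emulate the molecule classes of
interest — including an all-trans fatty-acid chain of any length — but are
not literature geometries, so geometry-sensitive quantities (e.g., exact
Cholesky vector counts) are reproduced only in trend.  Chain-local
properties saturate quickly with length: the least-local occupied orbital
of the n-alkanoic acid chain has σ₂ ≈ 1.6 bohr already at three carbons,
which is why `scripts/acceptance.py` runs the three-carbon member; the
basis-function counts are evaluated at the full twenty-carbon chain, where
they are geometry-independent.  Passing tests demonstrate algorithmic
correctness (factorization bounds, derivative identities, optimizer
behavior, invariances) — not chemical accuracy of the idealized geometries
or of the embedded double-zeta basis beyond the few-mEh level documented
above.

## Known limitations

* Closed-shell RHF only; no ECPs; angular momenta above d have counting
  metadata but no integrals (cc-pVTZ+ cannot be evaluated, only counted).
* Virtual ER localization converges but, as expected for this functional,
  yields larger spreads than variance-based schemes; several local minima
  exist and different starts may select different ones (the minimum
  verification only guarantees *a* minimum).
* The in-core ERI ceiling (n_ao ≤ 200) bounds the exact-oracle tests; the
  out-of-core pair-column path is functional but quartet evaluation in
  Python limits practical system size to a few hundred AOs.
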