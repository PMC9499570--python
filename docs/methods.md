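# Methods

This note records the models implemented in `fermifactor`, the defaults and
why they were chosen, and what the test suite does and does not demonstrate.

## Hamiltonians

The package works on active-space electronic-structure Hamiltonians

    H = E_core + sum_pq h_pq E_pq
        + 1/2 sum_pqrs (pq|rs) (E_pq E_rs - delta_qr E_ps),

with real spatial orbitals, chemist-notation two-electron integrals (pq|rs)
carrying 8-fold permutational symmetry, and a positive-semidefinite N^2 x N^2
integral supermatrix V. FCIDUMP is the on-disk interchange format (1-based
indices, `(i j 0 0)` one-body lines, `(0 0 0 0)` core energy); internally
everything is 0-based. Complex integrals are rejected; point-group symmetry
is not exploited. Files are written with a 1e-12 magnitude threshold and
descending-index ordering so repeated writes are byte-identical.

### Synthetic instances

`synthesize_hamiltonian(n_orb, cholesky_rank, seed)` builds
`eri = sum_l L_l (x) L_l` from random symmetric factors with 1/(1+l) decaying
weights and a random symmetric one-body matrix with entries of order 0.5 Ha.
This reproduces the structural features the downstream algorithms consume —
exact 8-fold symmetry, PSD supermatrix with a known, controllable Cholesky
rank, one- and two-body scales of order a Hartree — and deliberately nothing
else: there is no Coulomb decay structure, no spatial locality, no
near-sparsity, and no correlation between h1 and the ERIs. Consequently the
test suite demonstrates correctness of the machinery (decompositions,
norms, cost accounting, optimizers) on such instances; it does not
demonstrate that compression ratios or lambda values match those of
molecular integrals, which are far more compressible. Scaling exponents
fitted on the synthetic family are therefore upper-end estimates.

The scaling family used in tests spans N in {6, 8, 10, 12, 14} at fixed
half filling with Cholesky rank min(6N, N(N+1)/2) — the ~6-10 vectors per
orbital typical of molecular Cholesky decompositions — and THC rank
M = round(4.7 N), the generic rank-per-orbital multiplier.

### FCI oracle

`exact_spectrum` enumerates occupation-number determinants per
(n_alpha, n_beta) sector and applies the Slater-Condon rules, refusing
n_orb > 8. It exists to validate other components (lambda bounds, the MP2
surrogate's perturbation series, rotation invariance) and is itself checked
against an independent dense Jordan-Wigner construction of the Fock-space
Hamiltonian.

## Factorizations

* **SF** eigendecomposes V (pivoted Cholesky available behind
  `method="cholesky"`); eigendecomposition is the default because its
  ordering is deterministic. Truncation keeps the minimal eigenvalue-ordered
  prefix meeting a Frobenius tolerance, using the identity that the dropped
  error is the root-sum-square of dropped eigenvalues.
* **DF** eigendecomposes each SF leaf and drops eigenpairs below `leaf_tol`
  in magnitude; the average retained leaf rank Xi is the quantity entering
  space/time complexity.
* **THC** fits `(pq|rs) ~= sum chi_p^mu chi_q^mu zeta_{mu nu} chi_r^nu
  chi_s^nu`. Initialization is a symmetric CP decomposition of the stacked
  Cholesky vectors: ALS over three factor matrices with the two orbital
  factors tied by averaging each sweep (500 sweeps max, 1e-8 relative-change
  stop), seeded random-normal start. Refinement is L-BFGS on (chi, zeta)
  jointly with analytic gradients, up to 10,000 evaluations, ftol 1e-14. An
  optional L1 penalty rho * sum|zeta| (Huber-smoothed with width 1e-8)
  discourages lambda growth; the default is rho = 0 because no universally
  good strength exists — sweep it per system. Columns of chi are normalized
  to unit Euclidean norm afterwards, with scales absorbed into zeta, which
  makes lambda_THC well defined. Equal-objective solutions are resolved by
  whichever the optimizer reaches first; `init=` warm-starts a higher rank
  from a lower-rank solution (padded with 1e-3-scale random columns).

## Qubitization lambda

The one-body part uses the effective matrix
`T' = h1 - 1/2 (pr|rq) + (pq|rr)` (the reordering terms of the encoding
absorbed), lambda_1 = sum |eig(T')|. Two-body conventions:

* SF: 1/4 sum_l (sum_pq |L_pq|)^2
* DF: 1/4 sum_l (sum_m |f_lm|)^2
* THC: 1/2 sum |zeta| (unit-norm chi)

These are validated internally rather than taken on faith: a block encoding
represents H - c I, where the scalar c collects Tr(T'), the -1/2 sum of
squared factor traces released when each number-like factor is centred, and
— for the squared SF/DF constructions — a per-leaf midpoint lambda_l^2/4
(each centred square lies in [0, lambda_l^2] and is encoded about its
midpoint, which is exactly what makes the 1/4 prefactors rigorous rather
than off by two). `encoding_shift` computes c, and the property tests assert
lambda >= max |E - c| over every particle sector of the FCI oracle. Without
the midpoint term the 1/4 DF convention demonstrably violates the bound on
dense random instances.

## Rank selection

Truncation quality is measured where it matters: in a correlated energy,
not a tensor norm. The surrogate is closed-shell semicanonical MP2 — Fock
matrix from the given integrals with the first n_occ orbitals doubly
occupied, occupied-occupied and virtual-virtual blocks diagonalized, and
the standard spin-adapted pair-energy sum. The reference is frozen: the
reconstructed integrals enter only the amplitudes, never the Fock operator
or denominators, isolating the integral-truncation effect. Degenerate or
inverted gaps raise an error instead of being level-shifted, because a
silent shift would corrupt every downstream comparison. A CCSD(T)-grade
engine can be plugged in via the `surrogate` callable; the selection loop —
increase the knob until the error drops below 1 mHa (0.6275 kcal/mol),
configurable — is the algorithmic content and is engine-agnostic. The
error-vs-rank curve is not asserted to be monotone (the surrogate is not
variational); only the first-crossing selection is contractual.

## Logical cost model (`fermifactor-cost-1`)

Phase estimation applies the walk operator `ceil(pi lambda / (2 eps_pea))`
times — the standard qubitized-phase-estimation constant, frozen so targets
are well defined. The error budget is additive across phase estimation,
oracle rounding, and integral truncation; the split is configuration
(defaults 1 mHa each) because no principled universal split exists.

Each walk step is itemized:

* QROM data lookup over the Gamma stored coefficients with output width b,
  costed as `min_k ceil(D/2^k) + b (2^k - 1)` Toffolis (uncompute
  `min_k ceil(D/2^k) + 2^k`), with the `b 2^k` temporary output copies
  counted as ancilla at the optimal k;
* alias-sampling state preparation (comparator on the keep register +
  controlled swap on the index register);
* controlled swaps into the 2N-qubit system register;
* for DF/THC, rotation-angle lookup plus programmed Givens networks of N
  rotations at `rot_bits - 2` Toffolis each, applied and inverted on both
  spin sectors, with the N * rot_bits angle register counted in space;
* the qubitization reflection on index + keep registers.

Defaults: `coeff_bits = 10`, `rot_bits = 16`. Data sizes are
Gamma_SF = L N(N+1)/2, Gamma_DF = sum_l Xi_l (angles and coefficients),
Gamma_THC = M(M+1)/2 + N. The square-root QROM trade-off is what produces
the characteristic orderings — THC's O(M^2) table gives ~N per-step cost
and ~N qubits, SF's O(L N^2) table gives ~N^1.5 — and those orderings are
asserted as fitted exponents on the synthetic family, not as pointwise
counts. Ancilla accounting follows the sublinear (square-root) reading
throughout. The model's constants are versioned (`MODEL_VERSION`) and
pinned by regression tests; the per-step numbers are this package's own
cost model, not a reproduction of any external estimator's, so absolute
Toffoli counts should be compared across methods within the package rather
than against other tools.

Empirical scaling fits are ordinary least squares of log(value) on log(N),
reporting slope, exp(intercept), and R^2.

## Surface-code model (`fermifactor-surface-1`)

Logical failure rate per qubit per cycle: `p_L = 0.1 (p_phys / 0.01)^((d+1)/2)`
— the standard surface-code fit (prefactor 0.1, threshold 1%). Inputs above
0.5% are refused.

Factories are parametric models authored for this package. A raw injected
magic state fails with probability `10 p_phys`; a 15-to-1 distillation round
at distance d multiplies error as `35 p^3` and adds a topological term
(patches x cycles x p_L(d), with 12 patches x 6d cycles at level 1 and
20 x 6d at level 2). The AutoCCZ factory is two 15-to-1 levels (d1, d2)
feeding a catalyzed CCZ assembly that consumes four level-2 T states
(p_out = 4 p2), occupies `2*12*2(d1+1)^2 + 20*2(d2+1)^2` physical qubits,
and emits one CCZ per `ceil(5.5 d2)` cycles. The T15to1 variant groups four
T outputs per Toffoli. At p_phys = 0.1% these constants put the optimum near
d1 ~ 15, d2 ~ 29-31 and data distance ~ 29-31 for 10^9-10^10 Toffoli
workloads, the regime the compiled headline configurations occupy.

Space: each logical qubit occupies 2 (d+1)^2 physical qubits; a 50% routing
overhead applies to data + factories jointly. Time: runtime =
max(T x period x cycle_time / n_factories, T x reaction_time) — the
factory-bottleneck bound with a reaction-time floor for the sequential
Toffoli dependency. Total failure combines factory and data-qubit survival
in log space, so probabilities remain accurate at the 1e-15 scale.

Defaults: 1-us cycle, 10-us reaction time, four factories. (The source
literature for these workloads prints both millisecond and microsecond
cycle/reaction times in different places; only the microsecond reading is
consistent with its own compiled runtimes, so that is the default here.)

`optimize_config` exhaustively enumerates d_data in odd [3, 51], d1 in odd
[7, 25], d2 in odd [15, 41] (overridable), keeps configurations with total
failure <= 10%, and minimizes spacetime volume (physical qubits x seconds),
breaking ties toward fewer qubits and then smaller d_data. Infeasible grids
raise an error carrying the best failure probability found.

## DMRG cost extrapolation

CPU time scales as O(k^3 M^3), memory as O(k^2 M^2), disk as O(k^3 M^2) in
active orbitals k and bond dimension M. Extrapolation multiplies a measured
reference point by the corresponding ratios, with no internal rounding;
reports round half-away-from-zero at the end. The generic THC rank
multiplier is a through-origin least-squares slope of rank on N — an
intercept would make a single "rank per orbital" number ill-defined. The
orbital count k is always an explicit input, never hard-coded.

## Pipeline

`run_pipeline` chains load/synthesize -> (optional) rank selection ->
factorization + lambda -> logical resources -> surface-code compilation,
writing one JSON artifact per stage plus a summary whose every number
traces to a stage artifact. Outputs embed the seed, a hash of the
computation-relevant config fields, and both model version strings. All
randomness flows from the explicit config seed.

## Known limitations

* The MP2 surrogate is closed-shell; open-shell references require an
  external engine via the plug-in interface.
* Absolute Toffoli/qubit counts depend on authored model constants; they are
  internally consistent and versioned but not calibrated against external
  estimators.
* Factory models are parametric fits, not distillation-circuit
  constructions; routing is a flat 50% overhead, not a layout.
* THC refinement is non-convex; different seeds can reach different local
  optima (deterministic per seed). Planted-factor recovery is verified at
  small sizes only.
* No point-group symmetry, no complex integrals, no Trotter-based
  alternatives to qubitization.
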