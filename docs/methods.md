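# Methods

## Model

The CFN (Cavender–Farris–Neyman) model is the two-state symmetric Markov
substitution model on a tree: site states in {−1, +1} (purine/pyrimidine),
uniform root distribution, and transition probability
`P(i → j) = (1 + i·j·θ_e)/2` along an edge with Hadamard parameter
`θ_e = exp(−2 d_e)`, where `d_e` is the branch length in expected
substitutions per site. On the 3-leaf star tree the probability of observing
the leaf pattern `σ ∈ {−1,+1}³` is the polynomial

    p_σ(θ) = (1/8) (1 + σ₁σ₂ θ₁θ₂ + σ₁σ₃ θ₁θ₃ + σ₂σ₃ θ₂θ₃),

invariant under a global sign flip (`p_σ = p_{−σ}`), so the 8 patterns
collapse without loss to 4 split classes, ordered {} (all leaves equal),
{1}, {2}, {1,2} by which leaves carry the minority state relative to leaf 3.
Sites are iid; the data is the 8-pattern count vector `s` (or its split
collapse `s̄`), and the log-likelihood is
`ℓ(θ) = Σ_α s̄_α log p̄_α(θ) − N log 2`.

The parameter domain is deliberately the *closed* cube `[0,1]³`: `θ = 1` is a
zero-length branch and `θ = 0` an infinitely long one. Closing the domain
makes the maximizer set nonempty (the likelihood is upper semicontinuous)
at the price of losing identifiability on parts of the boundary — which is
precisely the phenomenon the solver characterizes.

Two classical reparameterizations are implemented because the estimator and
its correctness checks live in them: Sylvester–Hadamard conjugation
(`p̄ = H⁻¹ exp(Hγ)` with edge spectrum `γ = (−Σd, d₁, d₂, d₃)`), and the
Fourier coordinates `q = H₂ p̄ = (1, θ₁θ₃, θ₂θ₃, θ₁θ₂)`. The Hadamard matrix
constructor accepts any order up to 12 (the recursion is cheap and useful for
testing); only order 2 is used by the solver.

## The closed-form solver

The sufficient statistics are the pair agreement counts `M⁺_ij, M⁻_ij` and
correlations `B_ij = (M⁺_ij − M⁻_ij)/N`, consistent estimators of the Fourier
coordinates `θ_iθ_j`. Two genericity assumptions gate the closed form:

* **A.1** — every split class observed (`s̄_α > 0` for all four α). This
  guarantees `M⁺, M⁻ ∈ (0, N)` so no boundary log-likelihood formula ever
  sees `log 0`.
* **A.2** — the three `B_ij` are nonzero and pairwise distinct.

Both are checked on exact integers: `N·B_ij = M⁺ − M⁻` is an integer, so
zeros and ties are decided exactly. The same policy governs all regime
dispatch: membership in the interior region
`D = {x ∈ (0,1)³ : x_i x_j < x_k}` is tested as `(N·B_i)(N·B_j) < N·(N·B_k)`
in integer arithmetic, never on floats.

For generic data the maximizer set is:

1. **Interior** (`B ∈ D`): the unique point
   `θ* = (√(B₁₂B₁₃/B₂₃), √(B₁₂B₂₃/B₁₃), √(B₁₃B₂₃/B₁₂))`, whose pair products
   reproduce `B` exactly; the maximum equals the saturated multinomial value
   `Σ s̄_α log(s̄_α/N) − N log 2` because `θ*` fits the empirical split
   frequencies perfectly.
2. **Face, one θ = 1** (all B positive, one product constraint violated): a
   singleton — the leaf excluded from the *smallest-B* pair is pinned to
   `θ = 1` and the other two coordinates equal their correlations with that
   leaf.
3. **Curve, one θ = 0** (exactly one B positive): the odd leaf (excluded from
   the positive pair) is pinned to `θ = 0`; only the product of the two free
   coordinates is identifiable, fixed to the positive correlation. The
   returned representative is the balanced point `(√B, √B)` on the free pair.
4. **Independence union** (all B negative): every point with at least two
   coordinates zero; the likelihood is flat at `−N log 8`.

Non-singleton answers are returned as a structured constraint list (pinned
coordinates and/or a fixed product) plus one canonical representative,
because callers need both the set and a usable point.

Each regime's maximal log-likelihood is computed by two algebraically
equivalent closed forms (e.g. `M⁺ log(1+B) + M⁻ log(1−B) − N log 8` vs
`M⁺ log(M⁺/4N) + M⁻ log(M⁻/4N)` in the curve regime) and additionally
compared against direct evaluation of `ℓ` at the representative point; any
disagreement beyond 1e−9 raises an internal-consistency error rather than
returning silently. These redundancies cost microseconds and catch indexing
mistakes, the dominant failure mode in split/pair bookkeeping.

**Non-generic data.** When A.1/A.2 fail the closed form's hypotheses are
violated and the solver refuses by default with a diagnostic report listing
every violation (which split class is empty, which B values are zero or
tied). A `force_numeric` flag reroutes to the numerical maximizer instead.
The structure of the maximizer set at exact ties is deliberately not
invented; the numerical answer is tagged `NUMERIC_FALLBACK`.

## The numerical oracle

The oracle exists to validate the closed form and to serve the non-generic
fallback; it shares no code path with the solver. Design: a `grid_n³` scan of
the closed cube (boundary included, since maxima frequently lie there),
followed by bounded L-BFGS-B refinement with the analytic gradient of `ℓ`,
started from the best grid points, from the best grid point *of each of the
six faces*, and from seeded uniform restarts. The per-face starts matter: on
boundary-regime data the surface has distinct local maxima on different
faces whose values can differ by less than 1e−2, and a purely rank-based
start selection can leave the globally optimal face unexplored. Defaults
(`grid_n = 11`, `restarts = 5`, `ftol = 1e−14`, `gtol = 1e−10`) give
agreement with the closed form at the 1e−12 level on typical generic data,
comfortably inside the 1e−6 tolerance asserted in the tests. −∞ is used as an
honest value for the evaluator; inside the optimizer the split probabilities
are clipped at 1e−12 so the objective stays finite and the gradient keeps
pointing back into the feasible region.

## Simulator

`simulate_sites` draws iid sites by the generative story: a uniform root
state at the internal vertex, then each leaf copies the root with
probability `(1 + θ_i)/2`. Draws use `numpy.random.default_rng(seed)` in a
fixed, documented order — the root vector first, then the flip vectors for
leaves 1, 2, 3, each as one vectorized draw — so streams are bit-reproducible
for a fixed seed. The simulator emulates exactly the model the estimator
assumes: iid sites, no rate heterogeneity, no indels or alignment error, a
uniform root. Passing recovery tests therefore demonstrate correctness of
the estimator under its own model, not robustness to model violation on real
alignments.

`simulate_boundary_scenarios` produces *exact* regime fixtures without
sampling noise: it draws an integer correlation triple inside the requested
regime's region, inverts the linear identity `4 s̄_α = N ± N·B₁₂ ± N·B₁₃ ±
N·B₂₃` to split counts (adjusting parities by at most one unit so the
inversion is integral), expands to a pattern vector, and post-verifies the
regime with the solver's own exact dispatch.

## Parameters, defaults, units

* Branch lengths `d`: expected substitutions per site, in `[0, ∞]`; `θ`
  dimensionless in `[0,1]`; conversions are exact at the endpoints
  (`∞ ↔ 0`, `0 ↔ 1`).
* All log-likelihoods are natural-log; the CLI offers `--log2`.
* Float tolerances: 1e−10 absolute for Hadamard-conjugation agreement and
  1e−12 for the Fourier identity (all quantities are O(1)); 1e−9 for internal
  closed-form/direct-evaluation consistency; 1e−6 for closed-form vs oracle
  agreement (the oracle's termination accuracy, not the algebra, is the
  binding constraint).
* DNA input maps purines (A, G, R) to −1 and pyrimidines (C, T, U, Y) to +1;
  literal `0/1` and `-/+` alphabets are accepted; unmapped characters drop
  the column (counted) or raise, per policy.

## Problem sizes used in the test suite

Stochastic checks use sizes at which the asserted effects are decisive:
consistency and independence checks at 1e5 sites, empirical-frequency
agreement at 1e6 sites (4-sigma bands), unbiasedness over 200 replicates of
1e4 sites, parameter recovery over 50 seeds of 1e5 sites, and closed-form vs
oracle agreement over 500 random generic count vectors of 100–1000 sites.
All run in seconds because every estimator here is closed-form or
three-dimensional.

## Known limitations

* Three leaves only. For four or more leaves the likelihood equations are
  not solvable by pairwise sequence comparisons and in general not by
  radicals; nothing here generalizes mechanically.
* CFN only: two states, symmetric rates, uniform root. No molecular clock is
  assumed (all three branches vary freely).
* Behavior at exact A.2 ties (e.g. two equal B values) is surfaced as a
  diagnostic, not estimated: the maximizer-set structure there is outside the
  closed form's hypotheses.
* The alignment reader assumes clean, pre-aligned, equal-length sequences;
  it does no alignment or error modeling.
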