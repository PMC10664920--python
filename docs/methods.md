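# Methods

## Model

`netstab` analyzes the discrete-time dynamics of a chain of N layers (one
unit per layer unless expanded) driven by a constant input x in layer 1:

    h_{l,t} = x δ_{l,1} + α_{l-1→l} h_{l-1, t-Δ} + Σ_{k≥l} α_{k→l} h_{k, t-1}

Feedforward connections run l-1 → l; feedback connections run k → l with
k ≥ l, and the *distance* of a feedback connection is q = k - l (q = 0 is a
self-loop).  Feedback is always delayed by one step.  The feedforward delay
Δ distinguishes two transmission schemes:

* **biological** (Δ = 1): every transmission takes a time step, as with
  axonal conduction between cortical areas;
* **artificial** (Δ = 0): the feedforward sweep is instantaneous within a
  time step, as in a conventional deep network's forward pass.

In matrix form, with (M_FF)_{ij} = α_{j→i} δ_{j,i-1} (strictly
subdiagonal) and (M_FB)_{ij} = α_{j→i} Θ(i ≤ j) (upper triangular), both
schemes are linear iterations h_t = drive + M h_{t-1} with effective matrix

    M_B = M_FF + M_FB                    (biological)
    M_A = (Id - M_FF)^{-1} M_FB          (artificial)

Id - M_FF is unit lower triangular, so M_A always exists and equals the
finite Neumann series of the nilpotent M_FF.  Both schemes share the fixed
point h* = x (Id - M_FF - M_FB)^{-1} e_1; only its stability differs.  The
fixed point is stable iff every eigenvalue of the scheme's effective matrix
lies strictly inside the unit circle; the bifurcation boundary in weight
space is where an eigenvalue crosses it, p_M(e^{iθ}) = 0.

Layer indices are 1-based in every public interface; matrices are stored
0-based, so α_{j→i} sits at entry [i-1, j-1].

## Unit-circle conditions

For a monic real polynomial p(λ) = Σ c_n λ^n, λ = e^{iθ} with θ ∉ {0, π}
is a root iff the two residuals

    c_0 - Σ_{n=0}^{N-2} c_{n+2} U_n(cos θ)   and   Σ_{n=0}^{N-1} c_{n+1} U_n(cos θ)

vanish simultaneously (U_n: Chebyshev polynomials of the second kind); at
θ ∈ {0, π} a single alternating coefficient sum takes their place.  These
conditions are kept as an independent analytic cross-check; the primary
classifier is a dense nonsymmetric eigensolver, with the marginal band
|ρ - 1| ≤ 1e-8 separating genuine boundary points from floating-point
noise.

## Canonical families and the generator

The structured families double as the package's synthetic data:

* `single_q` — uniform feedforward chain (weight w_ff) with feedback of a
  single distance q (weight w_fb); loop gain g_q = w_fb · w_ff^q.
* `fig5a` / `fig5b` / `fig5c` — 2-, 3- and 5-layer slices parameterized by
  weight *products*: self-coupling w_i and reciprocal-pair product w_p
  (N = 2, 3), or the short-pair product w_short and the long-loop product
  w_long (N = 5).  Since redistributing weight inside a loop at fixed
  product is a diagonal similarity (spectrum-neutral, tested), all
  feedforward weights are set to 1 and the product rides on the feedback
  weight.
* `fully_connected` — dense coupling w_i on the diagonal, w_e elsewhere;
  deliberately non-layered and flagged as such.
* `chain_time_decay` — a chain with leaky self-feedback τ_l per layer, the
  scalar reduction of the time-decay recurrence
  h_{l,t} = τ_l h_{l,t-1} + I_{l,t}.

The random generator draws feedback weights from a bounded distribution at
a requested set of distances, with seeded, bit-reproducible output.  Study
samplers draw weights uniformly from [-1.5, 1.5] (feedback) and
[-1.2, 1.2] or [-1.5, 1.5] (feedforward) so that stable and unstable draws
are both common; slice windows are the symmetric [-2, 2] × [-2, 2],
covering every boundary branch of all three slices.  Sizes used by the
verification studies: 200 × 200 slice grids, 1e4 random specs for
containment, 1e3 networks for the equivalence study (N ≤ 10), 500 specs
per family for the simulation oracle, 1e3 instances for the nonlinear
study.  What the generator does *not* emulate: multi-unit layers with
heterogeneous within-layer weights, weight distributions with heavy tails,
and any form of training dynamics — conclusions are about the linear(ized)
activity dynamics only.

Multi-unit expansion replaces each scalar weight α by the uniform block
(α/units)·J.  Each block is rank one with the uniform vector as its range,
so block-row sums and the nonzero spectrum of the one-unit system are
preserved exactly.  This is one consistent choice of expansion, not the
only one; heterogeneous blocks would change the spectrum.

## Equivalence of the two schemes for single-distance feedback

When feedback sits at a single distance q, the characteristic polynomials
factor as p_A(λ) = λ^{k1} g(λ) and p_B(λ) = λ^{k2} g(λ^{k3}), so every
nonzero root z of p_B satisfies z^{k3} ∈ roots(p_A) and the two schemes'
bifurcation boundaries coincide.  The contraction exponent k3 is
*discovered* by searching 1..N for the power that maps one nonzero
spectrum onto the other (roots whose k-th power falls below 1e-6 count as
the zero root); across 1e3 random single-distance networks the discovered
k3 always equals q + 1 — the temporal contraction factor that also makes
the instantaneous implementation q + 1 times cheaper.

## Closed forms and their regimes

* **Single distance, long loops** (N/2 - 1 < q): the nonzero spectrum
  collapses to the single eigenvalue g_q (N - q) — loop gain times the
  number of loops — exactly (checked to 1e-10 against the eigensolver).
  The stability threshold on the loop gain is 1/(N - q).
* **Single distance, short loops** (q ≤ N/2 - 1): only the trace identity
  survives: the N - 2q nonzero eigenvalues sum to g_q (N - q), and the
  zero root has algebraic multiplicity ≥ 2q (measured via the rank of
  M_A^N with a relative tolerance, since powers of defective matrices
  scatter naive eigenvalue estimates).  The dominant eigenvalue is
  generally complex and *smaller* in modulus than the trace, so 1/(N - q)
  is only a lower bound on the true threshold here.
* **Monotonicity in q.**  "Longer loops are more stable" holds in two
  precise senses: within the exact regime the loop-gain thresholds
  1/(N - q) increase with q, and the per-link-weight thresholds (all
  weights equal to w, threshold on |w|) are nondecreasing over the whole
  range q = 1..N-1, matching (1/(N - q))^{1/(q+1)} where the closed form
  is exact.  It does **not** hold for the loop-gain threshold across the
  short-loop regime: at N = 7 with unit feedforward weights the measured
  threshold on |w_fb| is 0.2929 at q = 1 but 0.2324 at q = 2.  A dedicated
  test freezes this counterexample so the limitation stays visible.
* **Fully connected**: eigenvalues w_i - w_e (multiplicity N - 1) and
  w_i + (N - 1) w_e; stable iff
  -(1 + w_i)/(N - 1) < w_e < min(w_i + 1, (1 - w_i)/(N - 1)).  The dense
  threshold 1/(N - 1) on |w_e| is below the layered per-link threshold
  (1/(N - q))^{1/(q+1)} for every q — layering buys stability.
* **Mixed feedback** (distances q1 < q2, both in the long-loop regime):
  the relevant eigenvalue is approximately g1 (N - q1) + g2 (N - q2), so a
  longer loop with positive gain shifts the admissible window for the
  short-loop gain; verified against the eigensolver with tolerance 0.05.

## Scheme containment: what is actually true

A tempting universal claim — that the delayed scheme's stable region
always contains the instantaneous one — is **false**.  By the N = 2 closed
forms, at (w_i, w_p) = (0.5, -1.5) the instantaneous iteration is stable
(|λ| = 0.5) while the delayed one diverges (|λ| = √1.75); direct
simulation confirms both verdicts.  Over symmetric slice windows the
violations fill the mixed-sign quadrants, in both directions depending on
the quadrant.  What does hold, and what the suite verifies:

* **Axes / single distance**: on each slice axis one feedback type is
  zeroed, feedback is single-distance, and the two schemes' refined
  bifurcation points coincide (measured gap < 1e-12).
* **Nonnegative weights**: (Id, M_FF + M_FB) and (Id - M_FF, M_FB) are
  both regular splittings of Id - M_B, so their iteration matrices'
  spectral radii cross 1 together — the stable regions *coincide*
  (0 mismatches over random nonnegative specs).
* **Excitatory feedforward with inhibitory feedback** (the biologically
  motivated sign pattern; self-inhibition and negative loop products):
  containment holds, with the delayed region strictly larger for a few
  percent of draws, and same-sign slice quadrants show no violations.

The falsifiable universal test is still implemented and reported as-is;
its violation counts are honest measurements, not defects.

## Simulation oracle

`iterate_dynamics` is the brute-force check on every spectral claim.
Defaults: max_steps 10 000, tol 1e-10, divergence when the state sup-norm
exceeds 1e15.  The divergence bar sits far above any reachable fixed
point: a convergent near-critical chain amplifies the input by
w_ff/(1 - w_self) per layer, which already passes 1e6 for moderate depths,
so a bar at 1e6 would misread such runs.  Convergence requires, for three
consecutive steps, both a raw step below tol and the exact linear
distance-to-limit (Id - M)^{-1}(h_{t+1} - h_t) below tol; a plain step
test leaves an O(step·ρ/(1-ρ)) gap to the fixed point near criticality.
`steps_to_converge` reports the first step of the confirming run — the
step at which the state stopped changing.  Specs within 0.02 of the
boundary are excluded from oracle comparisons (verdicts there are
tolerance-limited), unstable modes are excited by a seeded 1e-8
perturbation of the initial state, and fixed-point agreement is measured
scaled by 1 + ‖h*‖_∞ because near-critical chains reach fixed points of
magnitude 1e6, where 1e-9 absolute agreement is below the
double-precision noise floor.

## Nonlinear analysis

The activation catalogue covers sigmoid, tanh, gaussian, ReLU, PReLU(α),
SiLU (sigmoid-linear), GELU (exact Gaussian-CDF form, not the tanh
approximation), ELU(α), softplus and identity, each with an analytic
derivative checked against central differences away from kinks.
Conventions: Θ(0) = 1, so ReLU/PReLU slopes at 0 take the right limit; the
ELU slope at 0 follows its x ≤ 0 branch (continuous for α = 1).  Catalogue
derivative ranges are recorded as stated; tight numerical bounds come from
a grid scan with bounded local refinement (gaussian: ±√2·e^{-1/2} ≈
±0.8578 → 0.86; SiLU: [-0.0998, 1.0998] → [-0.1, 1.1]).

Fixed points h* = F(x e_1 + M_B h*) are found by damped iteration from
h = 0 (the dynamics' own initialization, so only the reachable basin is
reported), with the damping factor doubling after improving steps and
halving otherwise — plain iteration can cycle for steep sigmoids.
Non-convergence is reported as a flag, not an exception.  Stability around
a fixed point uses the slope-scaled Jacobians
D·M_B and (Id - D·M_FF)^{-1} D·M_FB with D = Diag[F'(I*)]; the identity
activation reproduces the linear classification bit-for-bit.

The contraction claim — that slopes with |F'| ≤ 1 cannot increase the
spectral radius — is a theorem for entrywise-nonnegative M_B (if |A| ≤ B
entrywise with B ≥ 0 then ρ(A) ≤ ρ(B)), and that is what the suite
asserts, over the catalogue entries whose derivative ranges lie inside
[-1, 1].  SiLU and GELU exceed that bound (slopes up to 1.1); for signed
coupling matrices only the operator-norm bound ‖D·M‖ ≤ ‖M‖ survives, and
the suite tests exactly that weaker statement.

## Known limitations

* No limit-cycle or chaotic analysis beyond the stable/unstable verdict;
  marginal dynamics are classified, not characterized.
* Per-connection heterogeneous delays are out of scope; the two schemes
  are the only delay patterns modeled.
* The mixed-feedback eigenvalue formula is asymptotic; outside its regime
  the package flags predictions as approximate rather than refusing.
* Boundary tracing assumes the spectral radius varies continuously along
  grid edges, which holds on the implemented slices but need not on
  arbitrary parameterizations with eigenvalue crossings.
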