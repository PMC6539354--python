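# Methods

## Model

The package evaluates each decision-making unit (DMU) *o* by a non-oriented
slacks-based measure over a division × period network. Decision variables
are one intensity vector λₖᵗ per (division k, period t) and one slack per
observed variable: input excess s⁻, link excess sⁱⁿ, desirable-output
shortfall s⁺, undesirable-output excess sᵇ⁻, carry-over shortfall s꜀. The
objective is the ratio of the weighted average numerator brackets

  Nₖᵗ = 1 − (mₖ + linkinₖ)⁻¹ (Σ s⁻/x₀ + Σ sⁱⁿ/z₀)

to the weighted average denominator brackets

  Dₖᵗ = 1 + (r1ₖ + r2ₖ + ngoodₖ)⁻¹ (Σ s⁺/y₀ + Σ sᵇ⁻/y₀ᵇ + Σ s꜀/z₀),

with weights Wᵗ·Wᵏ, each weight vector normalized to sum to one.
Constraints per (k, t): x₀ = Xλ + s⁻; y₀⁺ = Y⁺λ − s⁺; y₀⁻ = Y⁻λ + sᵇ⁻;
z₀ⁱⁿ = Zⁱⁿλₖ + sⁱⁿ for each link into k (the *receiving* block's λ);
z₀ = Σⱼ zⱼλⱼᵏᵗ − s꜀ for each good carry-over; eλₖᵗ = 1 (variable returns to
scale); carry-over continuity Σⱼ zⱼ λⱼᵏᵗ = Σⱼ zⱼ λⱼᵏ'ᵗ⁺¹ for t = 1..T−1.
Carry-over values are stored per period t as the stock carried out of t.

Assumptions: strictly positive data (zeros are replaced, see below); convex
technology with variable returns to scale; links are consumed "as inputs"
by their target division; only the *good* carry-over category exists —
carry-over shortfall is scored in the denominator like a desirable output.
An optional `link_continuity` flag additionally equates the source and
target blocks' benchmark link flow (Σ zλ_source = Σ zλ_target); it is off
by default because the baseline model constrains only the receiving side.

## Solving

Because every slack is determined affinely by λ, the objective is a ratio
of affine functions; the Charnes–Cooper substitution (Λ, S, τ) = τ(λ, s, 1)
with the denominator pinned to 1 yields an equivalent LP, solved with
HiGHS via `scipy.optimize.linprog`. τ is bounded below by 1e-9 against
degenerate scalings. Since the self-benchmark (λ = indicator of *o*, zero
slack) is always feasible, the LP is feasible and bounded and θ*₀ ∈ (0, 1].

Slacks are generally not unique at the optimum. A second LP fixes the
numerator at its optimal value and maximizes the total slack/observation
sum, selecting a deterministic extreme point of the optimal face; all
reported slacks, factor indices and decomposition brackets come from this
lexicographic solution. At θ*₀ = 1 the ratio forces every slack to zero,
so "score one ⇔ all slacks zero" holds exactly.

Numerical choices: HiGHS defaults (primal/dual feasibility ~1e-9);
solutions are re-verified by recomputing constraint residuals in the
original scale with an acceptance threshold of 1e-6; reported tables round
to 6 decimals while full precision is kept internally; batch order and tie
reporting are by sorted dmu id.

## Decompositions and factor indices

Period efficiency (Σₖ Wᵏ Nₖᵗ)/(Σₖ Wᵏ Dₖᵗ), division efficiency
(Σₜ Wᵗ Nₖᵗ)/(Σₜ Wᵗ Dₖᵗ) and division-period efficiency Nₖᵗ/Dₖᵗ are
evaluated from the overall-optimal slacks. This is the established
convention for dynamic-network SBM decompositions: it guarantees the
mediant identity (θ*₀ is the weighted mediant of the period parts, hence
bracketed by the extreme period scores) and the degenerate equalities for
K = 1 or T = 1. Re-optimizing each component's own ratio — each printed as
a minimum in its own right — is available behind
`reoptimize_decompositions`; re-optimized component scores are weakly
smaller and lose the exact mediant identity.

Factor indices are target/actual ratios from the lexicographic slacks:
(actual − slack)/actual for inputs, links and bad outputs;
actual/(actual + slack) for good outputs and carry-overs. Link and
carry-over indices are computed with the same formulas but flagged
`extension=True` in the table, since the classical per-variable index set
covers only own inputs and outputs.

## Data handling

Panels are long tables `dmu,period,division,variable,role,value`. Link
variables are stored under their **source** division (where they are
produced); their slack is attributed to the receiving division. Validation
enforces completeness, role agreement with the spec and nonnegativity.
Zero cells are replaced by 1e-6 × the variable's smallest positive value
across the panel (the objective divides slacks by observed values, so
exact zeros are inadmissible); each replacement warns. Periods are opaque
ordered labels; order comes from the spec when given, otherwise from first
appearance in the data — never lexical sort, to keep carry-over continuity
chains correct. Weights default to uniform (Wᵗ = 1/T, Wᵏ = 1/K): no other
weighting is implied by the model, and common rescalings cancel in the
ratio.

In the packaged two-stage configuration the fixed-assets carry-over
attaches to the production stage by default — capital stock is a
production-side quantity — but `carryover_division=2` moves it to the
health-treatment stage, since an argument can be made for either
attachment. Units (persons, tonnes, 100 million CNY) are metadata only;
all scores are invariant to rescaling any variable's column.

## Synthetic data

`generate_planted_frontier` draws frontier units whose profiles lie, in
every (division, period) block, on a common hyperplane with a strictly
positive normal — positive coefficients on inputs/links/bad outputs,
negative on good outputs/carry-overs. Weak domination strictly decreases
that linear functional, while every convex combination of on-plane points
stays on the plane; therefore no feasible benchmark can dominate a frontier
unit (or an exact combination of them) and all of them score exactly 1.
Dominated units are convex combinations of the frontier units — the same
Dirichlet weights in every block, so carry-over continuity holds for the
certificate benchmark — with inputs/links/bad outputs inflated by factors
in (1.05, 1.5) and good outputs/carry-overs deflated by factors in
(0.6, 0.95), leaving strictly positive slack in every variable and a score
strictly below one. The certificate (weights and factors) is emitted so
tests can check the domination arithmetic without any solver. Magnitudes
span two decades (log-uniform) to exercise units-invariance realistically;
a single integer seed drives one generator in documented order (frontier
values, combination weights, inflation factors), so equal seeds give
byte-identical panels.

`generate_two_stage_panel` applies the same mechanics to the two-stage
preset with yearbook-like structure on the frontier: GDP increasing in
labor and energy; CO₂ and AQI increasing in energy; health expenditure
and media reports drawn independently; respiratory disease and mortality
increasing in the pollution links; smooth fixed-asset stocks. Dominated
units receive one multiplicative inefficiency level per stage,
|N(0, dispersion_s)| on the log scale, with defaults 0.15 (production) and
0.45 (health treatment). The 3× stage-2 dispersion plants the qualitative
pattern that cross-city spread of treatment-stage scores exceeds the
production-stage spread, which the test suite asserts at the default
settings over several seeds. What the generator does **not** emulate:
autocorrelated macro shocks, measurement error, scale correlations between
city size and inefficiency, or any calibration to real city statistics —
so passing tests demonstrate algorithmic correctness on panels with known
structure, not empirical conclusions about real cities.

## Verification

Two independent routes check the engine. (1) A brute-force reference
minimizer (`dndea.bruteforce`) enumerates the efficiency ratio on a
regular grid (step 1e-3) over each λ simplex for instances with one
division, ≤ 3 DMUs and ≤ 2 periods, eliminating slacks analytically; for
two uncoupled periods the product-grid minimum is found by Dinkelbach
iteration on the per-block grids (each step a pure vectorized
enumeration), and continuity-coupled instances are enumerated pairwise at
n ≤ 2, where the equality constraint is exactly representable on the grid.
Engine and grid agree to ~1e-4 across hundreds of random instances, well
inside the 2e-3 resolution of the grid. (2) Closed-form toys: a unit using
twice the input of its peer for the same output scores exactly 1/2; a unit
emitting twice the bad output scores exactly 1/(1 + ½·½) = 0.8.

## Problem sizes and limitations

The study-scale rehearsal uses 31 DMUs × 4 periods × 2 divisions (the
shape of the motivating application); one unit's two LPs have ~300
variables and solve in milliseconds, the full panel in about a second.
Known limitations: no super-efficiency ranking among efficient units; no
constant-returns switch; no bad/free/fixed carry-over categories; no
statistical inference on scores; scores are relative to the observed
sample, so adding units can only lower (never raise) existing scores.
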