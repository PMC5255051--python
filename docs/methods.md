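# Methods

## Error criterion

Each hypothesis `H_i` (i = 1..m) carries a weight `w_i ≥ 0`. For a
rejection indicator `R_i` and erroneous-rejection indicator `V_i`, the
realized weighted false discovery proportion is
`Q(w) = Σ w_i V_i / Σ w_i R_i` (0 when no rejection), and
`wFDR = E[Q(w)]` is controlled at a target level `q`. Conventionally the
weights are normalized to sum to `m`; all thresholds in this package use
the normalization-free form `q · (cumulative weight) / (total weight)`,
so `normalize_weights` is cosmetic and every decision is invariant to a
common positive rescaling of the weights (tested).

The supported design is the standard clinical one: `P` primary
endpoints with weight `R ≥ 1` each and `S` secondary endpoints with
weight 1, so the total-weight ratio is `R′ = RP/S`. The procedures in
`core` accept arbitrary weights; the calibrator supports `P = 1` with
equal secondary weights (the case with worked numbers; multi-level
hierarchies and unequal secondary weights are out of scope).

## Procedures

**wBH.** Sort all p-values ascending with their weights; let
`k = max{ j : p_(j) ≤ q · Σ_{i≤j} w_(i) / Σ w_i }` and reject the `k`
smallest. Ties are sorted stably by original position, and since the
rejection set is `{i : p_i ≤ p_(k)}`, tied p-values share their fate.
Equality with a critical value counts as a rejection. A zero-weight
hypothesis contributes nothing to any threshold but can ride along when
a later cumulative threshold covers its p-value — the step-up set
definition makes no exception for it. With equal weights wBH reduces
exactly to the classic BH procedure (validated against a textbook
implementation over 1,000 random instances).

**Weighted Simes.** For an intersection null over p-values with
positive weights, `p* = min_i p_(i) · Σ_j w_j / Σ_{j≤i} w_(j)`. Equal
weights recover the classic Simes statistic `min_i p_(i)·n/i`.

**HWF.** (i) compute `p*` over the secondary family and give it weight
`w* = Σ w_sj`; (ii) run wBH at level `α` on `{p*} ∪ {primary
p-values}` with weights `{w*} ∪ {primary weights}`; rejected primaries
are discoveries; (iii) iff `p*` is rejected, run wBH at the *same* `α`
on the secondary family. The intersection opens the gate but is never
itself counted as a discovered endpoint. Secondary rejections with a
closed gate are impossible by construction and asserted on every call.
With no secondary endpoints the hierarchy is meaningless and the input
is rejected (use `wbh_adjust`).

## Calibrating the working level

Applied at level `α`, HWF's wFDR exceeds `α` in the worst case: the
configuration that maximizes it (the *worst-case array*, WCA) pins one
secondary p-value at `p ≤ α/(R+S)` — opening the hierarchy with
certainty — and draws the primary and the remaining `S−1` secondary
p-values as independent uniforms.

Under the WCA with independent statistics the error can be computed
exactly. Given the open gate, the primary (true null, weight `R`) is
rejected at level 1 with probability exactly `α` (the pinned
intersection always passes both level-1 critical values, so the
primary's rejection reduces to `p_p ≤ α`). At level 2 the pinned value
occupies rank 1, so the `n = S−1` null uniforms face the critical
values `t_i = α(i+1)/S` at ranks `i = 1..n`. For such linear critical
values the step-up rejection count `j` has the exact Abel-type pmf

```
P(j) = (1−α) · C(n, j) · t_j^j · (1−t_j)^(n−j−1),   t_j = α(j+1)/S ,
```

which we verified to machine precision against an independent
first-crossing recursion valid for arbitrary thresholds (the recursion
lives in the test suite as the oracle) and against Monte-Carlo
simulation. The worst-case error is then

```
HWFDR(α; S, R) = Σ_{k∈{0,1}} Bern_α(k) Σ_j P(j) · (Rk+j)/(Rk+j+1) ,
```

each rejected outcome containing the pinned (correctly rejected)
secondary plus `j` false secondary discoveries and `k·R` weight of
false primary discovery. For `S = 2` the worst configuration is the
all-null one and the error is already ≤ α; the bound degenerates to α.

`calibrate_alpha` returns the largest `α` with bound ≤ q, by bisection
to 1e-7 after a 32-point monotonicity check of the bound on the search
bracket (a non-monotone bound raises rather than returning silently).
Calibration is parameterized by the per-hypothesis ratio `R`; `R′ =
R/S` is reported alongside. The two reference levels it produces are
α(0.05, 1, 6, R=3) = 0.0321 and α(0.05, 1, 50, R=100) = 0.0257.

For `R < S` with `S ≥ 20` the single-pin WCA is known to undershoot the
true maximum by up to ≈ 0.0016 (the gap grows as R falls); in that
regime the calibrator subtracts a safety margin (default 0.002,
settable to 0) from `q` before inverting, and records the effective
target in its result.

Under positive regression dependence the closed-form bound

```
HWFDR ≤ (1−α)·α(S−1)/S + α[ α(S−1)/S + (1 − α(S−1)/S)·R/(R+1) ]
```

is inverted instead (`dependence="prds"`). It fails for two small
windows — S = 2 with R ≤ 3.15 and S = 3 with R ≤ 1.28, where the
all-null configuration escapes it — and the calibrator then falls back
to the simple universal bound `α·(1 + RS/(R+S)²)` (at most `1.25α`,
attained at R = S), which has the closed-form inverse
`α = q/(1 + RS/(R+S)²)`. Note the simple bound is *not* uniformly
larger than the positive-dependence bound away from those windows; it
is the safe replacement inside them, not a majorant everywhere.

`mc_wfdr_worst_case` simulates the WCA directly (optionally with
several pinned secondaries) and is the package's empirical check on the
formula; the vectorized kernel is proven per-draw identical to
`hwf_test` + `wfdr_realized` in the tests.

## Gatekeeper baselines

The comparison baselines are serial-gatekeeper closed-testing
procedures at FWER level α: every intersection containing the primary
endpoint is tested through the primary p-value (the gate), and
pure-secondary intersections by a local Bonferroni or Simes test. The
closure shortcut — primary iff `p_p ≤ α`; then Holm, or Hommel for
Simes local tests, on the secondaries — is delegated to
`statsmodels.stats.multitest.multipletests` and validated against a
brute-force enumeration of all `2^(S+1)−1` intersections over random
draws. Weights play no role in the gatekeepers; their `S` is capped
(16 per table, 10 in the vectorized Simes kernel) since the oracle and
the closure are exponential in `S` and the comparison is only run on
small families.

## Simulation design

One replicate draws `Z_0..Z_S ~ N(0,1)` independently, adds the
primary effect `μ_p` to `Z_0` and the secondary effects to the false
secondaries, and forms two-sided p-values `p = 2(1−Φ(|X|))`. A
scenario fixes `(μ_p, μ_s1, μ_si, S, R, frac_false, q)`: the designated
false secondary (index 1) has effect `μ_s1`, the remaining false
secondaries (indices 2..m_1S) have `μ_si` — an exchangeable assignment
under independence, so the choice of indices is without loss of
generality; `μ_si` is ignored when only one secondary is false. Only
independent statistics are simulated; the PRDS calibration mode exists
but no dependent scenario generator is provided.

Reported measures (false-set conditional): overall weighted power
`Π_G`, primary power `Π_P`, secondary weighted power `Π_S`, the
probability `Π_ALOS` of at least one false-secondary discovery, the
empirical wFDR, and Monte-Carlo standard errors for each.
`Π_δ = δ/(δ+1)·Π_P + 1/(δ+1)·Π_S` is exposed as a post-processing
function of δ — a design-stage reporting weight that never enters the
analysis. HWF runs at the level calibrated per `(q, S, R)` cell; wBH
and the gatekeepers at `q`.

`run_scenario` processes replicates in 50,000-draw batches through
vectorized kernels (`_engine.py`), so memory is bounded and 10,000
replicates per cell take milliseconds; the kernels are asserted
decision-identical to the per-table procedures. `default_grid`
enumerates the full factorial design (μ_p ∈ {0..4}, R ∈ {1,2,8,32,
128,512}, S ∈ {2,4,8,16,32}, fractions {0.25,0.5,0.75,1} with S = 2
restricted to {0.5,1}, μ_s1 ∈ {2..6}, μ_si ∈ {1..3}); cells with a
non-integer false count are dropped and `μ_si` is collapsed when
m_1S = 1. The builder documents its enumeration rather than asserting
a particular total cell count. The test suite runs targeted sub-grids
(20 error-control cells at 10,000 reps; ordering checks at 20,000
reps), not the full design.

## Validation summary

What the passing tests establish: the procedures reproduce both
published worked examples digit-for-digit where inputs are printed; the
exact WCA formula, an independent recursion, and 200,000-draw
simulation agree; empirical wFDR stays below `q` across mixed
true/false scenario grids for both weighted procedures; gatekeeper
power collapses to ≤ α when the primary effect is absent while the
weighted procedures retain power, and the HWF-vs-wBH secondary-power
ordering flips between small and large primary effects.

What they do not show: behavior on dependent endpoints (real trial
endpoints are measured on the same subjects and are positively
correlated — only the calibration bound, not the simulator, covers
that), multi-primary designs (`P > 1` is accepted by the core
procedures but has no calibration), unequal secondary weights in
calibration, and hierarchies deeper than two levels.

## Fixtures and degenerate inputs

The antifungal-trial fixture stores the censored "> 0.5" secondary
p-value as 0.51; tests rerun every procedure at 0.51, 0.75 and 0.999
and assert identical decisions, since all of these exceed every
relevant critical value. The Crohn's-trial fixture exists in three
forms: the published head (four values, flagged incomplete), a
user-supplied full list, and a clearly-labelled synthetic 50-value
stand-in whose published order statistics are pinned and whose
unpublished values are interpolated to respect the published decision
boundaries. All-zero weights, out-of-range p-values, duplicate ids,
empty inputs, non-numeric p-value strings, and HWF without secondaries
raise informative errors; p-values tied with a critical value are
rejected; `α = 0` yields zero error trivially in every bound.
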