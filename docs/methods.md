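# Methods

## Model

A simulated feature is a vector `Y` of length `N = Σᵢ qᵢ` over `n` subjects
(first `n₀` control, remaining `n₁` treatment), drawn from a multivariate
normal — left-truncated at `a` when the non-negativity restriction is on —
with

* mean `μ₀` for every control observation and `μ₀ + f(tⱼ)` for a treatment
  observation at time `tⱼ`;
* covariance `Σ = bdiag(Σ₁, …, Σₙ)`, `Σᵢ = σ²Ω(ρ)`.

The model is on a *transformed* abundance scale (log or arcsinh of
normalized counts, under which marker-gene abundances are approximately
Gaussian). The package deliberately does not model read counts, library
sizes or compositionality; it emulates the distribution practitioners fit
after normalization.

### Trend families

| form | parameters | f(t) |
|---|---|---|
| none | — | 0 |
| linear/quadratic/cubic | β₀…β_p (p ≤ 3) | Σ β_k t^k |
| L_up | slope β₁ > 0, inflection IP | 0 for t < IP; β₁(t − IP) for t ≥ IP |
| L_down | β₀ > 0, β₁ < 0; IP = −β₀/β₁ implied | β₀ + β₁t for t < IP; 0 after |
| oscillating_M (β₁ > 0) / _W (β₁ < 0) | β₀, β₁; IP₁ < IP₂ < IP₃ | piecewise linear through the anchors below |

The oscillating trend rises (M) or falls (W) linearly as `β₀ + β₁t` until
IP₁, where it attains `v = β₀ + β₁·IP₁`; it is then linearly interpolated
through the anchor points (IP₁, v), (IP₂, 0), (IP₃, v) and (t_q, 0). Zero at
IP₂ is exact by construction. The implementation is this anchor
interpolation; each segment's slope, e.g. the final `(−β₀ − β₁IP₁)/(t_q −
IP₃)`, follows directly from the anchors. Because the final segment is
anchored at `t_q`, IP₃ = t_q is rejected; setting IP₂ and IP₃ beyond `t_q`
(with IP₁ inside the interval) degenerates to a single-peak absolute-value
trend, and is allowed. Interval membership at inflection points is
left-closed/right-open, so e.g. `L_up` gives f(IP) = 0 from both branches.

Validation is structural and interval-aware (`validate_trend` returns a list
of named violations; nothing is silently coerced): coefficient counts per
family, sign constraints (`L_up` slope positive, `L_down` decreasing from a
positive intercept, M/W initial slope sign matching the letter), hockey-stick
inflection strictly inside `(t₁, t_q)`.

`evaluate_trend` accepts arbitrary sorted times, so asynchronous schedules
use the same code path; the oscillating decay anchor stays at the design's
`t_q` (passed as `t_end`), not a subject's last observed time.

### Covariance

AR(1) correlation is indexed by *measurement order*, `ρ^|j−j′|`, also under
asynchronous schedules — elapsed-time (continuous-AR) kernels are out of
scope. Compound symmetry accepts `ρ ∈ [0, 1)`: negative exchangeable
correlation is only positive-definite for `ρ > −1/(q−1)`, a q-dependent and
rarely intended regime, so it is rejected with an explicit message. AR(1)
accepts `ρ ∈ (−1, 1)`. `σ` is one global parameter; per-group or per-time
heteroscedasticity is a non-goal.

`Σ` is kept as its list of per-subject blocks. Sampling, Cholesky
factorization and acceptance estimation all operate per block (they are
exact because subjects are independent); the dense `N×N` matrix is assembled
only on request for inspection at small `N`.

### Truncation: rejection vs censoring

With truncation on, each block is drawn by rejection sampling — redraw until
all coordinates exceed `a` — which is exact but infeasible when the
acceptance probability `p_acpt = P(Y > a·1)` is small. The acceptance
probability is estimated by a pilot Monte Carlo (default 1000 unconstrained
draws; the estimate carries binomial error ~1.6% at p = 0.5, shrinking near
the 0.1 decision threshold to ~0.9%). Blocks with estimated `p_acpt ≤ 0.1`
fall back to censoring: one unconstrained draw with sub-`a` values imputed
as `a`. The threshold and pilot size are user-settable
(`TruncationSpec(acceptance_threshold=…, pilot_draws=…)`).

Because all blocks within an arm share a mean and covariance, the estimate
is computed once per distinct (mean-block, covariance) pair and one mode is
applied to the whole group — so a design mixes modes across arms only when
their means differ. Rejection mode aborts with a diagnostic after 10⁵
redraw attempts for a single block rather than degrading silently; the
error suggests censoring. Draw batches escalate geometrically (1, 4, 16, …,
capped at 1024) so the common high-acceptance case costs a single draw.

Censoring changes the distribution (a point mass at `a` instead of
renormalized tails); the two modes coincide only as `p_acpt → 1`, which the
test suite checks with a two-sample Kolmogorov–Smirnov test at μ = 5σ. At
low acceptance the censored draw is the intended approximation, mirroring
the high zero-fraction of real feature tables.

### Schedules and missingness

Equidistant mode places all subjects on the same `q` evenly spaced points of
`[t₁, t_q]`. Asynchronous mode keeps a baseline at `t₁` (every subject is
assumed measured at enrollment) and draws the remaining `q−1` times i.i.d.
uniform on the open interval, sorted within subject.

Missingness selects `round(missing_pct · n)` subjects without replacement
across both arms (nearest rounding, ties to even), then per subject selects
`missing_per_subject` of the `q−1` non-baseline times without replacement
and overwrites `Y_obs` there with `miss_val`; `Y` is untouched and
`miss_data` lists every (subject, time) cell. `miss_val = 0` represents a
feature present but not detected; `miss_val = NA` (NaN in memory, "NA" in
TSV, round-tripped by the readers) a sample never collected. The mechanism
is missing completely at random; abundance-dependent (MNAR) dropout is a
known limitation.

### Communities and design-driven simulation

`simulate_community` draws `features` independent features on one shared
schedule; the first `diff_abun_features` carry the design's trend, the rest
none. Per-feature RNG substreams are spawned from the design seed
(`SeedSequence.spawn`), so features are independent yet individually
reproducible, and the whole table is reproducible from one seed. One trend
is shared by all differential features; heterogeneous per-feature trends
are a straightforward extension but not implemented.

`simulate_from_design` takes an observed (ID, time, group) table — e.g. a
small pilot study — and replicates each subject's schedule `k` times as new
subjects, emulating a scaled-up rerun of the study with unequal `qᵢ`
allowed; the standard pipeline then runs on that design (no missingness
stage, since the schedule itself encodes the realized sampling).

## Metrics and the sweep harness

Detection over `B` repetitions: sensitivity = fraction of truly
differential repetitions where *any* differential abundance was detected;
specificity = fraction of truly null repetitions where none was.
Repetitions whose estimator returned no estimate are excluded from the
denominators and reported as a separate non-missing-estimates count.
Continuous metrics compare `f̂` and `f` on the design's equidistant grid:
cosine similarity (∈ [−1, 1], length-comparable but boundary-saturated),
Euclidean distance (∈ [0, ∞), not comparable across grid lengths) and
normalized Euclidean distance (∈ [0, 2], the distance between unit vectors,
satisfying `d_norm² = 2(1 − cos)`). Direction metrics are undefined against
an identically-zero truth; the package raises an explicit error rather than
guessing. For asynchronous designs the detector contract is still the
equidistant grid of the interval; finer conventions (union grids,
interpolation) belong to the detector.

The harness runs a factorial grid × `B` repetitions, with per-repetition
RNG substreams keyed by (cell, repetition) — results are identical whatever
the execution order, and one seed reproduces the whole table. The estimator
the harness was built to study (Gaussian smoothing-spline ANOVA) is an
external method and intentionally not reimplemented: published benchmark
numbers are estimator properties, not simulator properties. Two reference
detectors ship for exercising the harness: a perfect oracle (returns the
generating trend; the self-test must score sensitivity and specificity
1.00) and a per-timepoint Welch t-test with any-timepoint Bonferroni
detection, a deliberately crude baseline.

## Defaults and problem sizes

Defaults mirror the documented worked examples: 20 subjects per arm,
`μ₀ = 2`, `σ = 1`, `ρ = 0.7`, 5–7 timepoints, zero truncation on,
acceptance threshold 0.1, pilot 1000. The benchmark grid is
`σ ∈ {1, 2, 4} × n/arm ∈ {10, 20, 50} × q ∈ {3, 6, 12}` (27 settings) at
`B = 100`, i.e. 2700 scheduled repetitions; with the oracle detector the
full grid runs in seconds. Stochastic checks in the test suite use
3-standard-error bands at n = 500 per arm (moment recovery) and 4-standard-
error bands on 20 000 draws (censored point mass), sizes at which Monte
Carlo error is far below the effects being verified while the whole suite
stays fast.

## Known limitations

* Gaussian on the transformed scale only — no count-level, library-size or
  compositional effects, no zero-inflation beyond truncation/censoring.
* Features in a community are independent; no inter-taxon correlation.
* Missingness is MCAR; dropout cannot depend on abundance or time.
* AR(1) ignores elapsed time between asynchronous measurements.
* Censoring mode is an approximation to the truncated distribution, chosen
  exactly when the exact sampler is impractical.

Passing tests therefore demonstrate correctness of the generative
procedure under its stated assumptions — not that the simulated data
reproduce every property of real sequencing experiments.
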