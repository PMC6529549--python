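# Methods

## The decision model

`cultev` treats a cultivation attempt as a bet. An isolate of value `i`
(an abstract nonnegative currency amount — grant dollars are the usual
mental unit) is recovered with cultivation probability `cP`; the experiment
costs `e`. The risk-neutral expectation is

    EV = i·cP − e·(1 − cP)

Cost is stored as a positive magnitude and applied with a negative sign
inside the expectation, which avoids sign ambiguity in inputs and reports.
A project recovering `x` isolates across categories amortizes its cost so
each isolate carries the share `e/x`:

    EV_k       = i_k·cP_k − (e/x)·(1 − cP_k)
    EV_project = Σ_k EV_k = Σ i·cP − (e/x)·Σ(1 − cP)

Two consequences anchor the test suite: the amortized cost actually charged
is `e · mean(1 − cP) ∈ [0, e]`, so `Σ i·cP − e ≤ EV_project ≤ Σ i·cP`; and
with a single isolate the project formula reduces exactly to the
single-attempt formula.

Break-even solvers invert the expectation analytically:
`e* = i·cP/(1 − cP)` for one attempt and `e* = x·Σ(i·cP)/Σ(1 − cP)` for a
project; `i* = e·(1 − cP)/cP` inverts for value. `cP = 1` (no break-even
cost exists; expectation is positive at any cost) and `cP = 0` (no finite
value helps) raise a dedicated `UnboundedBreakEvenError` rather than
returning infinities, so tables stay finite. A project of zero isolates has
an *undefined* expectation (the amortization divides by `x`); it raises
`EmptyProjectError` and is never reported as 0.

Reporting helpers mirror how such figures are quoted in practice:
single-experiment break-evens round to the nearest $100 (half away from
zero), and project break-evens report the largest whole-thousand cost
strictly below `e*` — valid because EV is strictly decreasing in `e`
whenever not all `cP = 1`. The sign classifier is strict at zero: an
expectation of exactly 0 is "non-positive", since the point of the exercise
is to *maintain a positive* expectation. Raw unrounded values are always
available alongside the rounded ones.

The model is deliberately risk-neutral: no utility curvature, discounting,
or portfolio covariance. Isolate values are opaque amounts; the toolkit
does no currency handling.

## Estimating cultivation probability

For each taxon, `cP` is the ratio of isolates actually recovered to the
occurrences expected in the wells:

    cP = n_isolates / expected_occurrences

Expected occurrences are a first-class input (they are estimates, not
integers). When derived from a design, two occupancy models are offered:

* **nominal** (default): `wells × abundance × cells_per_well`. This is the
  planning arithmetic practitioners use at the bench, and what every
  worked example in the package reproduces.
* **poisson**: `wells × (1 − exp(−cells_per_well × abundance))`, the
  expected number of wells containing ≥ 1 cell of the taxon when per-well
  cell counts are Poisson. Always ≤ nominal (since `1 − e^−x ≤ x`); it is
  the right correction when double-occupancy matters.

Raw ratios can exceed 1 when a taxon's abundance (hence its expected
occurrences) is underestimated; estimates are clamped to 1 with an explicit
`clamped` flag, never silently. Multi-experiment campaigns pool by summing
isolate counts and expected occurrences per taxon (`pool_records`) before
estimating, which weights each experiment by its expected occurrences.

Uncertainty is a Wilson score interval treating `n_isolates` as binomial
successes out of `round(expected_occurrences)` trials (computed via
statsmodels and intersected with [0, 1]). The rounding is a pragmatic
concession — the "trial count" is itself an estimate — and the interval
degenerates (raises) when the rounded denominator falls below the success
count. Endpoints are snapped to exactly 0/1 when the data sit on the
boundary.

## Planning

* `expected_isolates` = expected occurrences × cP.
* `wells_needed` inverts it: the smallest integer well count whose expected
  yield reaches the target (closed form `ceil(target/(a·λ·cP))` in nominal
  mode, with an explicit boundary check against float edge cases).
* `experiments_needed` makes the informal "run several experiments to hedge"
  advice quantitative: total isolate count across `k` experiments is modeled
  as Poisson with mean `k·μ`, and the rule returns the smallest `k` with
  `1 − exp(−k·μ) ≥ success_prob` (default 0.99). At μ = 1.46 this gives
  k = 4, consistent with the informal 5–10 once operational slack is added.
* `design_feasibility` converts a design into a project scenario by rounding
  each taxon's expected yield to the nearest integer (taxa rounding to zero
  are excluded and reported), then evaluates the amortized project EV at the
  stated budget. A `fractional=True` flag instead feeds the unrounded
  expected counts directly into the EV sums, which avoids the exclusion
  cliff for rare taxa.

## Portfolio scenarios

`scenario_sim` sweeps isolate-count combinations over a grid of
(value, cP) categories at fixed project cost and classifies each
combination's expectation sign. The default grid is nine categories — the
3×3 cross of values {10⁴, 5×10⁵, 10⁷} and probabilities
{0.282, 0.0146, 0.001} — with cost $100,000 and count levels {0, 1, 10, 100}
(262,144 combinations, within the 10⁶ exhaustive cap; larger level sets
route to seeded uniform sampling). Only two of those defaults are canonical
anchors: the highest-value category is a $10M isolate at cP 0.1%, and the
cost is $100,000. The other categories reuse the package's exemplar values
and probabilities and are fully configurable; conclusions drawn from the
default grid should be treated as illustrative, not as reproducing any
published figure. The low:high ratio axis defaults to minimum-value vs
maximum-value tiers. Zero-isolate combinations are emitted flagged
`undefined` (consistent with the empty-project rule) rather than dropped, so
`L^k` enumeration counts stay exact.

## The campaign simulator

`dte_sim.simulate_experiment` draws, per well, a cell count (always 1 under
`exact_one` loading; Poisson with mean `cells_per_well` under `poisson`),
assigns each cell a taxon independently by relative abundance, and runs one
Bernoulli growth trial per *distinct* taxon per well with that taxon's cP.
Community mass not covered by the profile is an inert "other" taxon with
cP = 0, keeping the multinomial well-defined. Two outcome modes:

* **simple** (default): every successful growth trial is an isolate. This
  matches the bookkeeping behind cP estimation, which ignores well purity.
* **axenic**: a well yields an isolate only when exactly one taxon's trial
  succeeds there — a purity requirement that depresses realized yields under
  Poisson loading (the two modes coincide under exact-one loading).

Campaigns derive per-experiment seeds deterministically from the master seed
via `numpy.random.SeedSequence(master, spawn_key=(index,))`; identical seeds
give identical outcomes within a numpy version, but cross-version stream
stability is not guaranteed, so statistical tests use Monte-Carlo
tolerances (3 standard errors), never byte-golden streams. Cells within a
well are drawn independently (no finite-pool correction), which is accurate
at the dilution depths modeled.

The fixture generator draws community profiles from a symmetric Dirichlet
(default concentration 0.5, giving the steep rank-abundance curves typical
of aquatic communities) and assigns cultivation probabilities log-uniform on
[0.001, 0.6], spanning the observed range from long-shot to
selective-enrichment-grade taxa. What the synthetic data do **not** emulate:
taxonomic structure, abundance estimation error in the amplicon profile,
media- or condition-dependent cP, dormancy dynamics, temporal variation, or
cross-well contamination. Passing recovery tests therefore show the
estimator is consistent *under the generating model* — isolates per expected
occurrence with known abundances — not that field cP estimates are unbiased
when abundances are themselves noisy.

`recovery_check` runs replicate simple-mode campaigns at a known generating
cP, estimates cP from each with nominal expected occurrences, and flags
recovery when the mean estimate is within 3 Monte-Carlo standard errors of
the truth. The default validation scale is 200 replicates of an 8,160-well
design (17 experiments × five 96-well plates), which runs in well under a
minute and keeps the standard error small relative to cP ≈ 0.0146.

## Numerical and interface choices

* TSV everywhere: UTF-8, tab-separated, required header, `#` comments, no
  quoting; currency as plain numbers. Reports carry `#` metadata lines
  (tool version, seed, run parameters) and render floats at 6 significant
  digits; writes are atomic (temp file + rename), so failures leave no
  partial outputs.
* All validation failures raise typed exceptions rooted at `CultevError`;
  the CLI maps them to a one-line stderr diagnostic and a nonzero exit.
* Tie-breaks: EV exactly 0 classifies non-positive; `round_to_hundred`
  rounds half away from zero; `largest_positive_thousand` steps down a full
  thousand when the break-even lands exactly on a multiple of 1,000.

## Known limitations

* cP is a black-box probability: no mechanistic model of dormancy,
  growth kinetics, media chemistry, or time-to-detection.
* Expected occurrences inherit whatever bias the abundance profile carries;
  the estimator reports the exact ratio of its inputs and does not model
  abundance uncertainty (the Wilson interval covers sampling noise in the
  isolate count only).
* The amortization rule charges every isolate the same cost share `e/x`
  regardless of category; no marginal-cost modeling.
* Planning is evaluate-only: no optimization over wells, media, or
  portfolio composition.
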