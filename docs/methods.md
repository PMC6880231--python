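# Methods

## Scoring model

One assessment block yields the attentional-bias index
`B = T1/n1 − T0/N0` (ms): the mean reaction time on trials whose probe
replaced the neutral image minus the mean on trials whose probe replaced
the substance image. `B > 0` indicates attention preferentially allocated
to substance cues. The decomposition into sums and counts (`T1, n1, T0,
N0`) is kept explicit in `AssessmentResult` so partial blocks and
exclusion counts stay auditable. `N0` and `n0` are treated as the same
symbol.

Baseline bias is classified **present iff `B > 0` strictly**; a score of
exactly zero is classified absent, because the presence criterion is "a
positive score" and zero is not positive.

Overall change compares the **latest observed** post-session score with
baseline: `magnitude = |B_last − B_baseline|` with a direction flag
(increased / decreased / unchanged). Interior missing sessions are skipped,
not imputed; a participant with no observed post-session raises rather than
returning a silent NaN. All arithmetic is at full double precision;
rounding to one decimal happens only in the report layer.

### Trial exclusions

Dot-probe pipelines conventionally drop anticipations, lapses and error
trials before averaging. `FilterConfig` defaults to the common window
200–2000 ms with error trials dropped, but the source protocol this package
reproduces states no exclusion rules, so the filter is fully configurable
and `FilterConfig.none()` reproduces unfiltered scoring exactly. The
defaults are a practice choice, not a claim about the original analysis
(the packaged session-score fixtures are already-scored values, so the
filter never touches them).

## Session schedule and missingness

The emulated protocol runs on weekdays: day 1 is assessment → intervention
→ assessment, each later day is intervention → assessment (rest intervals
between blocks are protocol metadata and do not affect RTs). Day 1's second
assessment is "post session 1"; the post-assessment of day *d* fills
timeline slot *d*. The default schedule plans **5 days**, giving one
baseline plus five post-session scores — the layout of the reference
session table, whose completer rows have exactly six scores and whose
holiday-affected participants cap at four post sessions when one day is
lost. Missing slots carry a reason code (`dropout`, `holiday`,
`technical`, or `none` when unexplained); slots after a dropout day are all
dropout-missing. Dropout granularity is the day: the one reference
participant who withdrew mid-day-1 (baseline only) is representable in
timelines and fixtures but is not generated by the simulator.

## Synthetic cohort generator

The generator defines the conditions every downstream test runs under.

* **RT model** — ex-Gaussian: `RT = Normal(μ, σ) + Exponential(τ)`, the
  standard response-time family (mean `μ + τ`). Per-participant parameters
  are drawn around μ = 450 ms (SD 50), σ = 40 ms (SD 10), τ = 60 ms
  (SD 15), typical of speeded two-choice probe localisation. RTs are
  floored at 0.5 ms (the floor is effectively never hit at these
  parameters).
* **Bias injection** — the current bias `b` enters as `+b/2` on
  neutral-probe trials and `−b/2` on substance-probe trials, so the
  condition-mean difference equals `b` exactly and the scored index is an
  unbiased estimator of the simulated truth. The symmetric split keeps the
  overall mean RT independent of `b`.
* **Mixture of biased and unbiased participants** — with weight 16/30 a
  participant has `true_bias_ms = 0`; otherwise a strictly positive bias
  `|Normal(60, 70)|` ms, a right-skewed positive distribution matching the
  wide spread of observed positive baselines (units of a few ms up to a few
  hundred ms).
* **Training dynamics** — a per-profile decrement `Normal(25, 10)` ms is
  subtracted from `b` after every completed intervention block (linear
  decay, chosen so the expected post-session trajectory has the closed form
  `b0 − k·d` and can serve as its own oracle). Negative draws — training
  that backfires — occur naturally, as they did for a minority of real
  completers. An optional floor caps the decay; by default there is none.
  Whether real bias decay is per-session or per-trial is not identifiable
  from session-level scores; only the per-session form is implemented.
* **Errors** — each trial is incorrect with a per-participant lapse
  probability drawn uniformly from 1–8 %, independent of condition (so
  dropping error trials cannot bias the index).
* **Dropout** — a fixed per-day hazard of 0.108 after each completed day,
  calibrated so the completion probability over a 5-day schedule,
  `(1 − h)⁴`, is ≈ 19/30 (about 11 of 30 participants fail to complete).
* **Demographics** — categorical fields are drawn independently per factor
  from the reference cohort's marginal counts (substance category,
  nationality, gender, race, education, employment, housing, psychiatric
  and physical disorder flags); age is `Normal(46, 11.6)` clamped to the
  21–65 eligibility window; the dependence-severity score is
  `Normal(10.6, 3.3)` clamped to 0–15. Craving visual-analogue ratings
  (0–100, slow downward drift across days) are generated alongside each
  session but never analysed.
* **Seeding** — every stream derives from one integer seed through
  `SeedSequence(seed, spawn_key=(participant, purpose))`, so participant
  *i*'s profile and trial noise are identical for any cohort size ≥ *i*+1
  and two runs with the same config are byte-identical.

### What the generator does *not* emulate

Image content and cue salience, within-block RT autocorrelation and
fatigue, condition-dependent error rates, per-trial (rather than
per-session) training effects, and any correlation structure among
demographic factors. Passing tests therefore show that the pipeline scores,
classifies and summarises correctly under a clean additive-bias RT model —
not that real dot-probe data satisfy that model.

### Classification noise at realistic block sizes

With 40-trial assessment blocks the index has a sampling SD of roughly
`sqrt(4(σ² + τ²)/n)` ≈ 23 ms. A participant whose true bias is exactly zero
is classified positive or absent by a fair coin at *any* block size —
strict-sign classification cannot converge to the generating mixture
weight, and the apparent absent fraction in a default cohort sits near
(mixture weight)/2 plus a small contribution from low-bias participants
falling below zero. The honest statement about zero-bias participants is a
type-I-error one — `|B| > 1.96·SE` occurs at the binomial 5 % rate — and
that is what the test suite asserts. The same arithmetic applies to real
cohorts classified by the sign of a noisy index, which is worth bearing in
mind when interpreting observed "absent bias" fractions.

## Chi-square battery

Group comparisons use the uncorrected Pearson statistic on observed counts,
`E` from margin products, `df = (R−1)(C−1)`, and an upper-tail p computed
as the regularized upper incomplete gamma `Q(df/2, x/2)`. The published
battery this package reproduces was computed without a continuity
correction — only the uncorrected statistic reproduces its printed values —
so Yates correction exists behind a flag and is off by default. Zero-count
levels are retained (a level empty in one group still shapes the table and
its df). Expected counts below 5 emit `SmallExpectedCountWarning` but do
not abort: cohorts of 30 produce sparse tables, and the reference analysis
itself ran on them. p-values are reported at two decimals in the journal
style by the report layer; full precision is kept internally.

Three of the nine published statistics (substances, race, physical
diagnosis) do not reproduce from the published demographic counts under
any standard chi-square variant — the race column in the source table does
not even sum to its group size — and the packaged battery table marks them
`reproducible = 0`. They are reported in the reproduction output as
documented discrepancies; the implementation is not tuned toward them.

## Packaged reference fixtures

The four reference tables are shipped as plain CSV with SHA-256 checksums
verified at load. Transcription choices: en-dash minus signs normalised to
ASCII; participant ids preserved as printed (they skip 025); footnote
letters kept verbatim; the participant whose mid-study sessions were lost
to a technical fault carries `technical` reason codes on those slots.
Recomputing the overall-change column from the (1-decimal) session scores
reproduces the printed magnitudes exactly for 25 of 29 evaluable rows and
within 0.1 ms for the remaining four — the published changes were computed
before rounding — with all 29 direction flags exact. The published results
text gives the change range as "12.0 to 409.5" ms while the table's maximum
is 409.4; the fixture carries the table value. One participant has no
post-session score and therefore no defined change.

## Numerical and edge-case policy

* Bias index undefined (a condition with zero trials after filtering) →
  `DegenerateBlockError`, not NaN.
* Change undefined (no observed post-session) → `NoPostSessionError`.
* All-zero row or column in a contingency table → `ValueError` (df
  undefined); zero *cells* are fine.
* SD of a single-participant group is reported as undefined (`None`),
  never 0.
* Oracle tolerances in tests: 1e-9 (absolute) for mean-difference and
  chi-square statistic equivalences, 1e-8 for the upper-tail p against
  numerical quadrature.
* Problem sizes used by the validation suite: 100 seeded streams × 5 000
  trials per condition for bias recovery; 200 streams × 200 trials per
  condition for the type-I rate; 5 000-trial blocks for the linear-decay
  trajectory.

## Known limitations

Scoring assumes one baseline block per participant and at most one
post-assessment per day. The simulator draws demographics independently per
factor, so it cannot generate correlated confounding. The chi-square layer
offers no exact test, effect sizes or multiplicity correction, matching the
analysis it reproduces; for sparse 2×2 tables a Fisher exact test from a
general statistics package may be preferable in new analyses.
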