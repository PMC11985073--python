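# Methods

This note records the statistical conventions, model assumptions, and
parameter choices frozen into `ethofeed`, in enough detail to reimplement the
analyses without reading the source.

## Event model and sequence grammar

An **observation** is one prey offer to one animal. Events are annotated as
`(step, onset_s, offset_s)` with time measured in seconds from prey contact.
The canonical order is contact < paralyze < tcr < bend < ingest, and an
observation must satisfy a strict-prefix-with-skips grammar:

- `contact` is present exactly once, at onset 0;
- each step appears at most once;
- step onsets are ordered by canonical rank (a later-ranked step never starts
  before an earlier-ranked one);
- steps may be missing; whatever is present must be consistent with the
  ordering.

`paralyze` is annotated as a single time point — the moment paralysis is
complete — so its onset equals its completion and it carries no offset. The
contact→paralyze latency therefore *is* the paralyze duration. Steps with
visible extent (tcr, bend, ingest) carry onset and offset; the step's
**duration** is offset − onset.

**Timing references.** Each step's latency is measured from its own
reference: contact for paralyze, and the *offset* of the immediately
preceding executed step for tcr, bend and ingest (the inter-step interval,
ISI). Each latency is scored within a 120 s window from its own reference,
not from contact; this per-step reading is a deliberate design choice — the
relevant question at each stage is "given the previous step finished, how
long until the next one starts?". A step absent or outside its window yields
one right-censored record at 120 s; steps after the first missing step have
no timing reference and produce no record at all.

## Sequence statistics

**Transition tables.** For a given "from" step, the outcome of each
qualifying observation (one that executed the from-step) is the next
canonical step it executed, or `none`. Skip-ahead outcomes keep their own
columns rather than being folded into the immediate successor. Rows are
multinomial and normalize to 1. Two conditions are compared on the 2×2
collapse (canonical-next vs everything else) with Fisher's exact test,
Bonferroni-adjusted over the four from-steps.

**Agreement probability.** For a tentacle-side step s ∈ {paralyze, tcr,
bend}, agreement with ingestion is (both executed + both absent)/n; a
censored step counts as absent. This measures how predictive the early steps
are of feeding success.

**Consumption.** Prey consumed per animal over its offers (ingest executed),
summarized as mean ± SEM across animals and compared with Mann–Whitney.

## Censored latency analysis

Kaplan–Meier product-limit curves are fitted per step and condition
(via `lifelines`) and reported as the cumulative fraction 1 − S(t) of
observations that have executed the step by t. Conventions:

- **T25/T50/T75** are the first event times at which the cumulative fraction
  reaches 0.25/0.50/0.75 — a step-function crossing with no interpolation.
  A curve that plateaus below the target leaves the percentile *not reached*
  (`None`), and any fold change built on it is reported as undefined with a
  reason rather than a number.
- **Fold change** between conditions is the ratio of T50 crossing times.
  Note this is a quantile of the *marginal* curve: if condition A executes
  the step in only 65% of trials, its 50% crossing sits at the 77th
  percentile of the conditional latency distribution, so the T50 fold can
  legitimately exceed the latency-median ratio. The package preserves this
  rather than rescaling, because it is what the estimator measures on real
  censored data.
- Groups are compared with the **log-rank (Mantel–Cox)** test (two-group,
  1 df; k-group with k − 1 df for the time course).
- Without censoring the KM percentiles reduce exactly to empirical-CDF order
  statistics; the test suite asserts this equivalence.

## Test battery

- **Fisher's exact test** (2×2 only): two-sided p by the probability-mass
  rule — the sum of hypergeometric probabilities of all tables with the
  observed margins whose probability does not exceed that of the observed
  table (with a 1 + 1e-10 relative slack against floating-point ties). This
  matches exhaustive enumeration; the suite verifies it for every 2×2 table
  with grand total ≤ 40.
- **Chi-square** (r×c): Pearson statistic *without* Yates continuity
  correction; a warning (not an error) is emitted when any expected count is
  below 5, and zero margins are an error.
- **Mann–Whitney U**: exact p when min(n) ≤ 8 and there are no ties,
  otherwise normal approximation with tie correction and continuity
  correction. Passing a censored sample is an error — censored comparisons
  belong to the log-rank test.
- **Kruskal–Wallis + Dunn's post test**: scipy's tie-corrected H; Dunn z
  uses the pooled-rank variance N(N+1)/12 − Σ(t³−t)/(12(N−1)). Pair
  convention: `pairs="all"` (all k(k−1)/2 pairs) or `pairs="vs-first"`
  (each group against the first, the control) — the time-course analysis
  uses `vs-first` with the starved arm first. Adjusted p is Bonferroni over
  the pairs actually tested, min(1, p·m).
- **Bonferroni** family sizes are explicit arguments, never inferred.

## Synthetic-data generator

The generator is a semi-Markov chain over the canonical steps: step k is
attempted only if step k − 1 executed; it succeeds with probability πₖ; its
latency from its timing reference is log-normal with median mₖ (s) and
log-scale σₖ; executed tcr/bend/ingest additionally receive a log-normal
duration. Latencies exceeding the 120 s window censor the step, so censoring
has both an explicit (1 − πₖ) and an emergent (slow draw) component. All
draws are independent across steps and observations; each animal gets its own
`numpy` bit-stream via `SeedSequence(seed).spawn`, making datasets
byte-identical for identical (config, seed).

**Assumptions (what the generator does and does not emulate).** It emulates
per-offer step execution frequencies, latency medians and their
satiety-dependence, satiety-invariant durations, and study-scale sample
sizes. It does *not* model within-animal correlation beyond the shared
stream, learning or fatigue across offers, prey heterogeneity, or latency
dependence between steps (independence is asserted empirically in the test
suite, |ρ| < 0.05 at n = 10,000).

**Latency family.** Log-normal is the default because step latencies are
positive, right-skewed, and naturally parameterized by a median (the quantity
the analyses estimate); σ acts multiplicatively so medians are
family-independent. `exponential` and `gamma` (shape 2) alternatives are
provided, median-matched, to check that conclusions are not family-specific.

**Core presets** (full library in `ethofeed.synthetic_data.PRESETS`; all use
a 120 s window and 5 offers per animal unless noted):

| parameter | paralyze | tcr | bend | ingest |
|---|---|---|---|---|
| π (starved) | 0.92 | 0.96 | 0.97 | 0.97 |
| π (fed) | 0.80 | 0.65 | 0.75 | 0.60 |
| median m, s (starved) | 4 | 2 | 3 | 5 |
| median m, s (fed) | 8 (×2) | 10 (×5) | 7.5 | 12.5 |
| latency σ (log scale) | 0.5 | 0.5 | 0.6 | 0.6 |
| duration median, s (both) | — | 2.5 | 4 | 30 |
| duration σ (both) | — | 0.4 | 0.4 | 0.5 |

`starved` has 19 animals, `fed` 18. The satiety effect is thus a joint drop
in execution probabilities and a step-specific slowdown concentrated on the
TCR, with durations untouched. The post-meal time-course presets
(`tc_starved`, `fed_tc_{5,10,30,60}`; single-offer arms of 87/62/74/67/64
observations) inhibit the TCR (median 2 → 10 s, π 0.95 → 0.72–0.80) from
5 min onward while paralyze parameters stay at starved values until 60 min
(median 4 → 8 s, π 0.92 → 0.80): rapid TCR inhibition, late paralysis
inhibition. Additional presets cover used vs unused tentacles,
manubrium-removed animals (no ingestion possible), and tentacle preparations
severed above/below the bulb.

σ = 0.5 for paralyze/tcr was fixed at design time so that a study-scale
two-arm experiment (100 animals/arm, single offer) estimates a ×5 latency
median ratio with useful precision via the KM T50 fold; this was chosen
before the validation thresholds were frozen and has not been adjusted since.

## Validation design and numerical choices

- **Oracle equivalence**: Fisher vs exhaustive enumeration over every 2×2
  table with total ≤ 40, swept in canonical margin classes (row sum ≤ n/2,
  column sum ≤ row sum) with the row/column-swap and transpose invariances
  property-tested separately; exact Mann–Whitney vs full
  `itertools.combinations` permutation; KM vs hand product-limit tabulation
  and ECDF; log-rank vs a hand-tabulated two-group statistic (χ² = 49/17).
- **Null calibration**: 2000 replicates of identical starved arms,
  50 animals each, single offer; rejection rates at α = 0.05 must lie in
  [0.03, 0.07] for the asymptotic tests and at or below 0.05 for Fisher
  (exact tests are conservative by construction). The chi-square table is
  ingestion occurrence (expected counts ≈ 8–42, within Pearson validity);
  its exact analytic null rejection rate at these margins is 0.054.
- **Recovery**: 200 replicate pairs of 100-animal arms differing only in the
  TCR latency median (×5); the KM T50 fold must land in [4, 6] in ≥ 90% of
  replicates.
- **Dissociation**: 200 five-arm time-course replicates; Dunn vs-first must
  flag TCR at 5 min and paralyze at 60 min but not earlier, jointly in
  ≥ 80% of replicates.

Replicate counts balance Monte-Carlo standard error against runtime: 2000
null replicates give SE ≈ 0.005 on a 0.05 rate; 200 replicates give
SE ≈ 0.02–0.03 on rates near 0.9. All simulation seeds derive from a single
root via `numpy.random.SeedSequence` and are reduced mod 2³¹ so they remain
valid explicit seeds everywhere. Pipeline outputs are written with sorted
JSON keys and deterministic row order so identical (inputs, seed) reruns are
byte-identical; figures use the Agg backend.
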