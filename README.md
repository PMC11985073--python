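# ethofeed

Quantitative ethology of the jellyfish feeding sequence: sequence-grammar
parsing of annotated behavioral events, censored time-to-event statistics for
step latencies, a nonparametric test battery, a calibrated synthetic-data
generator, and a command-line reporting pipeline.

## Scientific problem

Feeding in the hydrozoan jellyfish *Cladonema pacificum* unfolds as a
stereotyped sequence of discrete steps. After a prey item contacts a tentacle
(time zero), the animal executes, in strict order:

1. **contact** — prey touches the tentacle (defines t = 0),
2. **paralyze** — nematocyst discharge immobilizes the prey (annotated as the
   time point at which paralysis is complete; the contact→paralyze latency is
   the "paralyze duration"),
3. **tcr** — the tentacle contraction reflex shortens the tentacle toward the
   bell margin,
4. **bend** — the bell margin bends to bring the tentacle tip to the mouth,
5. **ingest** — the manubrium grasps and ingests the prey.

A trial may stop after any prefix of this sequence (the prey is dropped, the
reflex is not triggered, …), and each step is scored within a 120 s
observation window measured from that step's own timing reference: from
contact for paralyze, and from the preceding step's offset for every later
step (the inter-step interval, ISI). A step not executed within its window is
**right-censored** at 120 s.

The scientific question is how satiety reshapes this sequence. Fed animals
execute fewer steps per offer and are slower at the steps they do execute, and
the slowdown is step-specific and follows a distinct time course after a meal:
the tentacle contraction reflex is inhibited within minutes, while prey
paralysis is only affected an hour later. Quantifying this requires
first-order transition probabilities between steps, Kaplan–Meier latency
curves that respect censoring, and a battery of exact nonparametric tests —
which is what this package provides, together with a generative model whose
parameters emulate those study conditions so every statistical procedure can
be validated against a known ground truth.

## Model

For each prey offer the generator draws the sequence step by step. Step $k$
(in canonical order) is attempted only if step $k-1$ was executed; it succeeds
with probability $\pi_k$ and, if successful, its latency from its timing
reference is drawn from a log-normal distribution
$T_k \sim \mathrm{LogNormal}(\log m_k, \sigma_k)$ with median $m_k$ (seconds).
A latency exceeding the 120 s window is recorded as censored, so censoring is
both explicit (failure with probability $1-\pi_k$) and emergent (slow draw).
Steps with a visible extent (tcr, bend, ingest) also receive a log-normal
duration; durations are satiety-**invariant** in every preset. The `fed`
preset lowers each $\pi_k$ and multiplies latency medians (paralyze ×2, TCR
×5) relative to `starved`; the post-meal time-course presets inhibit the TCR
from 5 min after a meal but paralysis only at 60 min. Analyses never see the
generator's parameters — they must recover them from the event tables.

## Worked example

Simulate the two satiety conditions at study scale (19 starved and 18 fed
animals, 5 prey offers each) and compare them:

```python
import ethofeed as ef
from ethofeed import FeedingStep as FS
from ethofeed.latency_stats import LatencySample

starved, truth = ef.simulate_dataset("starved", seed=7)   # 95 observations
fed, _ = ef.simulate_dataset("fed", seed=8)               # 90 observations

# First-order transitions out of "paralyze" (rows sum to 1)
qual_s = [o for o in starved if o.has_step(FS.PARALYZE)]
qual_f = [o for o in fed if o.has_step(FS.PARALYZE)]
t_s = ef.transition_matrix(qual_s, FS.PARALYZE)
t_f = ef.transition_matrix(qual_f, FS.PARALYZE)
print(t_s.probability_for("tcr"), t_s.n)   # 0.9767441860465116 86
print(t_f.probability_for("tcr"), t_f.n)   # 0.625 72
print(ef.fisher_exact_2x2(t_s.two_by_two(t_f)).p)  # 5.839447820487889e-09

# Censored TCR inter-step intervals: Kaplan-Meier T50 and fold change
def tcr_sample(obs):
    recs = [r for o in obs if o.has_step(FS.PARALYZE)
            for r in ef.extract_timings(o)]
    return LatencySample.from_timings(recs, FS.TCR)

s, f = tcr_sample(starved), tcr_sample(fed)
print(ef.km_curve(s).percentile_times[50])  # 2.0013362935871286
print(ef.km_curve(f).percentile_times[50])  # 13.669147335422473
print(ef.t50_fold_change(f, s).ratio)       # 6.830010218283879
lr = ef.logrank_test(s, f)
print(lr.chi_square, lr.p_two_sided)  # 133.21642078737236 8.107405934840486e-31

# Prey consumed per 5 offers (mean ± SEM across animals)
print(ef.consumption_summary(ef.consumption_counts(starved)))
# {'n_subjects': 19, 'mean': 4.2631578947368425, 'sem': 0.16827479029167436}
print(ef.consumption_summary(ef.consumption_counts(fed)))
# {'n_subjects': 18, 'mean': 1.1111111111111112, 'sem': 0.19618733359220436}
```

The fed/starved T50 fold of ~6.8 is larger than the generator's ×5 latency
median ratio: with only 65% of fed animals executing the TCR at all, the
Kaplan–Meier curve's 50% crossing sits at a higher conditional quantile, a
real property of censored medians that the analysis deliberately preserves.

The same analysis from the command line:

```bash
ethofeed simulate --preset starved --seed 7 --out scratch/demo/starved.csv
# wrote 95 observations to scratch/demo/starved.csv
ethofeed validate --input scratch/demo/starved.csv
# {"n_observations": 95, "n_rows": 430, "rejected_observations": [], "rejected_rows": []}
ethofeed analyze --preset starved --preset fed --contrast starved,fed \
    --seed 7 --out scratch/demo/bundle
# bundle written to scratch/demo/bundle (19 tests)
```

The bundle contains `transitions.csv`, `km_curves.csv`, `percentiles.csv`,
`agreement.json`, `consumption.json`, `tests.json` (each test with raw and
Bonferroni-adjusted p), `fold_changes.json`, `run_log.json`, plus
transition-heatmap and Kaplan–Meier figures. In this run the fold changes are
paralyze 2.04, tcr 4.80, bend 3.10, ingest 3.83, and the paralyze→tcr
transition contrast has Fisher p = 0.00185 (adjusted 0.0074 over the
four-step family). `ethofeed analyze` also accepts real annotation CSVs via
`--input name=path`; `ethofeed report --bundle <dir>` re-renders figures from
a bundle without recomputation.

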