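# gviat

Scoring, reliability and validation toolkit for the **GV-IAT**, a
seven-block Implicit Association Test measuring implicit attitudes toward
intimate partner violence against women (IPVAW). The package is for
researchers who run latency-based implicit-attitude tasks and need the
full analysis pipeline — trial-level quality control, the standardized
D-score, internal consistency, stimulus-panel validity and the
implicit/explicit comparison — as reproducible, testable code rather than
spreadsheet arithmetic.

## What it computes

**D-score.** For each participant, using only the critical blocks B3, B4,
B6, B7 (trials above 10,000 ms trimmed; participants with >10% of trials
under 300 ms excluded):

```
D = ½ · [ (M_i1 − M_c1) / SD(B3 ∪ B6)  +  (M_i2 − M_c2) / SD(B4 ∪ B7) ]
```

where *M_c*, *M_i* are the compatible/incompatible block mean latencies
(which blocks are which follows the task version) and the SDs are sample
SDs pooled over each block pair. Positive D = slower when *Gender
violence* shares a key with *Good* = implicit rejection of IPVAW. Bands:
D < .20 null, .20 ≤ D < .50 mild, .50 ≤ D < .80 moderate, D ≥ .80 strong.
Both error-latency treatments are available: the built-in penalty
(latency runs to the correct response; default) and the block-mean +
600 ms replacement.

**Reliability & validity.** Split-half reliability of D (random
within-block halves, product–moment correlation across participants,
Spearman–Brown correction r′ = 2r/(1+r), averaged over 600 splits);
two-way random-effects absolute-agreement ICC for judge panels (single
and average forms); per-item Aiken's V = S/(n(c−1)) with exact null
significance.

**Group analysis.** Quartile segmentation of D, per-group summaries with
band-range labels, and classic one-way ANOVAs of explicit-scale scores
across the four implicit groups.

**Simulator.** Ex-Gaussian latency cohorts with a known per-participant
compatibility effect δᵢ, plus errors, fast guesses and lapses — so every
statistic above can be verified against ground truth.

## Worked example

```python
import gviat

task = gviat.load_task_spec()                     # packaged 240-trial task
cohort, truth = gviat.simulate_cohort(gviat.SimParams(n_participants=89, seed=7), task)
scores = gviat.score_cohort(cohort)
summary = gviat.cohort_summary(scores)
print("mean D: %.3f  sd: %.3f" % (scores["d"].mean(), scores["d"].std()))
print("band percentages:", summary["band_percentages"])

rel = gviat.split_half_reliability(cohort, n_splits=600, seed=7)
print(rel)

explicit = gviat.simulate_explicit_scores(truth, coupling=0.0, noise_sd=0.2,
                                          seed=7, scale_name="IBWB")
report = gviat.implicit_explicit_report(scores, explicit)
print(report.groups.summary[["group", "n", "d_mean", "band_range"]].to_string(index=False))
print("IBWB ANOVA:", report.anovas["IBWB"])
```

prints

```
mean D: 0.616  sd: 0.269
band percentages: {'null': 5.6, 'mild': 28.1, 'moderate': 39.3, 'strong': 27.0}
split-half reliability over 600 random splits: mean corrected r = 0.653 (sd 0.052, seed 7)
 group  n   d_mean      band_range
     1 22 0.262619       null-mild
     2 22 0.528020   mild-moderate
     3 22 0.710066 moderate-strong
     4 23 0.946756          strong
IBWB ANOVA: F(3, 85) = 0.991, p = 0.401
```

Read: the simulated cohort shows moderate implicit rejection on average
(mean D 0.616), most participants land in the moderate/strong bands, the
600-split corrected reliability is 0.65, and — because the explicit scores
were generated uncoupled from the latent effect — the four D-quartile
groups do not differ on the explicit scale (p = .401): the
implicit/explicit dissociation pattern.

The same pipeline runs from the shell:

```sh
gviat simulate --n 89 --seed 7 --out trials.csv --truth-out truth.csv
gviat score --input trials.csv --out scores.csv
gviat reliability --input trials.csv --n-splits 600 --seed 7
gviat validate-stimuli --ratings ratings.csv --out aiken.csv
gviat compare --scores scores.csv --explicit explicit.csv --out report.csv
```

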