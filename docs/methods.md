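# Methods

## The task and its data model

The GV-IAT is a seven-block forced-choice Implicit Association Test for
implicit attitudes toward intimate partner violence against women (IPVAW;
"gender violence" under Spanish law). Target categories are *Gender
violence* vs. *Non gender violence*; attribute categories are *Good* vs.
*Bad*; each category carries exactly six stimulus words. Blocks B1, B2 and
B5 are practice; B3–B4 and B6–B7 are the critical blocks, with per-block
trial counts (24, 24, 24, 48, 48, 24, 48) — 240 trials per participant.
Version 1 runs the compatible pairing (Gender violence + Bad) in B3–B4 and
the incompatible pairing in B6–B7; version 2 is the reverse. Because the
procedure is forced-choice with feedback, a trial's recorded latency runs
from target onset to the *correct* response, so error trials carry a
built-in time penalty.

The packaged default task ships the English stimulus translations. The
instrument itself is Spanish-language; Spanish or custom stimulus sets are
loadable as JSON task specifications — the word lists are configuration,
not code. Sessions with structural deviations (truncated blocks, unknown
words) load with a validation flag rather than failing, mirroring real lab
logs; scoring decides separately what is usable.

## D scoring

For each participant, after restricting to the critical blocks:

1. drop trials with latency > 10,000 ms (strictly greater; a trial at
   exactly 10,000 ms is retained);
2. exclude the participant if more than 10% (strictly) of the surviving
   critical trials are faster than 300 ms — these fast trials are *kept*
   in means and SDs for retained participants; they feed exclusion only;
3. apply the error-latency treatment (below);
4. compute, separately for the block pairs (B3, B6) and (B4, B7), the
   incompatible-minus-compatible mean difference divided by the sample SD
   (n − 1) of the two blocks' latencies pooled;
5. average the two quotients: D.

The exclusion denominator is the critical trials surviving the 10,000 ms
trim, because trimming precedes exclusion in the step order and the
analysis set is restricted to critical blocks from the start. Pooled SDs
are taken over *effective* (error-treated) latencies; under the default
built-in treatment these are the recorded latencies unchanged.

Positive D means slower responding when Gender violence shares a key with
Good — implicit rejection of IPVAW. Interpretation bands follow the
Cohen-style cuts, half-open with boundaries going up: D < .20 null,
.20 ≤ D < .50 mild, .50 ≤ D < .80 moderate, D ≥ .80 strong. Negative D is
classified null (absence of rejection): the bands grade rejection
intensity only.

Error treatments:

* **builtin** (default): latencies unchanged — the forced-choice log
  already accumulates the time to correct an error. This is the default
  because prior evidence for this instrument favors the built-in penalty.
* **penalty600**: each error latency is replaced by the mean of the
  correct-trial latencies of its block plus 600 ms. A block containing
  errors but no correct trial is unscoreable under this treatment and
  raises an error naming the block. On an all-correct session the two
  treatments agree exactly.

A deliberately naive step-literal implementation (plain lists, the
`statistics` module) lives in the test suite as an independent oracle; the
production path must agree with it to 1e-12 on randomized sessions with
both treatments.

## Split-half reliability

Within each scorable participant (exclusions applied first — reliability
concerns scorable measurements) and within each critical block, the
effective latencies are randomly partitioned into two near-equal halves;
with an odd trial count the extra trial joins a uniformly random half. D
is computed on each half exactly as in the full pipeline, the two half-D
vectors are correlated across participants (product–moment), and the
correlation is stepped up with the Spearman–Brown prophecy formula
r′ = 2r/(1 + r). The default repeats this over 600 random splits and
reports the mean corrected correlation; everything is reproducible from
one seed.

Splitting is stratified within block to preserve the block-pair structure
D depends on. Error treatment is applied to the full trimmed session
*before* halving, so block correct-means (penalty600) are estimated from
all trials rather than from a half. Splits that produce a degenerate
pooled SD are redrawn a bounded number of times, then reported as an
error. The implementation is vectorized over splits via per-block
sufficient statistics (mask-sums of latencies and their squares), making
600 splits on a 100-participant cohort a sub-second operation.

## Judge agreement and content validity

Stimulus-selection panels are items × judges integer matrices on a bounded
scale (1–7 by default).

* **ICC**, two-way random effects, absolute agreement, from the mean
  squares: ICC(A,1) = (MSR − MSE) / (MSR + (k − 1)MSE + k(MSC − MSE)/n)
  and the k-rater average form ICC(A,k) = (MSR − MSE)/(MSR + (MSC − MSE)/n).
  The average form is the reporting default, matching a pooled expert
  panel; both forms are exposed and labelled. Values ≥ .75 are flagged
  "excellent" per the usual convention. A matrix with no between-item
  variance has no defined ICC and raises an error.
* **Aiken's V** per item: V = S/(n(c − 1)) with S the summed distance of
  ratings from the scale floor; V ∈ [0, 1]. Significance uses the exact
  null distribution of S (each judge uniform over the c categories),
  computed by convolution whenever the support is modest and by a
  continuity-corrected normal approximation otherwise. Items with V below
  the user-supplied critical value (default .75, the conventional α = .01
  cut) are flagged for elimination; the critical value is a parameter, not
  a hard-coded table.

## The simulator

Latencies are ex-Gaussian — Normal(μ, σ) plus an independent
Exponential(τ) — the standard right-skewed reaction-time model; the right
tail is what the 10,000 ms trim acts on. Each participant draws a latent
compatibility effect δᵢ ~ Normal(effect_mean, effect_sd) in milliseconds,
added to every incompatible-phase latency. Errors occur independently per
trial and add an Exponential(error_recovery) correction time to the
latency, consistent with a log that runs to the correct response. Fast
guesses replace the latency with Uniform(150, 299) ms and lapses with
Uniform(10,001, 12,000) ms — placed to deterministically engage the
trimming and exclusion machinery. Version assignment alternates 1, 2, 1,
2, … with any fractional remainder randomized.

Defaults sketch a typical university cohort: μ = 600 ms, σ = 100 ms,
τ = 250 ms (mean 850 ms, SD ≈ 269 ms), effect_mean = 200 ms,
effect_sd = 80 ms, error rate 5% with 300 ms mean recovery, 1% fast
guesses, 0.2% lapses. With the 200 ms mean shift the expected cohort mean
D is ≈ 0.7 and the between-person spread of D ≈ 0.25, placing most
simulated participants in the mild-to-strong rejection bands — the regime
the instrument was designed to resolve.

A useful closed form anchors calibration: with a pure shift Δ, no
artefacts and no effect variance, E(D) ≈ Δ/√(σ² + τ² + Δ²/4), because the
pooled SD of two equal-size blocks whose means differ by Δ acquires a
between-block variance term Δ²/4. The simulator's mean D matches this
within Monte-Carlo error, and a 200-participant default-noise cohort
recovers the true δᵢ with correlation > 0.8.

What the simulator deliberately does not model: sequential effects
(practice, fatigue, block-order drift), stimulus-level variability,
speed–accuracy trade-offs, or any diffusion-style decision process.
Passing tests therefore demonstrate that the *scoring arithmetic and its
exclusion rules* behave as specified under realistic marginal
distributions — not that the instrument itself is valid for real
respondents.

Explicit-scale scores are generated on the instrument's 1–4 range (lower =
stronger rejection) as a clipped linear function of standardized δᵢ with
Gaussian noise; a coupling of 0 reproduces the implicit/explicit
dissociation pattern (explicit means flat near 1.55 across implicit
quartiles), a coupling of ±1 with no noise makes the explicit score a
monotone transform of δᵢ.

## Group analysis

Scored participants are cut at the empirical 25/50/75 percentiles of D
(linear interpolation between order statistics); assignment is d < Q1,
[Q1, Q2), [Q2, Q3), d ≥ Q3 — boundary values go to the upper group, a
convention the source description leaves open. With 89 distinct scores
this yields group sizes 22/22/22/23 (a rotation of the published
22/22/23/22). Each group is summarized by its D mean, SD, range and the
interpretation bands that range spans; explicit scales are summarized per
group with per-scale n (participants missing a scale are dropped for that
scale only) and compared across groups with the classic equal-variance
one-way ANOVA, F = MS_between/MS_within on (k − 1, N − k) degrees of
freedom. No Welch correction is applied by default, matching the reported
degrees of freedom convention of the instrument's validation analyses.

## Numerical and design notes

* All SDs are sample SDs (ddof = 1), including the pooled pair SDs.
* Strict inequalities throughout the screening rules: > 10,000 ms trims,
  > 10% excludes, < 300 ms counts as fast.
* Excluded participants keep a result row with the reason, rather than
  disappearing — cohort bookkeeping stays auditable.
* CSV interchange is fixed: UTF-8, comma, header, decimal point; floats
  round-trip exactly (`float_precision="round_trip"` on read).
* One seed drives each stochastic procedure (simulation, splitting);
  repeated runs are bit-identical.
* The acceptance script sizes its simulations at 89–200 participants and
  600 splits — large enough that Monte-Carlo error is small against the
  effects of interest, small enough to run comfortably on a laptop.

## Known limitations

* The headline field estimates of the original validation study (its
  split-half .73, judge ICC .999, Table-3 group means) depend on raw data
  not deposited; the package reproduces the *procedures* and verifies them
  on synthetic ground truth, not those specific sample values.
* Item-level scoring of the explicit instruments (IBWB, IPDMV) is out of
  scope; the pipeline consumes per-participant totals on the 1–4 scale.
* No alternative IAT scoring families (log-latency conventional effect,
  G-scores, process-decomposition models) are provided.
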