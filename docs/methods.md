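# Methods

## Stimulus model

Each trial is an ordered sequence of `n_stimuli` pure-tone values drawn
i.i.d. from a Gaussian with precision λ (inverse variance); the mean
shifts by a signed amount ±Δ exactly after index n/2. Values are stored
dimensionlessly — octaves relative to `base_frequency` (default 500 Hz)
for frequency experiments, dB relative to the listener-set
`reference_level` for intensity experiments — so every downstream
computation is carrier-independent. The printed precision values are
treated as the numeric inverse variance of these dimensionless values
(variance = 1/λ in oct² or dB²), the only reading consistent with
"inverse of variance".

Four presets span the design space:

| preset | varied | n | tone (s) | trial (s) | λ (low/med/high) | Δ (low/med/high) | direction task |
|--------|--------|---|----------|-----------|------------------|------------------|----------------|
| exp1   | frequency | 10 | 0.30 | 3.36 | 16 / 32 / 64 | 0.25 / 0.5 / 1 oct | no |
| exp2   | frequency | 10 | 0.30 | 3.36 | 16 / 32 / 64 | 0.25 / 0.5 / 1 oct | no |
| exp3   | frequency | 20 | 0.08 | 2.36 | 16 / 32 / 64 | 0.25 / 0.5 / 1 oct | yes |
| exp4   | intensity | 10 | 0.30 | 3.36 | 1/32 / 1/8 / 1/2 | 2.5 / 5 / 10 dB | yes |

The inter-stimulus interval is not printed anywhere, but the 3.36 s
trial length of a 10 × 0.3 s trial pins it at exactly 0.04 s, and the
same 0.04 s reproduces the 2.36 s trial of the 20 × 0.08 s preset; it
is therefore the shipped default for all presets. The fast-timescale
stimulus count is configurable (20 is the default because it is the
only count consistent with the printed 2.36 s trial length).

The pre-change mean μ₀ is roved per exemplar, uniform within ±0.5 oct
(frequency) or ±3 dB (intensity) of the experiment centre (0 oct /
−20 dB). Roving prevents absolute-value cues to the change while
leaving all within-trial statistics untouched; set `rove_range=0` for a
fixed μ₀. The intensity centre of −20 dB keeps typical draws well below
the amplitude ceiling; draws that would still reach 90% of the
reference amplitude are clipped at the cap and logged, preserving the
Gaussian metadata used by the analysis (re-drawing would bias the
stimulus distribution the observer model assumes).

Audio rendering is optional and purely diagnostic: one pure tone per
value (frequency: `base · 2^value`; intensity: amplitude
`reference · 10^(value/20)`), 5 ms raised-cosine on/off ramps
(configurable), silence during the gap, 16-bit PCM WAV output.

### Randomness

A single root seed fans out to named sub-streams. The stream of
exemplar *e* of a condition is keyed by `(seed, stream-tag,
precision-index, change-index, direction-index, e)`, so exemplars are
identical for every subject, bit-reproducible, and unaffected by adding
conditions or exemplars. Subject presentation orders and responder
noise use separately tagged streams.

## Ideal observer

The observer holds a conjugate Gaussian belief over the sequence mean
with the generative λ and the halfway change point known (both are
fixed properties of the paradigm; estimating them is out of scope).
Predictive surprise of an observation is −log of the prior predictive
density; under a flat prior (belief precision 0) the first
observation's surprise is defined as the attainable minimum, with a
warning. Bayesian surprise of the halfway update is KL(posterior ‖
prior) — the standard direction for Bayesian surprise; the reverse KL
is a documented alternative, not the default. For the trial-level
change estimate, the prior is the belief after the first half
(mean m₁, precision kλ) and the posterior additionally absorbs the
second half. Note the resulting KL has a floor of
½(½ − 1 + ln 2) ≈ 0.097 nats even when Δ̂ = 0, because the belief
sharpens regardless of whether the mean moves.

## Responder model

There is no participant model to adopt from behavioural reports alone,
so the simulator is the minimal construction that realises all three
canonical regimes and the direction bias: a linear latent salience

L = β_mc·m + β_prec·z(λ) + β_dir·1[up] + β_ext·x + ε,  ε ~ N(0, σ)

discretised by three ordered thresholds into the 1–4 rating (ties go to
the lower category). `m` is the change magnitude under the chosen
evidence source (true |Δ|, the observer's |Δ̂|, or an extreme-value
heuristic), `z(λ) ∈ {−1, 0, +1}` is the standardised precision level —
standardised so the frequency (λ 16–64) and intensity (λ 1/32–1/2)
presets share one parameterisation — and `x` is the max2−min1 extreme
metric. The direction choice is Bernoulli with
P(up) = logistic(slope·e + bias) on signed evidence `e`; a positive
bias yields the looming-type advantage for upward changes. Defaults:
β_mc = 1, β_dir = 0.25, β_ext = 0, σ = 1, thresholds (−0.5, 0.5, 1.5),
slope 3 — chosen so that a default cohort uses the full 1–4 range and
direction accuracy sits in the mid-0.8s, resembling a competent
listener; the regime presets set β_prec = +0.5 / 0 / −0.5 with σ = 1.
No lapse parameter by default (a uniform-lapse mixture is available),
and between-subject slope heterogeneity is off by default.

What the simulator deliberately does not emulate: sequential/order
effects within a session, learning or adaptation across trials,
reaction times, and any mechanistic account (stochastic resonance,
attention, neuronal adaptation) of *why* a regime might hold. Passing
recovery tests therefore show that the analysis pipeline can identify
the regimes from ordinal data at realistic cohort sizes — not that
human listeners follow this latent-linear model.

## Statistical pipeline

Per-subject condition summaries (mean rating, direction accuracy, per
18-cell design) feed a fully within-subject 3 × 3 × 2 ANOVA computed by
direct factorial decomposition: every effect's SS comes from its
marginal cell means, tested against the matching effect × subject
interaction. For every effect with ≥ 2 numerator df, Mauchly's W is
computed on the covariance of orthonormalised contrast scores; when its
chi-square p < .05 the degrees of freedom are scaled by the
Greenhouse–Geisser ε (trace²/(q·trace of the squared covariance),
clipped to [1/q, 1]) and the p-value recomputed. Huynh–Feldt ε is
reported for information only. Singular contrast covariances are
flagged and left uncorrected with a warning.

The post-hoc cascade mirrors standard practice for a significant
three-way interaction: two-way ANOVAs of each factor pair within every
level of the third factor; simple main effects for each significant
two-way model (collapsing any remaining factor to subject cell means);
and paired t-tests between precision levels wherever a precision main
effect (omnibus or simple) is significant. Each stage is
Bonferroni-adjusted by its own test count. All precision pairs are
tested; rows carry a `neighbouring` flag so reports can restrict to
adjacent levels.

Extreme-value analysis computes four per-trial metrics — the midpoint
jump (first tone of the second half minus last of the first, a
positional rule valid for any n), min2−max1, max2−min1, and total
range — and correlates the first three with exemplar group-mean
ratings across the 10 exemplars of each condition (54 Spearman
coefficients per experiment). The total range is computed but excluded
from the default report, as it adds nothing beyond the two cross-half
contrasts; pass `metrics=ALL_METRICS` to include it. With n = 10 the
permutation null is enumerated exactly (10! pairings of the rank
vectors, mid-rank ties, two-sided by |T − E[T]|); the large-sample
approximation is available as a fallback. Benjamini–Hochberg step-up
q-values are computed across the whole table.

### Pattern classification

The regime of a design slice (or of the whole design) is decided by two
orthogonal within-subject contrasts on the ordered precision levels:
linear (−1, 0, +1) and quadratic (+1, −2, +1), each tested against zero
with a one-sample t-test. The two contrasts form one decision family,
so each is tested at α/2 (Bonferroni): a significant positive linear
trend → `bayesian`, negative → `counter_bayesian`; otherwise a
significant quadratic (non-monotone) trend → `mixed`, else
`non_bayesian`. This keeps the probability of mislabelling a truly flat
pattern near α rather than 2α. Degenerate zero-variance contrasts are
resolved by consistency (identical non-zero trends count as perfect
evidence). The rule, and α = 0.05, are explicit arguments.

### Validation strategy

Correctness is established against independent oracles rather than by
self-consistency: ANOVA F values against a contrast-projection
implementation (and pingouin on sub-designs), Mauchly/ε against
pingouin, exact Spearman p against full enumeration and scipy's
exhaustive permutation test, BH against statsmodels and hand-computed
step-up, and the observer's closed forms against numerical quadrature.
The scientific acceptance surface is parameter recovery: cohorts of 50
subjects simulated under β_prec = +0.5 / 0 / −0.5 (unit latent noise)
must be relabelled correctly in ≥ 90% of 100 replicates per regime —
the flat regime's ceiling is the classifier's false-positive profile
(~95% with the α/2 family rule). Type-I calibration of the ANOVA is
checked on 1000 null cohorts of 20 subjects (each effect's rejection
rate within 0.05 ± 0.02).

Problem sizes used by the test-suite simulations — 10⁴ draws for
moment checks, 1000–2000 replicates for calibration, 100 replicates
per regime for recovery — were chosen so Monte-Carlo error is several
times smaller than each tolerance.

## Known limitations

- The responder model is linear-latent with homogeneous thresholds; it
  cannot express criterion drift, response sets, or subject-specific
  threshold spacing.
- The observer assumes known λ and change point; volatility or
  change-point uncertainty would need a different (sequential) model.
- The Huynh–Feldt ε for interaction effects uses the single-factor
  formula with the interaction's df, which is approximate (it is
  reported, never applied).
- The cascade's branch bookkeeping follows one defensible reading of
  hierarchical post-hoc practice; other labs nest the simple effects
  differently. All branch decisions are recorded in the output table,
  so any alternative adjustment can be recomputed from it.
- Human data can be ingested through the same response-table schema,
  but nothing here validates against human results; conclusions from
  synthetic cohorts transfer only to the extent the latent-linear
  responder resembles real listeners.
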