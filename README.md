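# tonechange

Tools for studying how the **precision** (inverse variance, λ) of an
auditory stimulus stream shapes the **perceived salience of a change
(PSC)** in its underlying mean. The package generates Gaussian
tone-sequence experiments, provides a closed-form Gaussian ideal
observer, simulates ordinal-rating cohorts under competing perceptual
strategies, and runs the complete repeated-measures analysis pipeline —
validated end-to-end by parameter recovery on synthetic cohorts.

## The paradigm

A trial is a sequence of *n* pure tones whose values (octaves re a base
frequency, or dB re a reference level) are drawn i.i.d. from
Normal(μ₀, 1/λ). Exactly halfway, the mean shifts to μ₀ ± Δ while λ
stays fixed. The design crosses 3 precision levels × 3 mean-change
magnitudes × 2 directions = 18 conditions × 10 fixed exemplars = 180
trials; listeners rate each change on a 1–4 Likert scale and (in some
presets) report its direction. Four shipped presets cover the varied
parameter (frequency vs intensity), timescale (10 × 0.3 s vs 20 ×
0.08 s tones) and prompt wording.

Under signal-to-noise (Bayes-optimal) reasoning, higher λ should make
an equal-sized Δ more salient. The pipeline distinguishes three
canonical precision–PSC regimes — **Bayesian** (PSC rises with λ),
**non-Bayesian** (flat), and **counter-Bayesian** (PSC *falls* with λ)
— via a within-subject trend test on the ordered precision levels.

## Core quantities

For a Gaussian belief over the sequence mean with precision π, updated
by an observation of precision λ:

- conjugate update: π′ = π + λ, μ′ = (πμ + λx)/π′
- predictive surprise: −log N(x; μ, 1/π + 1/λ)
- Bayesian surprise of the halfway update: KL(posterior ‖ prior) for
  Gaussians, which reduces to λΔ²/2 in the equal-variance case
- change estimate: Δ̂ = mean(2nd half) − mean(1st half), with standard
  error √(2/(kλ)) for k tones per half and P(up) = Φ(Δ̂ / SE)

The analysis stage implements a fully within-subject 3 × 3 × 2 ANOVA
(factorial sum-of-squares decomposition, each effect tested against its
effect × subject interaction), Mauchly's sphericity test with
Greenhouse–Geisser corrected degrees of freedom, a Bonferroni-adjusted
post-hoc cascade, Spearman correlations between per-trial extreme-value
metrics and exemplar group means (exact n! permutation p-values), and
Benjamini–Hochberg FDR over the 54-cell correlation table.

## Worked example

```python
import tonechange as tc

manifest = tc.run_end_to_end(
    "exp1", regime="counter_bayesian", n_subjects=30, seed=7,
    out_dir="demo", corr_method="asymptotic",
)
```

writes `trials.csv`, `responses.csv`, `metrics.csv`, `summaries.csv`,
`effects_psc.tsv`, `cascade.tsv`, `correlations.tsv`, `patterns.tsv`
and `manifest.json`. The effects table for that run:

```
                         effect        F  df_num_corr  df_den_corr  p_reported
                      precision 452.9853          2.0         58.0      0.0000
                    mean_change 311.0348          2.0         58.0      0.0000
                      direction  73.3207          1.0         29.0      0.0000
          precision:mean_change   3.7141          4.0        116.0      0.0070
            precision:direction   0.2288          2.0         58.0      0.7962
          mean_change:direction   1.1129          2.0         58.0      0.3355
precision:mean_change:direction   0.9393          4.0        116.0      0.4439
```

All three main effects are strong: ratings rise with Δ, differ by
direction, and — because this cohort was simulated under the
counter-Bayesian regime (negative precision slope) — the precision
effect is recovered with the *opposite* sign, as the pattern table
confirms for every slice:

```
                        slice_id            label  slope_statistic  evidence_p
                         overall counter_bayesian          -0.8167         0.0
    mean_change=low;direction=up counter_bayesian          -0.7233         0.0
  mean_change=low;direction=down counter_bayesian          -0.8767         0.0
```

`slope_statistic` is the mean within-subject PSC difference between the
high- and low-precision levels; a significantly negative value labels
the slice counter-Bayesian.

The same workflow is available from the shell:

```bash
tonechange generate --preset exp1 --seed 7 --out stimuli --audio
tonechange simulate --preset exp4 --regime counter_bayesian --subjects 70 --seed 11 --out responses.csv
tonechange analyze --responses responses.csv --trials stimuli/trials.csv --preset exp4 --out results/
tonechange recover --preset exp1 --replicates 100 --subjects 50 --seed 3 --out recovery.csv
```

## Layout

- `src/tonechange/config.py` — experiment configuration, presets
- `src/tonechange/paradigm.py` — conditions, sequences, orders, audio
- `src/tonechange/observer.py` — Gaussian ideal observer
- `src/tonechange/responders.py` — synthetic Likert/direction cohorts
- `src/tonechange/metrics.py` — extreme-value metrics, aggregates
- `src/tonechange/stats.py` — ANOVA, sphericity, cascade, Spearman, FDR,
  pattern classifier
- `src/tonechange/pipeline.py`, `cli.py` — end-to-end runs and CLI

See `docs/methods.md` for the modelling assumptions and numerical
choices.
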