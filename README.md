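# cciqeeg

Quantitative two-channel EEG analysis around a controlled cortical impact
(CCI), for electrophysiologists studying acute traumatic brain injury in
rat strains that differ in seizure-plasticity susceptibility (PPKS:
kindling-susceptible; PPKR: kindling-resistant; SD: outbred
Sprague-Dawley parent). The package provides the full analysis chain —
epoching around the impact mark, zero-phase 0.5–32 Hz bandpass filtering,
baseline-normalized binned power spectra, interhemispheric
magnitude-squared coherence, spectral entropy, kurtosis and line length,
binwise least-squares group statistics with LogWorth (−log10 p), and a
sparse integer risk score — plus a synthetic cohort generator with known
ground truth, so every stage is testable without animal recordings.

## The core quantities

For each subject, five 60 s epochs (baseline ending 0.5 min before the
impact; post-injury epochs beginning 0.5, 5, 10 and 15 min after it) are
reduced to spectra on a 64-bin grid (0.5–32 Hz, 0.5 Hz bins; Welch,
Hamming 512/overlap 128, zero-padded to 2,048 points) and 19 scalar
features: total power; percent band power per side in delta (0.5–4 Hz),
theta (4.5–8), alpha (8.5–13) and beta (13.5–32); band-mean
interhemispheric coherence Cxy(f) = |Pxy|²/(Pxx·Pyy); spectral entropy
H = −Σ Pᵢ ln Pᵢ of the normalized spectrum; kurtosis k = E(x−µ)⁴/σ⁴; and
line length. Group contrasts use a fixed-effects least-squares model
across frequency bins (construct F tests, LogWorth, significant-interval
extraction) and one-way ANOVA with Tukey's HSD.

The risk-score learner dichotomizes each feature at its
LogWorth-maximizing threshold and then searches *exhaustively* over
scorecards with at most 5 rules, integer coefficients in {−1, +1} and an
integer intercept, maximizing a penalized logistic likelihood — exact at
this scale, no MIP solver required. The fitted scorecard reports both
logistic and exact empirical score→probability calibration. A packaged
three-rule scorecard for immediate post-impact recordings (delta
coherence, contralateral beta share, contralateral kurtosis; scores 0–1,
2, 3 → 6.7%, 75.0%, 88.9% susceptible-strain probability) ships as
`builtin_scorecard()`.

See `docs/methods.md` for the signal model, statistical definitions, and
design choices.

## Worked example

```python
from cciqeeg.pipeline import RunConfig, run_pipeline

report = run_pipeline(RunConfig(seed=1, out_dir="demo_run"))
print(report["risk_model"])
print(report["n_patterns_reproduced"])
```

With the default cohort (10 subjects per strain) this prints

```
{'terms': ['coh_delta < 0.12785'], 'intercept': -1,
 'objective': -17.19670555596391}
11
```

meaning: all 11 tracked directional strain findings were reproduced on
the synthetic cohort, and the learned scorecard needs a single rule —
award one point when post-impact delta-band interhemispheric coherence
falls below 0.128 — which separates the plasticity-susceptible strain
perfectly in this draw (`demo_run/scorecard.md` shows the
score→probability table; the synthetic strains' delta coherence is
well separated by construction). `demo_run/stats.json` holds the binwise
effects, e.g. the baseline strain effect

```
"baseline_power_strain":  F = 43.4, LogWorth = 323.3,
    significant intervals [0.5, 4.5] and [5.5, 32.0] Hz
"power_timepoint_PPKS":   F = 0.48, p = 0.9998   (no spectral change)
```

— the kindling-resistant strain's slow-wave excess dominates the
baseline contrast while the susceptible strain's spectrum is unchanged
by the impact, the planted pattern.

Command-line equivalents: `cciqeeg pipeline run --seed 1 --out demo_run`,
plus per-stage commands (`cciqeeg synth cohort`, `cciqeeg preprocess`,
`cciqeeg features`, `cciqeeg riskscore fit/apply`).

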