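# Methods

`cciqeeg` analyzes two-channel epidural EEG recorded around a controlled
cortical impact (CCI), an experimental model of traumatic brain injury in
rats. The scientific question it serves: does the immediate post-impact
electrographic signature differ between rat strains selected for
susceptibility (PPKS) or resistance (PPKR) to kindling-induced plasticity,
relative to the outbred Sprague-Dawley (SD) parent strain — and can a
pocket-sized integer score assign a new animal to the susceptible class?
Because the underlying animal recordings are not publicly deposited, the
package pairs the analysis chain with a synthetic cohort generator whose
ground truth is fully known, so every stage is testable end to end.

## Epoching and filtering

Recordings are sampled at 1,024 Hz with one event mark at the impact.
Five 60 s epochs are analyzed per subject: a baseline epoch ending 0.5 min
before the impact, and post-injury epochs beginning 0.5, 5, 10, and 15 min
after it. Sample intervals are half-open `[start, end)` with 0-based
indexing and `start = cci_sample + round(offset * fs)`; with fs = 1024 and
the impact at sample 614,400 the baseline epoch is exactly
`[522240, 583680)`.

Each epoch is bandpass filtered to 0.5–32 Hz with a linear-phase FIR
applied forward and backward (zero net phase, output length preserved).
The magnitude template is: passband 0.5–32 Hz with ripple ≤ 1 dB,
stopbands at ≤ 0.1 Hz and ≥ 40 Hz with ≥ 40 dB attenuation. The filter is
a Kaiser-window design (45 dB design attenuation over the narrow
0.1→0.5 Hz transition, 6,609 taps, cutoffs at the transition midpoints);
a Parks–McClellan design of the order this transition requires (several
thousand taps) does not converge numerically, and the Kaiser design meets
the same template with margin (measured stopbands −42.7 dB and −68 dB,
passband ripple < 0.1 dB). Filtering is applied per epoch *after*
extraction so the impact artifact can never ring into an analyzed
segment; the epoch scheme itself never overlaps the artifact.

## Spectral estimation

Power spectral densities are Welch averages of Hamming-windowed
512-sample segments with 128-sample overlap (hop 384), per-segment
constant detrend, zero-padded to 2,048 FFT points so the native frequency
spacing is 0.5 Hz. Estimates are kept on a fixed 64-bin grid (bin centers
0.5–32.0 Hz); the four analysis bands partition it exactly — delta
0.5–4 Hz (8 bins), theta 4.5–8 Hz (8), alpha 8.5–13 Hz (10), beta
13.5–32 Hz (38). Post-injury spectra are normalized per subject to the
baseline total power (the 0.5–32 Hz PSD integral, averaged over the two
sides).

Two windowing biases are worth knowing. The 0.5 s segment length gives a
~2 Hz mainlobe, so sharply band-limited content smears a few percent of
its power into adjacent bins; and per-segment demeaning suppresses power
below ~1–2 Hz, noticeably for 1/f-shaped signals. Both biases are
identical across epochs and subjects, so normalized and between-group
comparisons are unaffected; absolute total power is a mildly biased
estimate of variance (the test suite checks it against a direct
periodogram oracle over the same band instead).

Interhemispheric magnitude-squared coherence,
`Cxy(f) = |Pxy|² / (Pxx · Pyy)`, uses the same Welch scheme with auto- and
cross-spectra averaged across segments *before* the ratio (a single
segment would give Cxy ≡ 1). Band-level coherence is the unweighted mean
over the band's bins.

## Scalar features (19 per subject-epoch)

* **Total power** — non-normalized PSD integral, mean of the two sides (µV²).
* **Percent band power** — per side, 100 × band sum / all-bin sum; the four
  bands sum to 100 by construction.
* **Band coherence** — delta/theta/alpha/beta mean Cxy.
* **Spectral entropy** — Shannon entropy of the 64-bin spectrum
  renormalized to sum to one, in nats (natural log; the base is a config
  constant). Bounds [0, ln 64] are attained exactly at single-bin and flat
  spectra.
* **Kurtosis** — the fourth standardized moment E(x−µ)⁴/σ⁴, population
  estimator, no −3: a Gaussian signal gives 3, the ±1 alternating sequence
  gives 1.
* **Line length** — implemented literally as the planar path length of the
  trace with unit index step, Σ√(1 + Δy²), so a constant N-sample signal
  gives N−1; the conventional amplitude-only variant Σ|Δy| is computed and
  stored alongside for sensitivity analysis.

Side labels: the right hemisphere is ipsilateral to the impact. Swapping
the ipsilateral flag relabels side-specific features without changing any
value.

## Group statistics

**Binwise model.** Spectra (or coherence spectra) are analyzed by a
fixed-effects least-squares model across the 64 bins. The construct-level
test for a factor (strain, side, timepoint) is the joint F-test of the
factor's main effect *plus* its factor-by-bin interaction, via a nested
model comparison against the model without that factor. The interaction
must be included: after per-subject normalization two groups can differ
at every frequency while their across-bin main effects are identical, so
a main-effect-only test has no power against exactly the spectral-shape
differences of interest. Effect strength is reported as
LogWorth = −log10(p). Separate per-bin F tests at α = 0.05 feed the
significant-interval report (maximal runs of consecutive significant
bins, endpoints as bin-center frequencies). Per-bin p-values are
uncorrected by default, mirroring bracketed-interval reporting practice;
a Benjamini–Hochberg flag exists. Subject is the experimental unit but
enters no random effect — a deliberate simplification that makes
within-subject (timepoint) tests conservative when stable between-subject
variability is present.

**Scalar features** are compared by one-way ANOVA with Tukey's HSD
(Tukey–Kramer for unequal n), using the exact studentized-range
distribution with pooled-error degrees of freedom; with two groups the
adjusted p equals the pooled two-sample t-test p to numerical precision.

## Integer risk score

The classifier target is plasticity susceptibility: PPKS = susceptible,
SD/PPKR = not, using the 19 features at the 0.5-min post-injury epoch.

1. **Dichotomization.** Each feature is split at the threshold maximizing
   the LogWorth of the 2×2 feature-by-class table over candidate
   thresholds (midpoints of consecutive sorted distinct values). The
   association p-value is a likelihood-ratio chi-square with a Fisher
   exact fallback whenever an expected cell count falls below 1; ties
   break toward the smaller threshold, and the point direction is the
   side richer in the susceptible class.
2. **Model search.** Exhaustive enumeration over rule subsets of size
   ≤ 5, integer coefficients in {−1, +1}, and an integer intercept in
   [−10, 10], maximizing logistic log-likelihood − λ·(number of terms).
   At 19 features this is ≈ 4.4 × 10⁵ subset-sign combinations × 21
   intercepts — small enough that enumeration is *exact*, so no
   mixed-integer solver is needed; a brute-force oracle verifies argmax
   identity in the tests. Tie-breaking is deterministic (fewer terms,
   then lexicographic feature order, then +1-first sign patterns, then
   smaller intercept) and the result is invariant to row and column
   order.
3. **Calibration.** Per achievable score the model reports both the
   logistic probability 1/(1+exp(−(intercept+score))) and the empirical
   class fraction as an exact ratio of counts.

The penalty default λ = 4.0 was set by a prescribed null calibration:
on all-noise 19-feature tables of 32 subjects (11/21 class split), λ ∈
{3, 4, 5, 6} all return ≤ 1 term in 100% of 200 draws (λ = 2: 42%); 4.0
sits centrally with margin on both sides. In the recovery test, planted
features carry a 2.0 SD class-conditional shift — sized so the
dichotomized signal is clearly identifiable; at weaker shifts (≈1.5 SD)
the *third* feature's incremental likelihood gain under the bounded
integer coefficients occasionally falls below λ, an identifiability limit
of the model class rather than a search failure.

A learned threshold outside a feature's mathematical range (e.g. a
coherence cutoff above 1) is flagged in the model's warnings. The
packaged three-rule tool (`builtin_scorecard`) carries exactly such a
flag on its delta-coherence rule, which it retains verbatim so its
calibration table (scores 0–1 → 6.7%, 2 → 75.0%, 3 → 88.9%) reproduces
the tool as printed.

## Synthetic cohort generator

**Signal model.** Each channel is a sum of four band-limited Gaussian
noise components (synthesis edges 0.5–4–8–13–32 Hz) shaped by a 1/f^a
envelope (a = 1 by default). Per band the two channels mix a common and a
private unit-variance source as
`ch = sqrt(s)·common + sqrt(1−s)·private`, so the shared variance
fraction s sets interhemispheric coherence (zero lag; expected
magnitude-squared coherence s²). A smooth waxing-and-waning envelope with
depth `am_depth` gates the supra-delta components (emulating post-impact
suppression of faster activity): it concentrates spectral mass at low
frequencies, lowering spectral entropy, while its probit-squashed uniform
marginal keeps the kurtosis footprint small. Sparse biphasic transients
(40 ms, Poisson-timed, amplitude in channel-SD units) raise kurtosis.
Parameters switch from the baseline to the post-injury regime at the
impact sample, where a 0.5 s saturating 1,000 µV square artifact is
written on both channels. Channel RMS is 50 µV at unit band gains; all
downstream features except total power and line length are
scale-invariant.

**Strain presets** encode the qualitative injury pattern: PPKR baseline
has a delta gain of 1.6 and supra-delta gains of 0.5 (slow-wave excess,
fast deficit, roughly power-neutral overall); SD baseline lowers
theta/alpha shared fractions (a mid-frequency coherence deficit). After
the impact: PPKS keeps its band gains (no spectral change); SD scales all
gains by 0.55 and PPKR by 0.7 (broadband power loss); delta shared
fractions become 0.25/0.45/0.65 (PPKS < SD < PPKR coherence ordering)
and theta shared fractions drop to 0.3 in all strains (the common 3–7 Hz
coherence loss); PPKS and SD apply `am_depth = 0.2` on the ipsilateral
channel only (entropy drop); PPKR alone injects ipsilateral transients
(0.05/s at 8 SD, kurtosis rise). Cohorts add per-subject log-normal
band-gain jitter (sd 0.2 on the log scale, identical in both regimes and
channels) emulating stable between-animal spectral differences; all
jittered values are recorded in the ground-truth manifest. Effect sizes
were fixed during development so that a study-scale cohort (default 10
per strain, ≈ the 32-animal design) reproduces every directional finding
in ≥ 90% of cohort draws, and were not revisited afterwards.

**Seeding.** One master seed; per-subject seeds derive from
counter-based `SeedSequence([master, strain_index, subject_index])`, so a
subject's recording is independent of cohort size and ordering. Equal
seeds give bit-identical output.

**What the generator is not.** It is statistical, not biophysical: no
neural mass dynamics, no anesthesia depth, no chronic epileptogenesis,
no electrode artifacts beyond the impact mark. Passing tests show the
*analysis chain* recovers planted structure of realistic size and
direction; they cannot validate the biology of the original recordings.

## Pattern evaluation

The pipeline's qualitative table tracks eleven directional findings
(baseline slow-wave excess and fast deficit in PPKR; post-injury
broadband power loss in SD and PPKR but stability in PPKS; the 3–7 Hz
coherence drop in all strains; the post-injury delta-coherence ordering;
the ipsilateral entropy drop in PPKS/SD with PPKR stable; the
ipsilateral kurtosis rise in PPKR with PPKS/SD stable). Positive
findings require construct-level significance at α = 0.05 with correct
mean direction. Entropy and kurtosis findings are judged on per-subject
injury *change scores* (post − baseline, which cancel the stable
between-animal jitter) compared across strains with Tukey HSD. "No
change" findings require the relevant p to stay above 0.01 — the same
evidence level at which the positive effects are claimed.

## Problem sizes

Default cohorts use 10 subjects per strain and 1,072 s recordings.
Monte-Carlo calibrations in the acceptance suite use 500 null replicates
(binwise type-I error), 1,000 replicates (Tukey family-wise rate), 50
replicates (planted-feature recovery at n = 40/class), and 10 cohort
draws (pattern reproduction); these sizes make the full pipeline and
suite runnable on a single CPU in minutes while keeping the Monte-Carlo
standard errors well inside the asserted tolerance bands.

## Known limitations

* Coherence is controlled per band with zero lag; phase relationships are
  not modeled (magnitude-squared coherence is lag-blind).
* The binwise construct test treats bin-level observations as independent
  (no within-subject correlation structure), so its LogWorth values are
  optimistic in absolute terms; the package uses them comparatively.
* The literal line-length formula mixes index and amplitude units; for
  µV-scale signals it is dominated by the amplitude term and behaves like
  the conventional variant (also reported).
* Spectral entropy is a deterministic functional of the spectrum, so any
  entropy effect necessarily has *some* spectral footprint; the presets
  make it small relative to between-subject variability rather than zero.
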