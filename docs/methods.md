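# Methods

This note documents the models, conventions and numerical choices behind
`eegwcst`: a pipeline for extracting EEG spectral correlates of Wisconsin
Card Sorting Test (WCST) performance and relating them to age, validated
end to end on synthetic cohorts with known ground truth.

## The analysis pipeline

### Task scoring

A WCST trial log records, per trial, the active sorting rule (color, shape
or number), the chosen deck, the set of categories by which the choice
matches the drawn card, and the feedback. Task mechanics: the rule changes
silently after 10 consecutive correct matches (one *completed category*),
the new rule always differs from the old one, and the test ends after nine
completed categories or 128 cards.

Scoring walks the log once:

* **completed categories** — number of 10-consecutive-correct runs (0–9);
* **perseverative errors** — incorrect choices that match the rule active
  before the most recent shift. By default such a choice counts as
  perseverative at any point of the current rule period; a configurable
  stricter window (`until_acquisition`) limits it to the post-shift search
  phase. A choice that matches both the old rule and neither-new is still
  perseverative — perseveration is its own class and takes precedence over
  the efficient/distraction split;
* **nonperseverative errors** — all other incorrect choices, split into
  *efficient* (before the first correct trial under the new rule, i.e.
  during rule search) and *distraction* (after the current rule has been
  demonstrated at least once). "Rule acquired" is operationalized as the
  first correct trial under the current rule.

Each raw measure is standardized across the cohort, z = (V − V̄)/SD with
the sample (n−1) SD; a degenerate cohort (zero variance) is an error, not
a silent zero. The pooled performance z-score is a sign-weighted average

    z = (w_c·z_cat + w_p·z_pers + w_n·z_nonp) / (|w_c| + |w_p| + |w_n|),

with default weights (+1, −1, −1): completed categories count positively,
both error types negatively. The magnitudes are a package choice (exposed
in the API) — only the signs are substantively constrained — and the
pooled score is invariant to positive rescaling of the weight vector.
Performance levels (good/medium/poor) come from 1-D K-means with k = 3,
25 random initializations and a fixed seed, labels named by descending
cluster mean.

### Preprocessing

Fixed stage order, enforced through a stage tag on every recording:

1. **Band-pass** 0.3–100 Hz: 4th-order Butterworth sections applied
   forward–backward (`sosfiltfilt`), which squares the magnitude response
   (48 dB/oct overall) and cancels the phase. Sampling rates below 256 Hz
   are rejected (the 100 Hz edge would sit too close to Nyquist).
2. **Mains notch**: zero-phase 2nd-order Butterworth band-stop with a 2 Hz
   stop band around 50 Hz. The band-stop transformation places a
   transmission zero exactly on the mains frequency; 45 and 55 Hz pass
   within 5%.
3. **Ocular correction**: seeded fast fixed-point ICA (scikit-learn
   FastICA), fitted on data decimated to ≈64 Hz (blinks live far below
   that) and applied at the full rate. A component is flagged as ocular
   when all three hold: (a) |corr| of its time course with the frontal
   proxy — the mean of the two most anterior channels — exceeds 0.7;
   (b) its scalp loading is frontal-dominant (mean |loading| over the
   front third of channels > 2× the back third); (c) more than 55% of its
   variance lies below 5 Hz. Criterion (c) is needed because a component
   aligned with a single frontal channel correlates with the two-channel
   proxy at exactly 1/√2 ≈ 0.707 even without any blink; the
   low-frequency criterion separates slow ocular transients from such
   broadband noise components. Flagged components are zeroed and the data
   reconstructed; with nothing flagged the data pass through bit-identical.
   On blink-free, near-Gaussian data the fixed point has no stable
   contrast optimum; an iteration-limit stop is therefore recorded in the
   report rather than raised (the flagging criteria protect the data),
   while a non-finite decomposition raises.
4. **Surface Laplacian (current source density)**: spherical-spline
   Laplacian (stiffness m = 4, regularization λ = 1e-5, 50 Legendre
   terms) with electrode positions projected onto the unit sphere, output
   reported in μV/m². On the unit sphere, clean EEG lands in the tens to
   low hundreds of μV/m² and focal high-amplitude artifacts in the
   thousands — the scale at which the standard 500/800 μV/m² rejection
   thresholds are meaningful. (At a 0.1 m head radius the 1/r² factor
   multiplies everything by 100 and those thresholds would reject every
   epoch of any realistic recording.)
5. **Epoching**: contiguous, non-overlapping 5-s epochs, trailing partial
   epoch discarded; epochs are not locked to task events.
6. **Rejection**: an epoch is rejected when any analysis channel exceeds
   500 μV/m² in absolute amplitude or 800 μV/m² peak-to-peak (amplitude
   takes precedence as the recorded reason). Thresholds apply per channel
   over the twelve pooled analysis channels and are configurable.

### Spectral features

Spectra are Hann-tapered per-epoch periodograms and cross-periodograms at
0.2 Hz resolution, averaged over accepted epochs; the taper normalization
preserves Parseval (the PSD integral over [0, Nyquist] equals the signal
variance). At least two accepted epochs are required — single-epoch
coherence is identically 1.

Four electrode pools of three channels each define the scalp regions:
FL = (FC5, F3, FC1), FR = (FC6, F4, FC2), PL = (CP5, P3, CP1),
PR = (CP6, P4, CP2). The **alpha peak frequency** (APF) per pool is the
argmax of the pool-averaged PSD on the 8–13 Hz grid (edges inclusive, ties
to the lower frequency); a peak rising less than 5% above the window
median, or sitting on a window edge, is flagged low-confidence. Bands are
individualized: alpha = APF ± 2 Hz, theta = APF−7 to APF−3 Hz. The APF is
detected on the task span and anchors the bands for both spans of the same
subject.

**Band power** is the pool mean of the PSD integrated over the band bins,
both edges inclusive on the discrete grid. **Pool coherence** is the
magnitude-squared coherence msc(ω) = |C_ij(ω)|²/(C_ii(ω)·C_jj(ω)) formed
from the epoch-averaged spectra for each of the 9 cross-pool channel
pairs, averaged over the band bins and then over the pairs (a magnitude —
square-root — mode is available as a config switch). Averaging the nine
pairwise statistics was chosen over correlating pool-averaged signals,
which would conflate within-pool phase alignment with between-pool
coupling. For a coupling between pools with different APFs the band is
anchored at the mean of the two detected peaks. Six couplings are
analysed: FL–FR, FL–PL, FL–PR, FR–PR, FR–PL, PL–PR.

**Baseline correction** defaults to subtraction (task − baseline) for both
power and coherence; a log-ratio mode (10·log₁₀(task/baseline), power
only) is available. **APF asymmetry** is the signed left-minus-right
difference (FL−FR frontal, PL−PR parietal), carrying a low-confidence flag
if either input does.

### Statistics

Per EEG marker: (i) a two-way ANOVA of age group × performance cluster
with Type II sums of squares (appropriate for the unbalanced design; the
interaction is included only when every cell holds ≥ 2 observations);
(ii) OLS of the marker on age and performance z-score; (iii) partial
correlations of the marker with age controlling z-score and with z-score
controlling age,

    r_xy·z = (r_xy − r_xz·r_yz) / √((1 − r_xz²)(1 − r_yz²)),

with the p-value from a t statistic on n − 3 degrees of freedom. The
partial correlation equals the correlation of the residuals from
regressing each variable on the control — the test suite verifies this
identity against an independent residual-regression implementation to
1e-10. Confirmatory subgroup modes rerun the age correlations on good
performers only and the performance correlations on elders only. No
multiple-testing correction is applied by default; the designs report raw
per-feature statistics.

## The synthetic-data generator

The generator defines the study conditions every downstream stage is
validated against: 62 subjects by default, in three age groups (young
20–34, mid 51–64, elder 67–82; proportions 19/28/15), 1024 Hz sampling,
300-s task recordings and 30-s baselines.

**Latent structure.** A latent skill variable is drawn with a target
age–skill Pearson correlation of −0.621. Per subject, the planted spectral
truth is: pool-averaged alpha band power 20 μV² at age 50 declining
0.15 μV²/yr (theta: 14 μV², 0.08 μV²/yr; floor 6 μV²; between-subject
noise SD 1 μV²); left-hemisphere APF 10.4 Hz at age 50 declining
0.025 Hz/yr while the right-hemisphere APF (10.2 Hz) carries no age slope;
band-averaged msc 0.03 at age 50 declining 0.0005/yr for the age-coupled
couplings, while the FL–PR coupling instead carries a performance-only
effect of +0.02 msc per skill SD (no age term). Baseline spans scale alpha
power ×1.3, theta power ×0.8 and coherence ×1.15 relative to task,
mirroring the usual rest-vs-task contrast. The FL–PR effect size was
calibrated so that the *measured* elders-only correlation (≈0.6 through
the full pipeline) matches the magnitude of reported performance-specific
coupling effects; with that magnitude a 15-subject elders subgroup detects
it reliably.

**Signal model.** Synthesis is exact in the frequency domain: each
component has deterministic spectral magnitudes and random phases, so the
analytic spectra and cross-spectra of the generated data equal the planted
targets and pipeline estimates converge to them with epoch count. Per
channel:

* a 1/f background, S(f) = 3/max(f, 0.5) + 0.05 μV²/Hz. Inside the
  1–18 Hz analysis range the background is channel-independent; outside
  it, 85% of the background power is carried by sixteen spatially smooth
  fields (Gaussian scalp profiles, width 0.09 m, fixed centres). The
  split is deliberate: a spatially correlated in-band background would
  impose a hard floor on cross-pool coherence — with correlation ρ the
  minimum achievable msc is (0.85ρ)² ≈ 0.3–0.45, exactly the
  volume-conduction redundancy the surface Laplacian exists to remove —
  making low planted targets unrealizable, while the smooth out-of-band
  share keeps the broadband Laplacian of clean data far below the
  rejection thresholds;
* one alpha and one theta oscillator per pool: Gaussian spectral bumps
  (σ = 0.5 and 0.7 Hz) at the pool's APF and APF−5, with a compact scalp
  map (Gaussian, width 0.03 m) centred on the pool;
* one flat band-limited shared source per coupling and band, spanning the
  whole band (background-only margin bins would bias the band average).

A damped Gauss–Seidel calibration solves the oscillator powers and shared
source gains jointly against the full analytic cross-spectral cube —
background correlation, scalp-map leakage and every other shared source
included — so that the pool-mean band powers and the band-averaged msc
values equal the planted targets (residuals < 5e-4 msc and < 0.1% power;
infeasible target combinations raise a configuration error rather than
silently degrade). The narrow pool maps matter here: wider maps leak
across regions and inflate cross-pool coherence beyond any target.

**Behavior.** A simulated agent plays the task: per trial it knows the
active rule with a probability given by a logistic link on skill,
perseverates on the pre-shift rule with a skill-linked rate while
searching, and lapses at a skill-linked distraction rate once the rule is
acquired. An oracle agent (rates 0, skill → ∞) completes nine categories
in exactly 90 trials with zero errors, which pins the scorer.

**Artifacts.** Blinks are 300-ms raised-cosine transients (two per
ledgered epoch, 350 μV at the most frontal site) with a frontal-dominant
spatial pattern falling to 0.1 posteriorly. Amplitude artifacts are focal
0.5-s biphasic (zero-mean) pulses of 400 μV on a single pooled channel —
biphasic because a net-area pulse excites second-scale tails in the 0.3 Hz
zero-phase high-pass that leak into neighbouring epochs; transients are
also placed ≥ 1 s from epoch edges for the same reason. The planted ledger
is returned for verification: amplitude artifacts exceed the post-Laplacian
500 μV/m² threshold in exactly the listed epochs, while blinks are removed
by the ocular stage and must not trigger rejection.

## What the synthetic validation does and does not show

The generator emulates the *statistical structure* of an aging/EEG study —
group sizes, the age–performance collinearity, band-power and APF slopes,
coupling effects, artifact types — not the biophysics. There is no head
model or forward solution; scalp maps are Gaussian profiles, not dipolar
topographies; spectra are stationary within a recording (no event-locked
dynamics, by design — the analysis epochs are not task-locked either); and
the in-band background is spatially independent, which understates
volume-conduction redundancy precisely where the Laplacian would remove
it. Passing tests therefore demonstrate that the pipeline measures what
was planted at realistic SNR and sample sizes — estimator correctness,
threshold behaviour, sign and detectability of planted effects — not that
it would reproduce any particular human dataset.

## Validation problem sizes

The validation battery (tests and `scripts/acceptance.py`) scales the
study conditions down so the whole suite runs on one CPU in minutes; the
sizes are the package's choices:

* coherence oracle: two-channel shared-source pairs, γ ∈ {0.25, 0.5, 1,
  2, 4}, 500 five-second epochs at 256 Hz, msc compared with
  (γ/(1+γ))² to ±0.02;
* Parseval: 60 epochs of unit white noise, integral within 2%;
* APF recovery: six subjects with on-grid planted peaks spanning
  8.6–12.2 Hz, 150 epochs, minimal coherence targets so the bump
  dominates; recovery within one 0.2 Hz grid step. (At realistic epoch
  counts the argmax of a σ = 0.5 Hz bump fluctuates by one bin — that is
  the estimator's resolution, not a defect.);
* artifact/blink checks: 3-subject cohorts, 60-s tasks at 256 Hz, full
  pipeline including ICA;
* partial-correlation null calibration: 2000 draws at n = 60;
* end-to-end recovery: 20 cohorts of 60 subjects, 19 channels, 256 Hz,
  300-s tasks (60 epochs), artifact-free with the ocular stage skipped;
  asserts the negative age slope of task alpha power (all four pools) and
  of the left APF in ≥ 95% of cohorts, and the positive elders-only FL–PR
  coherence/performance correlation (sign in ≥ 95%, median p < 0.05).

## Known limitations

* The joint band-power/coherence budget bounds realizable coherence:
  each pool funds three couplings, its oscillator and the in-band
  background from one band-power target, so the defaults use modest msc
  targets (≈0.01–0.08). Infeasible combinations raise immediately.
* Coherence features are measured after the surface Laplacian, which
  attenuates and slightly mixes the planted values; recovery tests
  therefore assert signs and detectability, not absolute post-Laplacian
  coherence levels. Pre-Laplacian estimates converge to the planted
  targets exactly.
* The WCST simulator draws card attributes independently, so a choice may
  match several categories at once (ambiguous trials), as in the real
  deck; the scorer classifies such trials by rule precedence
  (perseveration first).
* EDF files are read but not written; on-disk cohorts use BrainVision
  triplets (IEEE float32).
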