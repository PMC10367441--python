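# Methods

This note records the statistical models, preprocessing conventions, and
parameter defaults implemented in `wmcpm`, and the rationale for each
choice. Everything described here is enforced by the test suite.

## Data model

A subject contributes one or more runs of node time series (T × N, 1-based
node identifiers from a parcellation of up to 268 nodes), one motion
confound table per run, and behavioral data (N-back trials, emotion-
regulation choice trials, questionnaire items). Network masks are
undirected edge lists over the same node identifiers, one *high* and one
*low* mask; the reference masks have 1,674 and 1,203 edges on the 268-node
atlas and are disjoint.

## Denoising

**Framewise displacement.** Power's convention: the sum of absolute
backward differences of the three translations plus the three rotations
converted to arc length at a 50 mm head radius. The first volume is 0.

**Confound model.** A single joint least-squares projection removes, per
run: 24 motion parameters (the 6 realignment parameters, their backward-
difference derivatives, and the squares of both), 3 tissue signals (white
matter, CSF, global), one one-hot column per motion spike (FD ≥ 0.90 mm,
inclusive), and a discrete-cosine high-pass basis with 0.01 Hz cutoff
(`K = floor(2 · T · TR · f_c)` columns; K = 9 at T = 455, TR = 1 s). An
intercept is always included. Filtering inside the regression (rather than
sequentially) avoids reintroducing removed variance. Rank-deficient designs
warn rather than fail, since `numpy.linalg.lstsq` returns the minimum-norm
projection, which is the correct residual either way.

**Exclusions.** A run's mean FD ≥ 0.15 mm (inclusive) excludes the run; a
subject with no usable runs is excluded. Nodes whose raw parcel signal is
flat in any run (zero variance — signal dropout or no coverage) are treated
as missing for that subject.

## Connectomes and network strength

Per run: Pearson correlation between all denoised node pairs. Runs are
averaged **on the r scale** and the average is then Fisher-transformed,
`z = atanh(mean_runs r)`. The reverse order (transform, then average) is
not interchangeable — it inflates heterogeneous edges — and a test guards
the implemented order.

Missing nodes are harmonized across the cohort: the union of all subjects'
missing nodes is removed from every matrix, so all subjects share one node
set (268 → 266 when two nodes drop anywhere in the cohort). Masks are then
restricted to edges whose both endpoints survive (1,674 → 1,667 and
1,203 → 1,193 for the reference masks when those two nodes drop).

Network strength is the **mean** of the transformed weights over the mask's
edges. The mean rather than the sum keeps the score on the scale of a
Fisher-z correlation (cohort means near 0.05–0.10), makes the high and low
scores comparable despite different mask sizes, and makes the score
invariant to mask restriction in expectation. The combined score is exactly
`high − low`. For the moderation models, strength is grand-mean-centered
within the analyzed sample.

## Behavioral scoring

**N-back.** 8 blocks × 10 trials per run, alternating 0-back and 2-back.
Accuracy is computed per block and averaged within condition; the run
accuracy pools all blocks. A run is excluded when its pooled accuracy is
≤ 0.50 (inclusive — chance level is not usable evidence); a subject is
excluded only when every run fails. Per-subject accuracy averages the
usable runs within condition.

**Emotion-regulation choice.** 24 trials, 12 low- and 12 high-intensity
images; the score is the percentage of trials on which acceptance was
chosen, overall (the mean of the two intensity percentages) and per
intensity.

**Questionnaires.** DERS: 36 items on 1–5, items
{1, 2, 6, 7, 8, 10, 17, 20, 22, 24, 34} reverse-keyed as
`(min + max) − response`; CES-D: 20 items on 0–3; BAI: 21 items on 0–3.
Totals are sums; no imputation — any missing item fails the subject's
score. CES-D ≥ 20 (inclusive) marks the subject ineligible. Internal
consistency is Cronbach's alpha with the Feldt F-based interval
(`1 − (1 − α̂) · F` at the quantiles of F with df `n − 1` and
`(n − 1)(k − 1)`).

## Statistics

**Correlations.** Each pair first passes through Shapiro–Wilk on both
variables (recorded, not used to switch methods): rank-based correlation is
reported regardless, which is what the gate would mandate whenever either
variable departs from normality. Spearman's ρ is the Pearson correlation of
mid-ranks; the p-value uses the t approximation on `n − 2` df; the
confidence interval is Bonett–Wright:
`atanh(ρ) ± z · sqrt((1 + ρ²/2)/(n − 3))`, back-transformed. Cells use
pairwise-complete observations.

**Moderation.** With exactly two observations per subject (low / high
intensity) and a random intercept, REML has a closed form. Splitting the
data into the within stratum (difference scores `d_s = y_high − y_low`,
regressed on the centered moderator: estimates `b1`, `b3`, and
`σ̂²_e = σ̂²_d / 2`) and the between stratum (subject means: estimates the
remaining terms and `σ̂²_u = max(σ̂²_mean − σ̂²_e/2, 0)`) reproduces the
iterative REML fit exactly; the test suite verifies equality with
`statsmodels.MixedLM` to numerical precision and with difference-score OLS
to 1e-8. Fixed-effect tests use between-within degrees of freedom,
`n_subjects − 2` for the within-stratum terms (t(102) at n = 104). Simple
slopes of intensity are reported at ±1 SD of the moderator,
`b1 + k·SD·b3`, with variance from the within-stratum covariance. Only
balanced data are accepted; unbalanced input raises with a message
recommending listwise deletion, keeping the closed form exact.

**Power and sensitivity.** Correlation power uses the bias-corrected
Fisher transform `z_r = atanh(r) + r / (2(n − 1))` and a critical value
from the t distribution mapped back through `atanh` — the convention of
standard power software. It yields n = 55 for r = 0.37 (α = .05, power
.80). Solvers invert it by integer search (`power_n_for_r`) and by Brent
root-finding (`min_detectable_r` → 0.27 at n = 104). Interaction
sensitivity inverts noncentral-F power with `λ = f²(u + v + 1)` for a
1-df test in a 3-predictor model (→ f = 0.28 at n = 104). A 1e-9 slack in
the integer search keeps the solvers mutually consistent at the boundary.

## Synthetic data generator

The generator plants known structure at cohort-realistic scales so every
stage can be checked against ground truth.

**Connectomes.** Each subject's Fisher-z matrix is background plus
mask-specific mean shifts driven by a per-subject latent level (high mask:
mean 0.09, between-subject SD 0.03; low mask: mean 0.00, SD 0.02;
background mean 0.05; edge noise SD 0.25). These defaults put strength
means, SDs, and the combined-score SD at the scale seen in older-adult
cohorts. Behavior is `0.80 + 0.87 · (combined − mean) + noise(SD 0.084)`,
which gives a population Pearson correlation ≈ 0.36 at the default sizes
(population Spearman via `(6/π)·asin(r/2)` under normality).

**Time series.** To generate raw data the r-scale target matrix is
projected to the nearest correlation matrix (eigenvalue clipping with
diagonal rescaling) and sampled as multivariate normal through an
eigendecomposition factor. The generating truth is defined as the
transformed *projected* target, so recovery is measured against the
structure actually generating the data. Motion is a bounded random walk
(translation step 0.015 mm, rotation step 0.00025 rad) giving mean FD near
0.07 mm — an older-adult scale — with optional persistent 1.5 mm spikes at
a configurable rate.

**Behavior.** N-back trials are Bernoulli with a per-subject logit
ability; in full-study simulation the 2-back ability is coupled to the
planted combined strength so the strength–accuracy correlation survives the
whole pipeline. Choice trials follow a mixed logistic model with a random
subject effect (SD 1.5). Questionnaire items come from a one-factor model
whose loadings are calibrated to a target alpha through
`ρ = α / (k − (k − 1)α)` and then discretized to the Likert range by
Gaussian thresholds; discretization attenuates alpha slightly, which the
calibration tolerance absorbs. The moderation cohort is a balanced
two-condition design with defaults (intercept 64.66, intensity effect
−9.86, subject SD 22, residual SD 29, moderator SD 0.04) chosen so the
mixed-model standard errors land at realistic magnitudes for n ≈ 104.

## Limitations

- Parcellation from 4-D images requires the optional `nibabel` extra; the
  core pipeline operates on extracted node time series.
- The closed-form mixed model requires balanced data (two observations per
  subject); unbalanced designs must be reduced by listwise deletion first.
- The generator's multivariate-normal time series have no autocorrelation;
  temporal-filtering effects on effective degrees of freedom are therefore
  not simulated.
- Between-within degrees of freedom are the only supported df method;
  Satterthwaite approximations are out of scope because they never differ
  in the balanced two-observation design.
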