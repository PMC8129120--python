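# Methods

`spinescale` analyses longitudinal two-photon recordings of single dendritic
spines co-expressing SEP-GluA1 (a pH-sensitive tag reporting cell-surface
AMPA-receptor content, a proxy of synaptic strength) and dsRed2 (a structural
fill, a proxy of spine size). The experimental design it targets follows a
cohort of mice through five imaging sessions over 48 h — before and after a
~7 h sleep period, immediately after motor training, and again after a
post-training period spent either asleep (S) or sleep-deprived (SD) — and asks
whether sleep renormalises synaptic strength after learning-induced
potentiation.

## The normalized-difference statistic

All single-spine change analysis is built on the normalized difference

    ND = (x_post − x_pre) / (x_post + x_pre),

a bounded (−1, 1), antisymmetric, scale-invariant measure of fractional
change. ND maps monotonically to the post/pre ratio through
`ratio = (1 + ND)/(1 − ND)`; the working threshold of ±0.15 corresponds to
ratios of ~135% and ~74%. Classification is strict (`ND > thr` up,
`ND < −thr` down, else no change), so a spine exactly at the threshold is "no
change". Percentages of up/down spines are always computed within mouse first
and then averaged, so animals with many spines do not dominate; the up-vs-down
comparison is a two-sided paired t-test across mice. Dendrites are labelled by
strict majority of their up vs down spines (tie → "same").

Quintile analyses rank spines **within mouse** by the mean of two sessions'
intensities (not a single session) and cut the ranking into five near-equal
groups; averaging two sessions damps regression to the mean in the ranking
variable. Ties are broken by stable input order, which makes the assignment
deterministic.

"Max" spines are those with ND > 0.2 from the pre-training baseline to
immediately post-training — the putative learning-potentiated subset. Because
the partition is made on *measured* ND, it inevitably contains spines that
crossed the threshold by chance and will regress back; analyses of the max
partition must be read with that dilution in mind (it is why the mixed-model
interaction below is tested with an explicit two-group factor rather than by
re-thresholding).

The ratio-vs-baseline correlation (is proportional downscaling visible as a
negative correlation between baseline and post/pre ratio?) is mechanically
biased: measurement noise in the baseline enters both variables, producing a
negative correlation even for completely independent observations. The
`split_half` estimator adds and subtracts a fresh noise draw of the stated
measurement sd, yielding two pseudo-replicates with independent noise; one is
the baseline variable, the other the ratio denominator. This removes the
first-order coupling exactly. A second-order convexity bias — E[1/(x+ε)]
exceeds 1/x by ~σ²/x², more for small spines — remains in any ratio
estimator; at the package's default noise levels it is ≈ −0.05 in correlation
units, and the tests assert a large reduction relative to the naive estimator
rather than exact zero.

## Mixed-effect models

Four Gaussian linear mixed models, all fit by maximum likelihood
(statsmodels `MixedLM`), encode the longitudinal hypotheses. Spines are
nested in dendrites nested in mice; models 1 and 2 carry random intercepts at
all three levels, models 3 and 4 at dendrite and mouse level. Intensity
responses use a square-root transform to stabilise variance; model 3's
response is the raw intensity difference between the two post-training
sessions.

1. **time** (3 pre/post levels) on √intensity — is there a session effect
   across sleep and training?
2. **time × condition** (S vs SD) over the post-training interval — does the
   change depend on sleeping?
3. **condition × learning** (max vs other) on the 7h−0h difference — are
   learning-potentiated spines spared by sleep while the rest downscale? An
   optional time extension (7h−0h vs 24h−0h) tests persistence.
4. **sleep × training** factorial over the four main sessions, S mice only —
   is the sleep effect the same with and without preceding training?

Fixed effects are tested by likelihood-ratio tests (χ², df = parameter-count
difference); effect size is Cohen's f² computed from marginal R²
(variance of the fixed-effect predictor over fixed + random + residual
variance — the package documents this variant because R² is not unique in
mixed models). Post-hoc pairwise contrasts use single-step max-|z|
correction under the joint normal of the contrast estimates (multivariate
normal box probabilities), with Bonferroni as a fallback mode. Boundary
issues do not arise because only fixed effects are tested. Optimizers are
tried in a fixed order (L-BFGS, BFGS, Powell) and non-convergence is
reported on the fit object, never silently.

Calibration at small scale: on null simulations of the nested design
(6 mice × 2 dendrites × 5 spines × 2 levels) the LRT's type-I error is
0.05–0.06 at 1000 replicates, within binomial error of nominal, and the
max-|z| post-hoc controls familywise error at or below nominal.

## The two generative sleep models

Both mechanisms act on a log-normal baseline sample whose natural-scale mean
and variance match the observed pre-sleep intensities
(μ_log = ln(m²/√(v+m²)), σ²_log = ln(1+v/m²)).

* **Sleep-dependent potentiation** (5 parameters p_up, m_up, p_down, m_down,
  σ_ind): disjoint random fractions of spines are multiplied by m_up > 1 or
  m_down < 1; independent Gaussian noise of sd σ_ind is added to every spine.
* **Intervening-wake potentiation** (4 parameters p_down, m_down, σ_ind,
  σ_wake): sleep only downscales; apparent upscaling comes from a
  size-dependent wake-noise component bootstrapped from the observed pure-wake
  changes of SD animals, matched by baseline quintile (each dataset's own
  quintile cut points).

Scaling is multiplicative throughout — log-normal weight distributions are
the signature of multiplicative dynamics, and multiplicative events preserve
them exactly. Up- and down-scaled subsets are disjoint (overlap would make
the proportions non-identifiable). Post intensities are floored at 10⁻⁶ of
the baseline mean because additive noise can cross zero; at default noise
levels the floor touches far fewer than 0.1% of spines.

σ_wake semantics: the bootstrap wake deltas are rescaled by a **single global
factor** chosen so the wake component's overall sd equals σ_wake. This
preserves the *relative* spread across quintiles — the size dependence that
defines the mechanism — while exposing its magnitude as one parameter. A
per-quintile rescaling mode (each quintile forced to sd σ_wake) and a raw
bootstrap mode are selectable; the per-quintile mode makes the wake magnitude
size-independent and is not the default for that reason.

**Fitting.** A model is scored by the summed absolute relative error
Σ|((true − simulated)/true)| of its summary statistics against the target
sample: post mean, post variance, pre/post correlation, up/down proportions
at ND ±0.15, and the ten per-quintile up/down proportions. The quintile
proportions are part of the default fitting objective because the five core
statistics alone leave the five parameters under-determined (near-zero core
objectives occur at parameter vectors far from the generating ones); model
*comparison* uses the quintile-only errors, mirroring the logic that the two
mechanisms are distinguished by how scaling distributes across the size
spectrum. A signed-sum aggregation exists for diagnostics only — signed
errors cancel and make no sense as an objective.

Every candidate evaluation simulates a fixed n under common random numbers
derived from one seed, so the objective is a deterministic function of
(parameters, seed); optimisation is a deterministic coarse grid, a seeded
differential-evolution global stage, and Nelder–Mead polish. The simulation
n defaults to the cohort scale (~1530 spines).

**Recovery protocol and its limits.** In-silico recovery experiments share
the generative seed between the target dataset and the fit's
common-random-number stream; the objective is then exactly zero at the
generating parameters and recovery measures whether the optimiser finds the
global optimum. In a well-separated regime (downscaling factor 0.45, i.e.
ND ≈ −0.38, far past the classification threshold; baseline variance 0.3)
all parameters come back within a fraction of a percent over 30 replicates.
Two genuine limits are worth recording. First, with *independent* target
samples of n≈1500 the ±0.03/15% recovery bands are unreachable in principle:
a delta-method analysis of the relative-error estimator puts the parameter
sds at 4–6.5× those bands, driven by the heavy-tailed sampling noise of the
log-normal variance statistic and a (p_down, m_down, σ) ridge. Second, when
the true downscaling factor sits near the threshold (m_down ≈ 0.7,
ND ≈ −0.18), that ridge is flat even under shared draws and no optimiser can
resolve it; the package's recovery tests therefore probe the well-separated
regime and the limitation is stated here rather than hidden.

## The synthetic cohort generator

The generator is the test bed for the entire pipeline and emulates the study
design: 12 mice in two post-training conditions, 4–6 dendrites per mouse,
spines per dendrite ~ round(Normal(27.3, 14.2)) clipped at 5 (~1500 spines),
five sessions. Defaults, with units and origin:

| parameter | default | meaning |
|---|---|---|
| baseline_lognormal | (1.0, 1.0) | natural-scale mean/variance of spine SEP (arb. units) |
| dsred_coupling | 0.93 | natural-scale corr(spine SEP, spine dsRed2) at baseline |
| shaft_coupling | 0.18 | natural-scale corr(spine SEP, shaft SEP) |
| state_schedule | 0.363/0.568/0.379 (S) or 0.987 (SD)/~0.5 | wake fraction per interval |
| sleep_downscale | (0.25, 0.72) | event probability ∝ sleep fraction; multiplicative factor |
| wake_upscale | (0.03, 1.30) | event probability ∝ wake fraction; factor |
| learning_boost | (0.135, 2.2) | fraction of spines potentiated at training; factor |
| learning_protection | 1.0 | P(boosted spine resists post-training sleep downscaling) |
| volatility_log_sd | 0.20 | per-interval within-spine log-scale fluctuation |
| measurement_noise_sd | 0.02 | additive per-observation noise (intensity units) |
| turnover | (0.003, 0.003) | per-interval formation/elimination probabilities |
| performance_model | 12.0 − 40·ND, target r −0.64 | session-2 onset speed (rpm) vs net ND |

Baseline channels are drawn from a trivariate Gaussian on the log scale with
log-correlations obtained by inverting the log-normal correlation transform,
so the natural-scale couplings are hit exactly and baselines stay exactly
log-normal. Dynamics are multiplicative: per interval, a spine may be
downscaled (probability ∝ sleep fraction) or upscaled (∝ wake fraction);
learning multiplies a 13.5% "boosted" subset by the boost factor; every spine
carries symmetric log-scale volatility (median 1). Boosted spines resist
post-training sleep downscaling with probability `learning_protection` — the
"smart down-selection" mechanism that yields the condition × learning
interaction. dsRed2 tracks the SEP log-increment with coefficient 0.8 plus
its own noise; shaft channels random-walk slowly. Additive measurement noise
(floored at a small positive value) is applied last; the noise-free
trajectory and all event labels are stored as ground truth, and recomputing
ND from the noise-free intensities reproduces the stored latent labels by
construction.

Turnover defaults (0.003/interval each way) reproduce the ~98% all-session
persistence of the emulated preparation; formation and elimination are
balanced by construction. Newly formed spines draw their baseline from the
lower half of the intensity distribution (new spines are small) — a modelling
choice, not an observed quantity. The volatility parameter controls the
within-spine across-time autocorrelation, which the emulated study does not
report; it is exposed as a free parameter and its default (0.20) was chosen
so that baseline up/down fractions at ND ±0.15 fall in the observed 12–20%
range.

Behavioral data: 20 trials × 2 sessions per mouse; session 1 improves
linearly within session for all mice; each mouse's session-2 onset is linear
in its true net post-training ND with noise calibrated per cohort so the
expected mouse-level correlation matches the target (−0.64). The calibration
budgets for trial-averaging noise; residual attenuation by spine-level
measurement noise and the n=12 sample leaves the realized mean correlation
near −0.55.

What the generator does **not** emulate: epoch-level sleep architecture (one
wake fraction per interval), image registration errors, spine-identification
ambiguity, trial-by-trial learning curves beyond the linear summaries, or
any spatial correlation of dynamics along a dendrite. Tests passing on this
generator show the pipeline's statistics are correct and calibrated under
the assumed data-generating process; they do not certify the biological
conclusions on real data.

## Image fixtures and quantification

The quantifier reproduces ROI-based two-channel spine photometry.
Coordinates: arrays are (z, y, x); physical positions in μm with the origin
at the centre of voxel (0,0,0); sub-voxel membership is voxel-centre
inclusion. Marks are filtered by strict thresholds (head width > 3 pixels,
protrusion > 6 pixels at the x/y voxel size). Each spine gets four ROIs on
the best plane ±1: a spineROI (disc of the stated width around the head,
minus the backbone tube's in-plane footprint), a shaftROI (tube footprint
within ±2 μm arclength of the spine's nearest backbone point — ties broken
toward lower arclength), and congruent background translates of both
(default 3 μm perpendicular; `choose_background_offset` picks the candidate
minimising background intensity, first-listed winning ties). After
background subtraction, spine SEP, spine dsRed2 and shaft SEP sums are
normalised to the **per-voxel mean** background-subtracted shaft dsRed2 of
the spine-adjacent shaftROI (one reading of "mean of the adjacent shaft
signal"; a session-global mean is the other reading and is not implemented).
Congruent backgrounds make the quantities exactly invariant to uniform
offsets, and the ratio normalisation to channel gain.

Fixtures render a straight dendrite (in-plane footprint of the stated
radius, smeared one z-step up and down as the axial PSF does at 1 μm
z-steps) and Gaussian spine-head blobs whose discrete kernels are normalised
so the rendered integrated intensity equals the stored truth exactly; shot
noise is Poisson at a stated photon scale. Placements closer than the
minimum separation are rejected (the quantifier assumes uncontaminated
spineROIs). On default-noise fixtures the quantifier recovers normalised
intensities within 5% (2% noise-free, the residual being ROI
discretisation).

## Pipeline and reproducibility

`run_pipeline` executes simulate → validate → ND/classification → turnover →
max partition → behavioral statistics → the four mixed models → both
mechanism fits, writing every table as CSV plus a JSON/text report carrying a
config hash and the seed. All stage seeds derive from one root seed via
`SeedSequence.spawn`, so identical configurations produce byte-identical
reports. Problem sizes in the shipped tests (cohorts of ~300–1600 spines,
1000-replicate null calibrations at 6×2×5 spines, 20-replicate recovery and
50-replicate selection experiments at 1000–1500 spines) were chosen so the
whole suite exercises every claim at meaningful precision on a single CPU.
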