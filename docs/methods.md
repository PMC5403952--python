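# Methods

## Data model

A trial is one stride of one subject, linearly resampled onto a 50-point
grid at every 2% of the gait cycle (0, 2, ..., 98% — a half-open cycle, so
sample 1 is foot strike and the next stride's foot strike is not
duplicated). Nine sagittal series are carried per trial: angle (deg),
moment (N·m/kg, normalized to body mass), and power (W/kg) for ankle, knee
and hip. Sign conventions: flexion/dorsiflexion positive, extensor moment
positive, power positive = generation; the pipeline is invariant to the
convention, but one must be fixed for the synthetic templates.

Sub-phase labels (1–7: loading response, mid-stance, terminal stance,
pre-swing, initial swing, mid-swing, terminal swing) are carried per sample
in the data file rather than derived from events, because pathological
gait has irregular sub-phase durations that the disparity networks consume
directly as input rows.

Raw-signal smoothing is a zero-phase (forward–backward) second-order
Butterworth low-pass filter, default cutoff 6 Hz at the native sample
rate — standard gait-kinematics practice; zero-phase application avoids
the lag that would shift sub-phase alignment. The cutoff is a config
parameter, not a derived quantity.

## Cyclogram pairs and the normal reference

The 36 coupled relationships arise from the unique enumeration consistent
with the group sizes 3/3/3/9/9/9: same-type groups (angle–angle,
moment–moment, power–power) pair distinct joints only; mixed groups
(angle–moment, angle–power, moment–power) take all 3×3 ordered joint
combinations with the first-named variable type as the x-variable — 3
within-joint plus 6 across-joint pairs.

The normal reference is the conventional pointwise trial average on the
percent-of-cycle grid (no time warping), justified by the stable sub-phase
durations of normal gait; pathological trials are never averaged. Each
variable's reference **range** (max − min of its mean curve) is the
normalization denominator for every downstream error statistic. By default
only left-side (non-dominant) trials enter references and analyses,
matching the support role of the prosthetic limb; the side is configurable.

## The disparity network

Architecture is fixed at 30 → 7 → 3 with linear activations. Inputs and
targets are range-normalized before training (variables via the reference
min/range, labels mapped linearly from 1..7 to [0, 1]) so the MSE < 0.9
acceptance bound is meaningful across pairs with heterogeneous units.

Training minimizes the column-wise squared error with **Levenberg–
Marquardt backpropagation** — the standard trainer for small feed-forward
networks. The Jacobian of the residuals with respect to all 241 weights
and biases is exact (the network is linear), so each damped Gauss–Newton
step solves the local quadratic model directly; damping starts at 1e-3,
shrinks ×0.3 on success and grows ×10 on failure, with at most 200
iterations. This matters numerically: the ten trial rows per variable are
nearly collinear, and first-order descent stalls in the resulting
ill-conditioned tail, whereas LM converges to the true least-squares
minimum — at which the composed 3×30 affine map of the network coincides
with the closed-form least-squares solution on the training columns (an
invariant the test suite checks at 1e-3).

Acceptance criteria per fitted network: (1) final training MSE < 0.9 on
the normalized scale; (2) validation and test MSE "similar", operational-
ized as |MSE_test − MSE_val| ≤ 0.5 × max of the two (threshold exposed in
config); (3) Pearson correlation between flattened predictions and targets
exceeding 0.9 on each of the 60/20/20 splits (columns are the sampling
unit). Weights are reinitialized (Glorot-scaled Gaussian, seeded) and the
split redrawn up to 10 times; a network that never passes is returned
flagged `accepted=False`, excluded from downstream tables with a warning,
and never used silently.

## Disparity statistics

Closeness: `C = (1 − e_pc) × 100`, with `e_pc` the mean over both
predicted variable curves and all 50 grid points of |predicted −
conventional| / range. Per-point normalized errors are clipped at 1 (one
full range = 100% error) so C always lies in [0, 100]. Subject-level C is
the mean over all accepted pair networks.

Per-sub-phase mean normalized error: the same per-point normalized errors,
unclipped, averaged within each sub-phase (using the subject's pointwise
modal labels across their ten trials) and over the two variable rows;
reported ×100. Sub-phases with no labeled sample are flagged missing
(NaN), never zero. Count-weighted per-phase errors recompose the global
`e_pc` exactly when no point exceeds the clip level. The per-phase maximum
over the 36 pairs (ties broken by canonical pair order, deterministically)
names the worst coupled relationship per sub-phase.

## Manipulation and dominance selection

Substitution replaces the chosen variable's values with the reference mean
curve at exactly the samples labeled with the target sub-phase — the
within-phase reading; it is idempotent and local by construction.
Manipulation operates on the ten-trial input rows, never on the targets
(which are the normal profile by construction), and the trained network is
never refitted.

A candidate variable is viable when its substitution reduces the own-phase
error and worsens neither cyclically adjacent sub-phase (LR and TSw are
adjacent at the stride boundary) by more than the neighbor tolerance.
Among viable candidates the lowest own-phase post-error wins; candidates
within the tie tolerance of the winner are all reported. No viable
candidate means no parameter is selected — the mid-swing outcome, which
reflects the ballistic-synergy interpretation: between initial and
terminal swing the shank extends passively under momentum and gravity, and
forcing any parameter there degrades the neighboring phases. Both
tolerances default to 5% relative error difference and are exposed in
config; the protocol describes ties and the no-parameter rule
qualitatively only, so the quantitative form is this package's choice.

Knee-only restriction: a selected hip/ankle variable is replaced by the
knee variable whose coupled pair with it has the lowest disparity-stage
error at that sub-phase (ties within tolerance keep both); knee selections
and "none" outcomes pass through. Cohort-level tables aggregate subjects
by majority vote, ties reported — the per-subject-to-cohort aggregation
rule is otherwise unspecified and is a deliberate design choice here.

## Synthetic data

Templates are periodic cubic splines through hand-set keypoints shaped
like standard normative sagittal gait curves (peak ankle push-off power
≈ 2.8 W/kg near 52% of the cycle, swing knee flexion ≈ 60° near 73%, and
so on). They are parametric approximations, not digitized from any source:
the analysis is validated by recovery properties (planted deficits found,
cohort ordering reproduced), not by curve identity.

Canonical sub-phase boundaries follow the standard Rancho/Perry
convention: LR 0–10%, MSt 10–30%, TSt 30–50%, PSw 50–60%, ISw 60–73%,
MSw 73–87%, TSw 87–100%.

Noise model: per-sample additive Gaussian noise (sd a fraction of each
variable's template range), smoothed with a short circular Gaussian kernel
so trials stay smooth, plus a constant per-subject offset shared across
that subject's trials. Sub-phase boundaries are jittered by rounded
Gaussian draws (sd in percent of cycle), preserving ordering and at least
one sample per phase. Per-phase amplitude scales and offsets follow the
trial's own jittered labels, so cohort deficits stay locked to their
sub-phase.

Default cohort profiles, ordered by clinical severity (the magnitudes are
free parameters chosen once a priori, since no quantitative description of
the pathological deviations exists to emulate):

| cohort        | deficits                                                        | jitter sd | noise sd | subject sd |
|---------------|-----------------------------------------------------------------|-----------|----------|------------|
| normal        | none                                                            | 0.5%      | 0.02     | 0.02       |
| orthosis      | all moments/powers ×0.85                                        | 1.5%      | 0.03     | 0.03       |
| transtibial   | ankle moment ×0.55, ankle power ×0.45, knee power ×0.85         | 2.0%      | 0.035    | 0.035      |
| transfemoral  | knee power ×0.25, knee moment ×0.30, stance knee angle ×0.5, ankle power ×0.55, ankle moment ×0.65 | 3.0% | 0.045 | 0.045 |

What the generator does **not** emulate: compensatory strategies on the
intact side, speed-dependent curve reshaping, non-sagittal planes,
ground-reaction forces, or realistic between-subject template variation
beyond constant offsets. Passing tests therefore demonstrate that the
pipeline recovers deficits of the planted, phase-localized,
amplitude-scaling kind under realistic noise — not that it reproduces any
particular clinical cohort's error magnitudes, which depend on real
subject data.

## Problem sizes and determinism

The default study conditions used by the test suite and the acceptance
script: 5 training subjects × 10 trials for the normal cohort (one
arrangement per subject, 250 columns per network), 10 subjects per cohort
for ordering checks, 5 held-out normal subjects for validation, 10/20
seeded replicates for the planted-signal recovery checks. Training all 36
networks takes about a second; the full pipeline a few seconds. Every
random draw — cohort generation, per-subject offsets, split selection,
weight initialization, restarts — derives from a single master seed via
spawned `numpy.random.SeedSequence` streams, so fixed-config runs are
byte-identical.

## Known limitations

* Exact reproduction of published per-subject error magnitudes is out of
  scope: they derive from real gait-lab recordings that are not deposited.
* The three output neurons are interpreted as (variable-a curve,
  variable-b curve, phase signal), the only reading consistent with the
  3-row target layout.
* With 30 near-collinear inputs and 250 columns the least-squares problem
  is well posed but ill conditioned; optimizers weaker than LM can return
  networks that pass the MSE/R gates yet sit measurably away from the
  least-squares map.
* The degenerate all-zero cohort profile generates (flagged with a
  warning) but produces a reference with zero range, which downstream
  stages reject by design.
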