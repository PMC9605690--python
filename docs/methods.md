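# Methods

This note documents the models, numerical procedures and design choices
behind `dnpop`, and what the synthetic-data tests do and do not establish.

## Signal model

ΔF/F is the calcium-activity proxy per ROI: 100·(F − F0)/F0, with F0 the
minimum over all of a fly's trials of the minimum sliding-window mean
(window 15 frames, stride 1) of the raw trace. Frames below a small
near-zero threshold (default 1e-6, a guard against motion-correction
padding) are excluded from baseline candidate windows; a non-positive
baseline is an error, not a silent NaN.

All regressors are related to fluorescence through the calcium response
function crf(t) = −e^(−a t) + e^(−b t) with a = 7.4 /s (rise) and
b = 0.3 /s (decay), sampled at the behavior frame period (0.01 s),
normalized by trapezoidal quadrature to unit integral on [0, 30] s.
Convolution is causal and happens on the 100 Hz grid *before* linear
interpolation to the ~16 Hz neural frame times (convolve-then-resample):
the kernel is smooth, behavior events are short, and convolving first
avoids aliasing the indicator edges.

## Cross-validated encoding models

Every encoding statistic rests on one regression core (`dnpop.regression`):

- **Folds** are contiguous temporal blocks within trials; every trial
  contributes one block to every fold. Fluorescence and behavior are
  strongly autocorrelated, so random frame-level folds would leak.
- **Ridge penalty** acts on regressors standardized to the training fold;
  the grid is logarithmic, 1e-3…1e3 (7 points), chosen per outer fold by
  nested fivefold blocked CV maximizing held-out R² (ties break toward the
  smaller penalty). The intercept is unpenalized (centering).
- **R²** follows 1 − SSE/SST on held-out blocks. Raw per-fold values are
  retained (they feed the Mann–Whitney tests); the summary value is the
  fold mean clipped below at zero. Clipping after averaging keeps a model
  that is merely noisy on one fold from being confused with one that is
  uninformative everywhere.
- **UEV** of a regressor group is R²_intact − R²_shuffled, where the
  group's rows are jointly permuted in time within each trial; 10 seeded
  permutations are averaged. The shuffled refits reuse the per-fold
  penalties of the intact fit — the shuffled model is a null reference,
  and re-tuning its penalty only adds variance. Both R² values are clipped
  at zero before differencing and the UEV itself is clipped at zero.
- All fits run on sufficient statistics (per-block Gram matrices), so a
  nested CV costs a few passes over the data; batched variants score many
  neurons against one target (the encoding map) or many targets against
  one design (odor UEV, residualization) in single passes.

Tie-break for behavior assignment at exactly equal maxima: the earlier
behavior in the fixed order walking, resting, head grooming, front leg
rubbing, posterior movements.

Context-dependent encoding restricts the single-neuron behavior model to
frames of one odor context. Contexts are equalized per trial to the same
number of equally long contiguous presentation blocks — air subsampled to
the odor amount as random contiguous segments, and the commoner odor down
to the rarer one — because held-out R² is biased by data amount and by the
autocorrelation structure of the sampled frames; comparing contexts with
unequal block counts produces spurious "context dependence". Folds inside
a context treat each presentation block as a unit so every test fold mixes
frames from several presentations.

## Behavior heuristics

Motion energy: each joint coordinate is convolved with the 8th-order
central finite-difference first-derivative stencil (length 9, per-frame
units), the L1 norm is taken across axes, and the result is low-pass
filtered (Butterworth order 10, cutoff 4 Hz). The filter is applied
zero-phase (forward–backward) so labels do not lag the kinematics; the
published order is interpreted as the design order of the one-way filter.
The cascade thresholds are the printed ones (0.5 mm/s forward velocity;
total energy < 0.3 for resting; front/hind energies 0.2; tarsus height
0.05), and the hysteresis filter (a state must hold 50 consecutive frames
to take effect, switching at the first frame of the qualifying run) is
re-applied to the cumulative label map after each cascade stage. The
tarsus-height split direction — raised tarsi (> 0.05) = head grooming — is
chosen from grooming biomechanics (forelegs sweep the head); only the
threshold value, not its direction, is fixed by the rule set.

Fictive trajectories integrate yaw into heading (wrapped to (−π, π]) and
advance the position by the body-frame velocity rotated at the midpoint
heading (second-order accurate; a circle of radius v/ω is reproduced to
0.01% at dt = 0.01 s). Roll contributes lateral translation only when a
ball radius is supplied.

## TV-regularized differentiation

The derivative u of a trace minimizes ‖A u − (trace − trace[0])‖² +
λ·TV(u), with A the running-sum operator and TV the total variation of u.
Substituting the antiderivative c = A u turns this into L1 trend filtering
of c with a second-difference penalty; the solver is a primal-dual
interior-point iteration on the box-constrained dual quadratic program,
with pentadiagonal Newton systems solved by banded Cholesky (O(n) per
iteration, ~40 iterations, deterministic). Default λ = 5000 in trace
units; the convergence criterion is a duality gap below 1e-5 relative to
the squared trace norm, which is far below the noise floor of any
derivative use here. As λ → 0 the estimate reduces to finite differences;
on a pure ramp the slope is recovered to better than 1%.

## Synthetic experiments

The generator's defaults are the study conditions all recovery tests run
under: 5 flies × 5 trials × 540 s, neural rate 16.4 Hz, behavior rate
100 Hz, 75–95 ROIs per fly.

- **Behavior** is a semi-Markov chain over walking, resting, head
  grooming, front leg rubbing and posterior movements with gamma dwell
  times (shape 4; means 5/4/3/2.5/2.5 s, floored at 0.8 s — the hysteresis
  filter makes sub-half-second states meaningless) and a transition matrix
  in which rest is predominantly followed by walking and head grooming by
  front leg rubbing, the two sequential confounds the disambiguation
  analysis must untangle.
- **Kinematics**: walking bouts get a bout-specific forward speed
  (mean 7 mm/s, s.d. 1.5, floored well above the 0.5 mm/s threshold) with
  150 ms cosine ramps at the edges; turns are raised-cosine yaw excursions
  (1–2 s, ±2.5 rad/s, Poisson rate 0.25 /s within walking). The pose proxy
  oscillates front/hind joints (amplitude 2.0, 2.5 Hz) so the motion-energy
  thresholds 0.3/0.2 separate moving from resting with a comfortable
  margin, and tarsus height sits at 0.15 during grooming vs 0.01 otherwise.
- **Odor schedule**: 60 s humid-air lead-in, then alternating 15 s odor /
  45 s air blocks (4 ACV + 4 MSC per 9-min trial). ACV multiplies the
  probability and dwell of walking by 1.6, speeds walking up by 1.3 and
  scales turn amplitude by 0.6 (more, faster, straighter walking); MSC
  scales walking probability by 0.8.
- **Neurons**: drive = planted weights on (behavior indicators, rectified
  yaw left/right, forward speed, odor indicators) at 100 Hz, convolved
  with the crf, resampled, plus white Gaussian noise (σ = 1 %ΔF/F).
  Class proportions: 30% walk, 12% head groom, 4% rest, 7%+7% turn, 5%
  speed, two neurons per odor, remainder non-encoding. Amplitudes (≈5–6
  %ΔF/F) give walking-class signal-to-noise around 2, i.e. single-neuron
  behavior R² in the 0.5–0.8 range typical of strong encoders. ROI
  positions draw from class-conditional Gaussians: grooming ventral,
  walking dorsal, turn classes lateralized at x = ∓16 μm.

Everything is a pure function of (config, seed), so regeneration is
byte-identical.

What the generator does *not* emulate: imaging noise structure (shot
noise, motion artifacts, bleaching by default — a linear drift flag
exists), nonlinear calcium dynamics and indicator saturation, behavior
kinematics beyond the threshold-relevant statistics, inter-fly variability
in encoding strength, and correlated noise across neurons. Passing
recovery tests therefore show that the pipeline's statistics are correct
and well-calibrated under their own model assumptions — not that real
recordings satisfy those assumptions.

## State space, decoding, densities, events

- **PCA** is fit per fly on TV-derivatives of the (non-denoised) traces,
  concatenated across trials, walking frames only; covariance PCA without
  per-neuron variance scaling since all traces share %ΔF/F units. Resting
  epochs are projected with the walking-fit mean and components. The
  high-loading rule w²_pc1 + w²_pc2 > 0.1 is evaluated on unit-norm
  component vectors.
- **Residual decoding**: residuals are ΔF/F minus the held-out-fold ridge
  prediction from convolved behavior regressors, so no frame is explained
  by a model that saw it. LDA decodes odor vs air at the frame level with
  classes balanced by seeded subsampling; shrinkage (Ledoit–Wolf, `lsqr`
  solver) is enabled whenever training frames < 5 × features. Scores are
  per (trial, fold) accuracies; feature sets are compared by a two-sided
  Mann–Whitney U test on those points.
- **Spatial densities** use Gaussian kernels with a log-spaced candidate
  bandwidth grid (0.5–50 μm, 25 points) selected by exact leave-one-out
  log-likelihood; the normalized map is KDE(subset)/KDE(reference), masked
  where the reference falls below 1% of its maximum. Known limitation:
  LOO maximum likelihood can collapse to the smallest candidate when the
  sample contains near-duplicate points; the 1D medial–lateral axis is x.
- **Events**: an epoch onset is isolated when no same-behavior epoch ended
  within the preceding second; blocks span [onset − 1 s, min(onset + 4 s,
  epoch end)). Pixel-mode averages re-baseline each block by its first
  five frames and are discarded when fewer than 50 blocks survive 1 s
  after onset; trace-mode averages use ΔF/F directly. Ward clustering runs
  on the condensed 1 − r distances directly (Lance–Williams update on the
  given dissimilarities, not a squared-Euclidean embedding), with scipy's
  deterministic leaf ordering.

## Problem sizes

The test suite and the acceptance script run the full default experiment
(5 × 5 × 540 s) for encoding, rotation and spatial recovery; odor UEV,
residual decoding (25 trial × fold score points) and the labeler check use
one fly of it; sequential-behavior disambiguation uses a dedicated
3-trial experiment with grooming forced to precede rubbing; PCA recovery
uses a 20-neuron rank-2 population. These sizes were chosen so every
recovery property is measured at the scale the corresponding analysis is
designed for.
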