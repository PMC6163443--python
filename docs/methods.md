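# Methods

This note records the modelling choices behind `gaitshift`: what each stage
assumes, which parameters matter and why their defaults are what they are,
what the synthetic generator does and does not emulate, and where the design
was genuinely open.

## The measurement model

A subject walks on a treadmill wearing four IMUs (lower back, lateral thigh,
lateral shank, foot dorsum) sampling tri-axial linear acceleration and
angular velocity at 100 Hz. Only the three proximal accelerometers feed the
movement-pattern model; the foot gyroscope exists solely to find gait
events. Two baseline sessions on separate days define "typical" gait; one
post-intervention session is scored against it.

### Attitude correction

A static accelerometer observes the gravity reaction, which fixes the
device's vertical but says nothing about heading. We therefore apply the
*minimal* rotation (about the axis normal to the measured mean and the
vertical) taking the standing-still window mean onto +Z, and leave the
horizontal axes as mounted, relabelled AP/ML by the manifest's declared
orientation. Preconditions: the window spans ≥ 0.5 s and its mean magnitude
lies within 20% of 1 g (`attitude.static_tolerance_g`), otherwise the sensor
was not at rest. Gravity is *not* subtracted from the vertical channel: the
later column standardization removes every column mean anyway, so a constant
offset is inert.

### Filtering

"4th-order recursive Butterworth at 10 Hz" leaves phase handling open. The
default is zero-phase: a 2nd-order design run forward and backward
(`filtfilt`, reflect padding of 3× order), whose net magnitude response is
4th-order at the cutoff; amplitude at 10 Hz is therefore ½, not 1/√2.
Zero phase is preferred because a causal filter's group delay (~tens of ms)
would systematically shift detected gait events; a literal single-pass
`causal` mode is available. Edge transients live in the first/last fraction
of a second and are discarded with the incomplete first/last strides.

### Event detection

The foot ML angular velocity has one dominant, high-SNR landmark per stride:
the positive mid-swing lobe. The detector anchors there (peak prominence
≥ 0.3 × the signal's 95th percentile, ≥ 0.6 s apart) and then applies the
definitional rules between consecutive anchors: IC = first
positive→negative zero-crossing after the lobe; TO = most negative sample
between that IC and the next lobe. Strides with IC→IC duration outside
[0.6, 2.0] s (generous bounds around ~1.1 s treadmill strides) are dropped,
and the longest contiguous run of surviving strides is kept so events form
one interleaved chain. The ML column and its sign come from the manifest —
axis guessing is deliberately refused. On synthetic data with realistic
noise, detected ICs sit within ±1 sample of truth; TO, which lies in a flat
trough, jitters by a few samples and is the dominant source of
"segmentation noise" in the cycle matrices (as it is in practice).

### Segmentation

Each stride is resampled by linear interpolation to 60 stance points
(including IC and TO) plus 40 swing points (ending at the next IC; the TO
sample is not duplicated), giving 100 points per channel and a 900-vector
per cycle in a fixed sensor-major layout (back, thigh, shank × AP, ML, V ×
stance-then-swing). PCA and the OCSVM are permutation-invariant to column
order, but the fixed layout makes persisted models and the waveform report
decodable. Linear interpolation introduces no overshoot; cubic is available.

## The subject-specific model

### Feature reduction

Baseline cycles are standardized column-wise with the baseline mean and
*population* SD (divisor m — an arbitrary but fixed convention, recorded
because it scales scores slightly), then decomposed by SVD. The smallest k
with cumulative explained variance ≥ 95% is retained ("at least 95%" read as
minimal k). Sign ambiguity is resolved by making each component's
largest-|loading| entry positive, so refits are bit-identical.
Zero-variance columns standardize to 0 and are excluded from variance
accounting. Post-intervention cycles are projected with the frozen baseline
constants; nothing is ever re-fit on post data (tests assert the model bytes
are unchanged by projection).

### One-class boundary and ν selection

The boundary is a Gaussian-kernel ν-OCSVM trained on the baseline PC scores.
Choices the method leaves open, and what this package does:

* **Kernel scale**: median pairwise distance among baseline score vectors
  (seeded subsample capped at 200) — scale-adaptive and subject-specific; a
  fixed numeric override is accepted.
* **ν selection**: every ν on a 0.05…0.95 grid (step 0.05) is fit on a
  seeded 80% split and evaluated on the held-out 20%; among ν with a
  held-out outlier rate strictly below 1%, the *largest* is selected — the
  tightest boundary still consistent with a ≤1% false-outlier rate, hence
  the most sensitive to post-intervention change. (`smallest` is available.)
* **Boundary offset**: by default ρ is calibrated to the minimum training
  kernel sum, so the boundary encloses 100% of the baseline cycles and ν
  controls only the boundary's *shape*. This is the behaviour of the
  standard commercial one-class SVM implementation used in this literature
  (bias re-estimated so that a configured fraction — default zero — of
  training observations scores negative), and it is what makes the <1%
  selection rule meaningful: with the raw dual offset (`bias="margin"`,
  also provided), the fraction of held-out cycles outside the boundary
  tracks ν itself, so no grid value could ever satisfy the criterion.
* **Split policy**: a single random 80/20 split, literally. With ~54
  held-out cycles, "<1%" means "0 of 54", so one atypical baseline cycle
  landing in the split fails every ν. When that happens the pipeline
  escalates to the averaged repeated-split estimate (5, then 25 splits)
  before declaring the subject untrainable; roughly 2% of synthetic
  subjects genuinely never qualify, and a cohort run isolates them.

Scoring is an independent kernel summation over the stored support vectors
(never a call back into the fitting library), so persisted boundaries are
portable; tests verify the decision values against a generic quadratic-
program solution of the one-class dual.

### Change statistic and clinical association

The movement-change statistic is the percentage of post-intervention cycles
with negative decision value. Clinical improvement is the mean of the four
KOOS subscale changes (post − pre), clipped below at zero — the question is
whether gait deviation tracks *improvement*, so deteriorations are "no
improvement" rather than negative evidence. Association is Spearman's ρ on
(outlier %, clipped improvement); for n ≤ 9 the two-sided p comes from the
exact permutation null over all n! orderings (feasible and exact where the
t approximation is dubious), with mid-rank ties. Magnitude labels:
negligible < 0.10 ≤ small < 0.30 ≤ medium < 0.50 ≤ large. Pearson's r is
reported as a supplement, computed on the same clipped changes.

### Waveform report

Per (sensor, axis, phase-point): Welch's two-sample t-test (between-session
variances need not match; a pooled-variance option exists),
Holm–Bonferroni step-down across all 900 points jointly (the conservative
family; per-sensor correction is a config option), and a flag only where
adjusted p < 0.05 *and* |Cohen's d| > 0.8. Cycles are treated as independent
observations; stride-to-stride autocorrelation inflates the effective n and
is a known, uncorrected limitation of per-cycle analyses.

## The synthetic generator

`gaitshift.synth` emulates the study design: 2 s standing (for attitude
correction) + 2.5 min walking per session at 100 Hz, stride time 1.1 s
(jitter SD 0.03 s), stance fraction 0.60, two baseline days plus one post
day, paired KOOS records. Per-channel stride templates are small Fourier
series (6 harmonics, 1/h amplitude decay) with site-scaled oscillation RMS
(back 1.2, thigh 1.8, shank 2.6 m/s²; AP 60%, ML 40% of vertical; +1 g DC on
vertical channels). The foot ML gyro template is a periodic spline with the
canonical event morphology (zero-crossing at IC, −150 deg/s trough at TO,
+300 deg/s mid-swing lobe), so detector accuracy is measurable against
exact ground truth.

Stride-to-stride variability is driven by a few latent factors acting
*nonlinearly* — a multiplicative amplitude gain (SD 6%), two periodic phase
warps (SD 1.5% and 1.0% of the cycle) and stride-time jitter — plus additive
smooth per-stride noise (0.05 m/s² RMS) and white measurement noise
(0.02 m/s²). The nonlinearity is the point: time warps curve the cycle
distribution so that ~30 linear PCs are needed at the 95% threshold while
the intrinsic dimension stays low, which is also what makes a tight
one-class boundary with a near-zero false-outlier rate attainable — the
qualitative geometry of real gait data. Latent draws are truncated at
±2.5 SD: stride variability in a controlled treadmill session is
physiologically bounded, and unbounded tails would make single wildly
atypical cycles routine.

Between-day effects are additive smooth template perturbations (0.008 m/s²
RMS) plus a small day-level warp offset (0.004) and a fresh mounting tilt
(5° ± 2° about a random horizontal axis, exactly recoverable by the
attitude correction since no yaw is applied). Day effects are deliberately
well below stride noise — consistent with re-mounted sensors in a
controlled protocol — so that a no-intervention subject is statistically
exchangeable between sessions at the waveform report's effect-size gate.

The intervention is an additive template shift: a fixed smooth unit-RMS
profile across the nine channels (site weights thigh 1.0 > shank 0.7 >
back 0.4) scaled by `shift_delta` (m/s² RMS). Default cohorts use 8
subjects with deltas evenly spaced over 0–0.25, which spans outcomes from
0% to ≈100% post outliers; simulated KOOS improvement is 120·delta points
(≤ 30) plus noise (SD 2), clipped to [0, 100].

What the generator does **not** emulate: impact transients and
high-frequency content above the 10 Hz band, asymmetric or pathological
waveform shapes, turning or overground bouts, sensor drift/bias
instability, and any biomechanically validated forward dynamics. Passing
tests therefore demonstrate that the machinery recovers known structure
under realistic cyclic variability — not that it would detect any
particular clinical pathology.

## Problem sizes used in checks

The automated checks run the full chain at the protocol's native scale
(2.5-min sessions, ≈135 cycles/session, ≈270 baseline cycles per subject):
20 seeded subjects for the cycle-count statistics, one full subject for the
ν-selection criterion, 50 seeded 8-subject cohorts (via the generator's
direct cycle-bank path, which skips signal synthesis and event detection
but keeps the identical cycle statistics) for the association-recovery
property, and 200 replicates for the waveform null control.

## Known limitations

* TO detection picks the minimum of a flat trough and jitters by a few
  samples; this propagates into normalization as phase noise.
* The held-out <1% rule is a hard quantile on a ~54-cycle split; it is
  intrinsically unstable at this n (see split policy above).
* With the calibrated offset, the boundary hugs the most extreme baseline
  cycle; a contaminated baseline (e.g., a stumble) would loosen it. No
  robustification is applied because the method's definition of "typical"
  is exactly "what baseline contained".
* Waveform-report inference treats cycles as independent.
* Spearman p-values at n = 8 have a granular permutation null; "p = 0.02"
  resolutions below 1/8! are not meaningful.
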