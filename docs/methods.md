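# Methods

`lithofocus` rebuilds, end to end, the analysis behind AI-gated
extracorporeal shockwave lithotripsy (ESWL): estimate how often
operator-controlled treatment actually hits the stone, train a U-Net to
segment the stone in ultrasound frames, gate firing on the segmenter's
output, and quantify what gating buys in hit rate and avoided mishits.
The clinical raw data (ultrasound videos of 11 patients) are private;
what is reproducible from public information are the aggregate counts —
a test-set confusion matrix over 18 440 frames and per-patient
frames-in-focus tallies over 23 212 frames — and everything derived
from them. Those counts ship as package fixtures. The image pipeline
itself is exercised on synthetic data with known ground truth.

## Synthetic ultrasound model

The generator emulates the features the pipeline consumes, not acoustic
physics.

**Geometry.** A 64×64 8-bit frame contains a kidney ellipse
(semi-axes 24×27 px) on a dark background, a bright elliptical stone
echo (default semi-axes 4×3 px), and a fixed focal zone, by default an
ellipse of semi-axes 7×9 px. Piezoelectric focal zones are ellipsoidal,
and an elliptical zone keeps the overlap computation exact by pixel
counting; a rectangular zone is also supported. Coordinates are
row-major with the origin top-left, positions are (x, y) with x the
column, masks are {0,1} arrays.

**Motion.** Respiration carries the stone along a line in the imaging
plane with displacement

    s(t) = A · sin^(2p)(π (t/T + φ)),

where T is the respiratory period (default 4 s), A the amplitude
(default 22 px) and p ≥ 1 the *dwell exponent* (default 2). The even
sine power has flat minima: the stone is nearly stationary around
end-expiration and transits quickly mid-cycle, which is exactly the
clinically observed pattern (and the window a gated lithotripter would
exploit). p = 1 gives raised-cosine motion; large p approaches a stone
that is parked except for brief excursions. A *dwell offset* shifts the
end-expiration resting point away from the focal-zone centre: offset 0
is a perfectly targeted treatment, large offsets a poorly targeted one.
The real 3-D stone path is projected to 2-D here; the imaging-plane
relationship of the clinical system is not public, so the projection
direction is simply a configurable unit vector (default mostly
cranio-caudal).

**Appearance.** The intensity map (background 40, kidney 95, stone 230)
is degraded by multiplicative gamma speckle of unit mean (shape 6), the
standard first-order B-mode emulation; the column band beneath the
stone is attenuated by up to 50% with a 15-px decay length to imitate
the acoustic shadow of a calcified stone — a deliberately confusable
dark feature for the segmenter. Frames are rendered from a per-frame
random stream keyed on (sequence seed, frame index), so any frame is
reproducible in isolation and whole sequences are byte-identical across
runs.

**Ground truth.** Each frame carries its exact stone and kidney masks,
the pixel-counted overlap fraction with the focal zone, and the binary
label `overlap ≥ 0.5`. By construction the generator's labels agree
exactly with the gating rule applied to its own masks — an invariant the
tests enforce frame by frame.

**Cohorts.** `simulate_cohort` draws per-patient variations of
amplitude (±35%), stone size (±25%), respiratory phase, dwell exponent,
and — decisively for the hit rate — dwell offset (0–16 px), all scaled
by a jitter parameter in [0, 1]. At jitter 1 the per-patient hit rates
spread over roughly 20–90%, matching the heterogeneity of the clinical
cohort (21.3–89.0%); at jitter 0 all patients share one label track and
the pooling test accepts homogeneity. Defaults are 11 patients with 200
frames (13.3 s) each.

What the generator does **not** model: RF-level speckle correlation,
probe retraction artifacts, stone fragmentation over the treatment
course, out-of-plane motion, or annotator subjectivity. Passing the
synthetic end-to-end test therefore shows the pipeline's logic is
sound, not that the network would reach clinical-grade accuracy on real
ultrasound.

## Annotation scheme

Labels are stored either per frame (0 = out of focus, 1 = in focus) or
as transition records — (start frame, label) pairs marking where the
state changes — because a stone stays in or out of focus for runs of
frames. Expansion and compression are exact inverses on valid input; a
transition list ending before the last frame extends its final label to
the end. Frame indices are 0-based everywhere; clinical narration of the
"tenth frame" is 1-based and converts at the I/O boundary. Window
sampling (uniform start of a fixed-length annotation window in a longer
video) and label corruption (independent flips at a target mismatch
rate, emulating the 37.5% interobserver disagreement measured between
the two clinical annotators) support study-design experiments.

## Segmentation network

The architecture is the canonical U-Net: an encoder of two 3×3
convolution + ReLU layers per stage with 2×2 maximum pooling, a
bottleneck, and a decoder of 2× nearest-neighbour upsampling stages
whose features are concatenated with the symmetric encoder features
before two further convolutions; a 1×1 head emits two channels. The
stone and kidney channels are independent sigmoids rather than
mutually exclusive classes because the stone lies inside the kidney;
marking the kidney gives the network contextual information about where
a stone can be.

The implementation is written directly on numpy (im2col convolutions,
explicit backprop, Adam) and is validated against central finite
differences in the test suite. At the default depth 3 and 8 base
channels the network has ~120k parameters and trains in under a minute
on one CPU core — the architecture, not capacity, is the object of
interest, and no GPU framework is required.

Training choices (none of which are published for the clinical model,
so all are declared package defaults): per-channel positively weighted
binary cross-entropy with stone weight 20 (a stone covers ~1% of a
frame; the unweighted loss is minimized by predicting no stone), Adam
at 3·10⁻³, batch 8, at most 30 epochs, early stopping with patience 5
returning the weights of the epoch with minimum validation loss. One
integer seed controls initialization and shuffling; there is no
augmentation. Images are bilinearly resized at the prediction boundary
if needed, masks nearest-neighbour.

Cross-validation is patient-based rotation: with n patients there are n
folds; fold i validates on patient i, tests on patient i+1 (cyclic),
and trains on the rest, so each patient validates exactly once and
tests exactly once, and no test-patient frame ever influences the
weights of its fold.

## Focal-zone gating

A predicted mask becomes a firing decision by exact pixel counting:
overlap = |stone ∩ zone| / |stone|, in focus iff overlap ≥ 0.5 — the
boundary counts as a hit, enforced verbatim. Disconnected mask
components are treated as one stone (their union). Masks under 5 pixels
are *no detection*: some emptiness criterion is needed (the clinical
detector reported no stone in 20.6% of frames, but its criterion is not
public) and 5 px suppresses speckle-sized fragments. Two policies
resolve no-detection frames: exclusion (drop and count, the primary
analysis) or conservative relabeling as out-of-focus (an undetected
stone is never fired upon); exclusion retains 18 440 of 23 212 frames
on the clinical counts. Raising the threshold can only turn in-focus
calls into out-of-focus ones, never the reverse.

## Evaluation

Standard confusion-matrix metrics, each computed at full precision and
rounded only for display (one decimal in percent, four for κ):
accuracy, sensitivity, specificity, PPV, NPV, prevalence, detection
rate, detection prevalence, balanced accuracy = (sens + spec)/2,
Youden's J = sens + spec − 1, no-information rate =
max(prevalence, 1 − prevalence), and Cohen's
κ = (p_o − p_e)/(1 − p_e) with p_e from the marginals. Undefined ratios
are reported as NaN rather than raised so degenerate synthetic runs
still produce reports. PPV equals the hit rate of gated firing — fire
only on in-focus calls and the fraction of shots that hit is exactly
PPV — which makes it the clinically decisive metric.

Efficiency arithmetic, at a continuous firing rate of 90 pulses/min:
relative treatment time = annotated-in-focus / TP (gated firing skips
frames, so matching the operator's hit count takes longer); mishit
ratio = relative treatment time × FP / annotated-out-of-focus; mishit
reduction is its complement; hits/min are rate-scaled fractions of
annotated frames. One documented subtlety: the clinical methods text
describes the mishit computation with the *true negatives*, but the
actual published arithmetic uses 1961, the *false-positive* count.
The FP form is implemented — mishits are shots fired while the stone is
out of focus, which is what false positives are — and the report notes
the basis explicitly.

The conservative-policy variant recomputes the suite over all frames
with no-detections as out-of-focus decisions. Reconstructing that
matrix from the published marginals gives sensitivity 51.5% and
specificity 83.1%; the clinical report prints 51.2%/83.0%, a ~0.3-point
gap whose source (their exact alternative matrix) is not public, so
these are consistency checks rather than exact targets.

## Hit-rate statistics

**Pooling test.** Whether frames may be pooled across patients is a χ²
goodness-of-fit question: expected hits E_i = n_i × pooled rate, with
the pooled rate Σ hits / Σ frames; χ² = Σ (O_i − E_i)²/E_i over the
*hit-count cells only*, df = k − 1. The hit-cells-only construction is
an inference: it reproduces the published statistic (927.4 at pooled
rate 50.12%) exactly, whereas including the miss cells roughly doubles
it. On the clinical tallies the test rejects emphatically, so the
cohort summary must resample patients, not frames.

**Bootstrap.** The resampling statistic at both levels is the mean —
the hit proportion of resampled frames at patient level, the mean of
resampled per-patient rates at cohort level — and the reported "median
hit rate" is the median of that bootstrap distribution. This
convention, a bootstrap median *of a proportion*, is what the published
numbers pin down: the per-patient point values equal n_focus/n_total to
one decimal, the cohort point value 55.2% equals the mean of the eight
rates, and the cohort interval 43.2–67.3% is reproduced by BCa on the
mean (BCa on the sample median gives ≈ 47.9–61.2 and cannot match).
Defaults are 5000 resamples at frame level and 3000 at patient level.

Intervals are bias-corrected and accelerated: z₀ = Φ⁻¹ of the fraction
of bootstrap statistics strictly below the plug-in value (the Efron
convention, also R's), acceleration from jackknife skewness
a = Σd³ / (6(Σd²)^1.5) with d the deviations of leave-one-out
statistics from their mean (closed form for the mean statistic), and
the interval endpoints are the adjusted-level quantiles of the
bootstrap distribution. Constant data give a degenerate interval equal
to the constant. The implementation is cross-checked in the tests
against `scipy.stats.bootstrap(method="BCa")` on common data.

Reproducibility envelope: with 5000 resamples the per-patient interval
endpoints vary by ~±0.1–0.2 points across seeds and land within ±0.5
points of the published values. The one systematic offset is the
smallest patient (438/492 frames), whose published lower bound of 86.2%
sits ~0.4 points above what BCa reproducibly yields; R's own `boot`
package centres at the same 85.8% on these data, so the residual is an
artifact of the original single bootstrap draw, not of this
implementation.

**Convergence.** One resample stream is drawn once and the tracked
percentile (default the 95th) is evaluated on growing prefixes; the
relative change between consecutive grid points falls below 1% past
2000–3000 resamples on the clinical rates, which is the rationale for
the 3000-sample patient-level default.

**Normality.** Skewness and kurtosis z-scores follow the small-sample
convention of the SPSS-style GUIs used in the original analysis:
bias-corrected G1 and G2 divided by SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3)))
and its kurtosis analogue, plus the Shapiro–Wilk p-value. On the eight
clinical rates: skew z = −0.005, kurtosis z = 1.73, Shapiro–Wilk
p = 0.33.

**Calibration.** On simulated Bernoulli frame data (n = 3000, p = 0.55)
the 95% BCa interval covers the true rate in ~95–96% of replications;
the acceptance machinery checks the 93–97% band.

## Problem sizes for the packaged runs

The reference checks are deterministic and instant apart from the
bootstraps (seconds). The scaled synthetic study used by the tests and
the acceptance script is 11 patients × 200 frames, ~57 annotated masks,
and two trained cross-validation folds (~400 held-out test frames,
about two minutes of CPU); training all 11 folds is a one-line change
(`n_folds=None`) and takes ~10 minutes. On this easy synthetic task the
trained segmenter is near-perfect (held-out Dice ≈ 0.95), so the
qualitative contract — held-out PPV strictly above cohort prevalence —
holds with a wide margin; the clinical gap (75.3% vs 58.0%) is not a
numerical target, since the original images and weights are
unavailable.

## Known limitations

- The synthetic task is far easier than clinical ultrasound; absolute
  synthetic metrics say nothing about clinical performance.
- Focal-zone geometry, image resolution, and the clinical detector's
  no-detection criterion are free parameters, not published facts.
- The χ² cell construction and the bootstrap statistic conventions are
  inferred from matching the published arithmetic, as documented above.
- Single-observer ground truth: the corruption model treats
  interobserver disagreement as independent per-frame flips, which
  ignores the run-structure of real disagreement.
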