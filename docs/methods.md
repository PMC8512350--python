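# Methods

## Eye-state classification

Each frame is classified per eye by normalized-correlation template matching.
The match score between a candidate patch `p` and a template `t` of the same
shape is the Pearson correlation coefficient of their pixel intensities,
clamped below at 0 so the score lives in [0, 1]; anti-correlated patches are
treated as "no match" rather than as negative evidence. The score is
undefined (a degenerate-input error) when either patch has zero intensity
variance; at run time a zero-variance candidate patch (e.g. one that is
entirely zero-padding) leaves that eye unclassified instead of erroring.

A calibration set holds K template pairs (default K = 3) cut from operator-
selected open-eye frames, all sharing one patch size, plus the acceptance
threshold (default 0.68). Classification scans templates in order and stops
at the first score ≥ threshold (eye open); the eye is closed only when all K
scores fall below. Early stopping is exactly equivalent to testing the
maximum score, which the tests verify by enumeration. The frame is *combined
closed* only when both eyes are closed; if either eye is unclassified the
combined state is *missing*, never closed — a deliberate asymmetry that
avoids fabricating closures from incomplete evidence.

Eye centres come from an injected landmark provider (any face-landmark engine
can be wrapped; the synthetic provider returns the rendered centres, and the
CLI uses fixed centres stored in the calibration file, appropriate for a
rigidly mounted camera). Patches are fixed-size rectangles centred on the
provided coordinates with the calibration's patch size; portions outside the
frame are zero-padded and flagged. The patch size itself is configuration:
there is no single natural choice, so it is taken from the calibration
regions (28 px square in the synthetic geometry).

Unclassified frames are retained and can be resolved only through an override
file (CSV of inclusive frame ranges with a target state; later rows win on
overlap), mirroring a manual review workflow rather than silently imputing.

The partial-closure convention — an eye whose pupil is ≳ 75% covered counts
as closed — is carried implicitly by the open-eye templates and the 0.68
acceptance threshold; no separate pupil-coverage estimator exists, by design.

## Event segmentation

Closure events are the maximal runs of combined-closed frames. Missing-state
frames terminate runs and mark the adjacent fragments (and any event touching
the series edges) as *truncated*; gaps are never bridged. An event is a
*blink* when its duration is ≤ the blink cutoff and *qualifying* otherwise.
The cutoff is primary in milliseconds (200 ms) and derived in frames as
`round(200 · fps / 1000)` — 12 frames at 60 fps, 6 at 30 fps — so non-60-fps
recordings rescale correctly. Only qualifying events enter any indicator.

## Windowed indicators

Windows tile the recording consecutively without overlap: half-open frame
ranges of `N = round(window_s · fps)` frames (1800 at 30 s / 60 fps). A
trailing partial window is reported with its true frame count and flagged
incomplete; summaries use complete windows only.

PERCLOS is a time fraction, so a qualifying event spanning a boundary
contributes its per-window frame counts. ECD and FEC are event-level
statistics, so each qualifying event belongs wholly to the window containing
its start frame, with its full duration; this preserves the duration
distribution at the cost of letting an ECD numerator exceed the window
length in pathological cases. ECD over zero qualifying clusters is *missing*
(a mean over an empty set), never 0, and missing ECDs are excluded from
session means with the contributing window count reported.

Fatigue flags use strict inequalities ("above"): PERCLOS > 0.15,
ECD > 400 ms, FEC > 5. A missing ECD never flags. Unclassified frames stay in
the denominator N (N is fixed per window) and are counted; windows with more
than 10% unclassified frames (configurable) are flagged low-confidence.

Session summaries are arithmetic means of the first and last min(10, count)
complete windows of each indicator — five-minute heads and tails at the
default geometry — matching a pre-test/post-test design.

## Synthetic data

`generate_session` draws Poisson numbers of blinks and drowsy closures,
places them without overlap (rejection sampling with bounded retries), and
emits a per-frame aperture signal: open frames jitter in [0.9, 1], event
frames in [0.02, 0.2], so thresholding at 0.25 of full opening — the
synthetic analogue of the 75%-coverage convention — recovers the ground-truth
mask exactly. Blink durations are truncated normal (default 110 ± 30 ms,
capped at 200 ms); closure durations are 200 ms plus a lognormal
(heavy-tailed, always above the cutoff; durations are converted to frames
with a ceiling so quantisation can never turn a closure into a blink). The
`drift` parameter ramps closure rate and duration linearly by a factor
(1 + drift) across the session, emulating fatigue accumulating during a
drive. Default profiles were set analytically from rate × mean-duration so
that mean session PERCLOS lands near real rested (~0.05) and drowsy (~0.13)
drivers; the drowsy profile crosses the 0.15 flag threshold in occasional
windows, as real drowsy recordings do.

`render_frames` draws two dark ellipses (semi-axes 10 × 6 px) on a bright
background whose vertical opening follows the aperture, with a residual lid
line when closed, plus i.i.d. Gaussian pixel noise (default SD 0.02 in [0, 1]
intensity units). The geometry is chosen so that open-vs-open patch
correlations sit well above 0.68 and open-template-vs-closed correlations
well below it. What the renderer does **not** emulate: head pose and motion,
illumination changes, landmark jitter, eyelash/eyebrow structure, specular
reflections, or asymmetric eyes. Passing end-to-end tests therefore
demonstrate the correctness of the pipeline's logic, not the robustness of
template matching on real faces.

`generate_fss_dataset` simulates the three-level subjective-fatigue process:
`fss = b0 + b1·occasion + b2·indicator + u_subject + u_condition + ε`, with
independent normal random intercepts per subject and per condition-session
within subject. Defaults (intercept 25, time slope 5, indicator slope 10,
variances 200/230/170) sit near magnitudes estimated for real drivers. Three
named indicator columns (`perclos`, `ecd`, `fec`) share one marginal
distribution (unit normal plus a +1 shift in the drowsy condition); the
active one — `ecd` by default — drives the response, the others are null
predictors, so model-comparison output shows one informative and two
uninformative indicator models. The `indicator` column aliases the active
one.

## Statistical evaluation

The three-level model is estimated by maximum likelihood through statsmodels'
`MixedLM` (subject grouping, a variance component for condition-within-
subject); the model specification, and all derived quantities below, are
owned by this package. The indicator predictor is z-standardised over all
rows before entry. `converged` reports the optimizer's own flag; variance
components are clipped at 0. Parameter count is fixed effects + 2 random-
intercept variances + 1 residual variance, and AIC = 2k − 2ℓ.

- ICCs (intercept-only model): each level's variance over the three-level
  total. Requested on any other model, the call errors.
- Marginal/conditional R²: σ²_fixed over total (marginal) and fixed + random
  intercepts over total (conditional), with σ²_fixed the population variance
  of the fixed-effect linear predictor.
- ΔR² per level: (σ²_ref − σ²_new)/σ²_ref between nested fits; negative
  values (variance increases, common when a level-1 predictor soaks up
  between-group variance) are reported unclipped; a zero reference variance
  yields a missing value.
- Model comparison: likelihood-ratio χ² with df equal to the parameter
  difference. The default reference ladder tests model 2 against model 1 and
  every later model against model 2. Note that a χ² of 5.673 on 1 df gives
  p ≈ 0.017 — significant at 0.05, not at 0.01; published tables sometimes
  star such values inconsistently, and this package always reports the
  computed p.

Paired comparisons use the paired t (one-sample t on differences, df = n−1)
with a dependent-samples Cohen's d in the correlation-corrected form
d = t·√(2(1−r)/n), which reduces to mean difference over the common SD when
the occasions share a standard deviation; there is no single canonical
dependent-samples d, so the formula is documented and swappable
(`method="dz"` gives mean difference over the SD of differences). Two
identical samples return t = d = 0; a constant non-zero shift (zero-variance
differences, undefined t) errors.

ROC analysis uses the Mann–Whitney rank AUC (ties count ½), a stratified
within-class percentile bootstrap for the 95% CI, and a Youden-optimal
threshold chosen among midpoints of adjacent distinct scores (positive
predicted strictly above threshold). Higher scores are always treated as
evidence for the positive class; no automatic direction flipping.

## Numerical and scaling choices

All stochastic operations take explicit seeds; nothing touches global random
state. CSV exports use `%.17g` so values round-trip exactly; missing ECDs
serialize as empty fields. The test suite and the acceptance script run
end-to-end renders at 60 s × 60 fps on 64 × 96 px frames, mask-oracle checks
on 1,000 random masks at a reduced window geometry (2 s windows at 30 fps,
which exercises identical code paths at lower cost), and mixed-model recovery
at 200 subjects × 100 replicates — sizes chosen to keep a full run in the
low minutes on one CPU while leaving Monte-Carlo error far below the margins
being tested. Single-fit variance-component estimates at 200 subjects carry
~25% sampling SD at the subject level, so component recovery is asserted on
replicate averages (unbiasedness), while slope recovery is asserted as 95% CI
coverage across replicates.

## Known limitations

- The renderer's idealised geometry means classification accuracy on real
  video is untested here; the landmark provider and template threshold would
  need re-validation per camera setup.
- MP4 decoding requires an ffmpeg-capable imageio backend; PNG frame
  directories are the always-available path.
- The mixed model assumes Gaussian errors and random intercepts only; random
  slopes for time are not modelled (they can be added upstream in
  statsmodels if needed).
- With only two occasions per session, within-session fatigue change is
  identified as a linear trend only.
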