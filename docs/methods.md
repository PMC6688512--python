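# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `gaitresp`, in the order the pipeline runs them.

## Coordinate and unit conventions

All marker positions are stored in millimetres in a lab frame with +Y
anterior (walking direction), +Z vertical, +X to the subject's right;
reported lengths are metres, angles degrees.  The anterior axis is
auto-detected per trial as the axis of largest net sacrum displacement,
with its sign from the net displacement, so trials recorded walking in −Y
or along X are handled identically.  Frames are indexed from 0; step
windows are half-open `[HS_i, HS_i+1)` per side (one stride each).

## Signal conditioning

Gaps (NaN runs) in any marker channel are filled by linear interpolation;
a run longer than 0.1 s, or more than 10% of a channel missing, rejects
the trial — longer drop-outs cannot be reconstructed credibly at gait
frequencies.  Filtering is a zero-lag Butterworth low-pass at 6 Hz:
"fourth-order zero-lag" is interpreted the way gait laboratories usually
mean it, a 2nd-order design applied forward and backward (effective 4th
order, squared magnitude response, so the gain at the design cutoff is
0.5); a strict 4th-order-per-pass mode is available
(`filter_strict_order`).  The filter demands a series at least three
warm-up lengths long, rejecting degenerate clips.

## Event detection

Heel strike is the local maximum of the heel's anterior position relative
to the sacrum; toe off is the local minimum of the toe's.  This
coordinate-based rule needs no force plates, is invariant to walking
direction, and is verifiable against the simulator's ground-truth event
times (noise-free trials agree within 3 frames at 300 Hz; 1 mm marker
noise within 6).  A velocity-threshold fallback is selectable
(`method="velocity"`).  Detected events are forced to alternate
HS→TO→HS per side starting at a heel strike; trials with fewer than three
heel strikes on either side are rejected.

## Steady-state selection

Per subject-session at least six trials are required.  The first trial is
treated as familiarisation and dropped; in each remaining trial the first
and last two steps per side (acceleration/deceleration) are excluded and
the central two steps per side retained — with an even number of
candidates the tie is broken toward the later pair, favouring the more
settled gait.  Five retained trials × two sides × two steps ≈ 20 analysed
steps per subject-session.

## Spatio-temporal variables

Within the retained windows: stance % is (toe-off − heel-strike)/stride;
double support is the *initial* per-side double support (own heel strike
to contralateral toe-off, as % of stride) — whether published per-side
double-support values are initial or halved-total is generally ambiguous,
so the choice is labelled explicitly.  Step length is the anterior
heel-to-heel distance at the closing heel strike; because a 6 Hz zero-lag
filter rings for tens of milliseconds around the contact corner, each
heel's landing position is read as the median of its stance-phase plateau
rather than the instantaneous sample, which recovers generated step
lengths to well under 1%.  Step width is the mediolateral analogue.
Speed is sacrum displacement over the windows' span; cadence is two steps
per stride window.  Per-subject aggregation is the mean over retained
steps/trials; the asymmetry index is computed from the per-side *mean*
step lengths (stable at ~20 steps), with the mean of per-step indices
also reported (`spatial_asymmetry_per_step_pct`) since the two differ on
heterogeneous gait.  For controls, who have no affected side, the min/max
form is side-agnostic and needs no side assignment.

## Joint and trunk angles

Only sagittal lower-limb angles are reported, so a full Euler sequence is
unnecessary: with a flexion-first (mediolateral-axis-first) convention the
reported angle is the difference of the two segments' sagittal-plane
inclinations.  Thigh is ASIS→knee vs the pelvis vertical (from the
ASIS/sacrum plane), knee is thigh vs shank (knee→malleolus), ankle is
foot pitch (heel→toe) vs shank.  Trunk flexion-extension and lateral
bending are the pelvis-centre→mid-acromion segment against the pelvis
vertical in the sagittal/frontal planes; trunk axial rotation is the yaw
of the acromion line in the lab frame.  RoM is max − min over the union
of retained windows.  Degenerate (zero-length) segments raise.

## The synthetic forward model

`generate_trial` renders a 13-marker walking trial (sacrum, L/R ASIS,
knee, malleolus, heel, toe, acromion, C7) from a `GaitProfile`.  The
marker set is deliberately minimal: it is exactly the set the measurement
chain consumes, not a reconstruction of any laboratory's full model.
Two coupled constructions share a constant-speed pelvis:

* **Feet and events.**  Each heel alternates a stationary stance plateau
  and a swing that advances one stride length, on a periodic schedule
  with the two sides offset by half a stride; landing offsets are chosen
  so each side's step length equals the profile's value exactly.  The
  swing displacement uses a trapezoidal-velocity profile with short
  (≈20 ms) ramps so the velocity transition at touch-down is sharp enough
  for the coordinate-based detector to localise events to a few frames.
  Stance fraction places toe-off; by periodicity the initial double
  support equals stance % − 50, so generated profiles enforce that
  identity.
* **Joint angles.**  Thigh and knee curves per side are one shared smooth
  two-harmonic periodic template (unique extrema per cycle, range
  normalised on a dense grid) scaled to the hip and knee RoM; the shank
  angle is then a scaled copy of the same template, and the ankle curve
  reuses it too, so every extracted RoM equals its target identically.
  The foot-pitch channel is solved backward from the ankle target.  Trunk
  tilt/bending/yaw oscillate with amplitudes set by their RoMs
  (flexion-extension at step frequency, the others at stride frequency).

A pure joint-angle-driven chain cannot simultaneously realise target step
lengths — leg-segment excursions under realistic RoMs fall short of the
required foot displacement — hence this hybrid: each measured quantity is
governed by the markers it is actually read from.  The price is that the
skeleton is not rigidly consistent (heel and malleolus are generated
independently); no reported variable spans that seam.  Marker noise is
white Gaussian, default 1 mm SD per coordinate — the order of
optoelectronic spatial accuracy (~0.2 mm) plus soft-tissue artifact.

Noise-free round-trips recover step lengths and cadence within 1% and all
RoMs within 0.5° (tested on 100 trials); passing these tests shows the
measurement chain is unbiased on data satisfying its assumptions, not
that it is robust to real-world artifacts the generator omits: soft-tissue
wobble is not autocorrelated here, there is no marker mislabeling or
occlusion bursts, no turning, festination or freezing episodes, and the
gait is perfectly periodic within a trial.

## Cohort generator

`generate_cohort` draws 36 patients and 22 controls by default, two
sessions, six trials each.  Gait variables are truncated normals with
configurable per-group, per-session means/SDs (defaults are a published
Parkinson's rehabilitation cohort's group summaries); clinical covariates
(age, sex, disease duration, UPDRS-II/III, Hoehn–Yahr stage 1–3 in half
steps, levodopa-equivalent dose) are drawn to match that cohort's
demographics.  Sex is coded male = 0 / female = 1 throughout, so a
negative sex coefficient means women improve less; the coding is the
exported constant `SEX_CODING`.

Patient follow-ups for the five modelled outcomes (speed, cadence, both
step lengths, trunk rotation RoM) are `baseline · (1 + Δ/100)` with Δ a
configured linear function of the covariates plus Gaussian noise
(`regression_truth`; residual SDs sized so explained variance is of the
order the corresponding fitted models report).  Every other variable's
follow-up — and all control variables — are drawn from the follow-up
distribution with within-subject correlation 0.7, so both sessions' group
moments match the configured conditions.  Spatial asymmetry is treated
this way too: experiments with drawing the asymmetry delta independently
of the control range made the normalization anchor nearly independent of
Δ (because a substantial minority of patients start inside the control
band, where the closer-to-control rule and the delta disagree), which
says something real about anchor-based designs — under the configured
group moments the anchor-Δ association, and hence the AUC, is modest.
The MCID machinery itself is therefore validated on purpose-built
threshold cohorts (labels generated by a known Δ cut-off), where the
recovered MCID lands within 20% of truth.

Per-subject step lengths realise the drawn asymmetry index exactly when a
trajectory profile is built (the affected side is the shorter); in the
truth table the patient follow-up step lengths keep their regression-truth
values, so the asymmetry column and step-length columns are each faithful
to their own generating rule rather than mutually coupled.

Determinism: every random draw descends from `SeedSequence(seed)`; trial
materialisation uses `SeedSequence((seed, subject, session, trial))`, so
any subject's trials can be regenerated independently of draw order.

## Statistics

* **Speed matching** keeps control trials with speed inside the closed
  patient-group band [mean − SD, mean + SD], per session; a control with
  no surviving trials is excluded from matched comparisons (logged).  The
  band is computed against the whole patient group, not per pair.
* **Gated comparisons**: Shapiro-Wilk at α = 0.05 per sample (on paired
  differences for paired designs) routes to pooled-variance Student *t* /
  paired *t* or Mann-Whitney / Wilcoxon.  The pooled (not Welch) *t* is
  deliberate: it is the form recomputable from published group moments.
  Cohen's *d* uses the pooled-SD denominator (SD of differences when
  paired) and is reported as a magnitude.  The gate's type-I error stays
  at the nominal 5% under the null (10,000-rep check).
* **Improvement** is strict distance reduction toward the control mean;
  ties (exact mirror overshoot, baseline already at the mean) count as
  not improved — the conservative reading.  The chi-square compares the
  improved count to an even split (1 df).
* **Power**: required paired-*t* sample size by exact noncentral-*t*
  search (smallest n with power ≥ target), no normal approximation.
* **MCID**: anchor = improved AND follow-up within control mean ± k·SD on
  the healthy side (k = 1 default, configurable — "reached control
  values" has no canonical operationalisation).  ROC thresholds are
  midpoints between distinct deltas; orientation is flipped if needed so
  AUC ≥ 0.5 and reported; AUC equals the Mann-Whitney concordance
  probability (ties half).  The cut-off minimises (1−Se)² + (1−Sp)²,
  ties toward higher Se then higher threshold.  AUC CIs are DeLong
  (structural components), with a Hanley-McNeil binomial fallback.
  LR/PV/post-test arithmetic is exact odds algebra; Sp = 1 yields an
  infinite LR+ sentinel.
* **Regression**: OLS with classical SEs.  Backward selection drops the
  largest-p predictor above α = 0.10 and refits; 0.05 would contradict
  retaining a p ≈ 0.06 term, and 0.10 is the common backward-selection
  default.  The outcome's own baseline covariate is never dropped.  Ties
  in p are broken lexicographically, making selection order-invariant.
  Diagnostics: Durbin–Watson, VIF, Shapiro-Wilk on residuals,
  Breusch–Pagan, |externally studentized residual| > 3 flagged.

## Problem sizes

Default simulations were sized for fast, repeatable runs on a laptop
core: the round-trip suite uses 100 noise-free trials of 8 strides at
300 Hz; oracle equivalence uses 1,000 random ROC instances (n ≤ 30);
regression recovery uses 200 cohorts of 36 patients; the type-I error
check uses 10,000 replicates of n = 20 per arm.  The full test suite runs
in well under a minute apart from these, which add ~25 s total.

## Known limitations

* C3D ingestion is not included; trials travel as long-format CSV (a
  lossless, diffable interchange the writer also emits).
* No inverse dynamics, no frontal/transverse lower-limb angles, no
  treadmill or turning gait, no arm swing beyond the shoulder girdle.
* The generator's group draws are independent across variables given the
  session (no realistic cross-variable covariance beyond the
  asymmetry–step-length coupling and the session correlation).
* DeLong CIs are asymptotic and degrade below ~10 per class; the binomial
  fallback is provided for those cases.
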