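# gaitresp

Quantifying which gait deficits respond to rehabilitation — and who will
respond — from 3D motion-capture data.

`gaitresp` implements a complete case–control gait-responsiveness analysis
for clinical movement laboratories, built around the kind of study design
used to evaluate short-term rehabilitation in Parkinson's disease: patients
and healthy controls walk over ground while an optoelectronic system tracks
reflective markers at 300 Hz; spatio-temporal and kinematic gait variables
are extracted before and after treatment; and three questions are answered
statistically:

1. **Which gait variables differ from controls, at matched speed?**
   Control trials are restricted to the patients' gait-speed band
   (mean ± SD) to remove speed as a confound, then each variable is compared
   with a normality-gated two-sample test (pooled-variance Student *t* or
   Mann-Whitney *U*) with Cohen's *d* effect sizes.
2. **Which improvements are clinically meaningful?**  Changes are expressed
   as percent deltas, Δ = 100·(follow-up − baseline)/baseline.  An
   anchor-based MCID (minimal clinically important difference) analysis
   scores Δ against a "normalized" anchor (the patient improved *and*
   reached the control range) with an empirical ROC curve: the MCID is the
   Δ cut-off minimising (1−Se)² + (1−Sp)², and likelihood ratios convert
   pre-test to post-test probability of normalization (Fagan-nomogram
   arithmetic).
3. **Who improves?**  Multiple linear regression with backward selection
   predicts each Δ outcome from baseline clinical covariates (age, sex,
   UPDRS-II/III, Hoehn–Yahr stage, disease duration, levodopa-equivalent
   dose, and the baseline value of the variable itself), with the standard
   validity checks (Durbin–Watson, VIF, Breusch–Pagan, residual normality,
   studentized-residual outliers).

Because raw clinical marker data are rarely shareable, the package ships a
first-class synthetic-data module: a forward model that renders labelled
13-marker walking trials from a ground-truth gait profile (step lengths,
cadence, stance %, joint and trunk RoMs…), plus a cohort generator that
draws patients and controls from configurable group distributions and
builds patient deltas from a known clinical→Δ linear truth.  Every stage of
the pipeline is validated against this ground truth.

## The measurement chain

Marker trajectories are gap-interpolated, low-pass filtered with a zero-lag
fourth-order Butterworth filter (6 Hz), and segmented into gait cycles by
coordinate-based event detection: heel strike at local maxima of the heel's
anterior excursion relative to the sacrum, toe off at local minima of the
toe's.  The first trial and the first/last two steps of each remaining
trial are discarded; only the central two steps per side per trial enter
the analysis (≈ 20 steps per subject-session).  Reported variables:
cadence, speed, per-side stance and initial double-support %, step
length/width, sagittal hip/knee/ankle RoM per side, trunk RoM in three
planes, and the spatial asymmetry index

    asymmetry % = 100 · (1 − min(A, NA) / max(A, NA))

where A and NA are the mean step lengths of the (most) affected and less
affected sides.

## Worked example

```bash
gaitresp run-all --seed 1 --out demo_out
# pipeline complete: 116 parameter rows, 2 MCID analyses, 5 regression models -> demo_out
```

This simulates the default cohort (36 patients, 22 controls, two sessions,
six trials each) and writes `parameters.csv`, `comparisons.csv`,
`deltas.csv`, `mcid.json`, `regression.json` and `run.log`.  From
`comparisons.csv`, the baseline patient-control contrasts at matched speed
(seed 1):

| variable              | test     | statistic | p        | Cohen's d |
|-----------------------|----------|-----------|----------|-----------|
| cadence               | pooled-t | 1.64      | 0.106    | 0.44      |
| spatial asymmetry (%) | pooled-t | 4.53      | 3.1e-05  | 1.23      |
| knee RoM, affected    | pooled-t | −16.59    | 2.8e-23  | 4.49      |

Patients cycle faster, walk more asymmetrically and flex the knee less
than speed-matched controls, with the knee deficit the largest effect —
the configured group distributions separate knee RoM by several SDs, and
the extracted statistics recover that.  From `regression.json`, the
ΔSpeed model retains the configured truth structure (UPDRS-III, sex and
baseline speed; male = 0 / female = 1):

```
delta_speed   adjusted R² 0.684, F 26.2
  const            B  1.464   SE 0.111   p <0.001
  baseline_speed   B −0.563   SE 0.086   p <0.001
  sex              B −0.227   SE 0.057   p <0.001
  updrs3           B −0.027   SE 0.006   p <0.001
```

i.e. men with lower motor scores and slower baseline gait gain the most
speed — each estimate within two standard errors of the generating
coefficients (1.264, −0.446, −0.248, −0.018).  `mcid.json` holds the
anchor-based responsiveness of spatial asymmetry and trunk rotation (AUC,
MCID cut-off, Se/Sp, LR±, predictive values and post-test probabilities).

The same analyses are available as a library (`gaitresp.kinematics`,
`.parameters`, `.stats`, `.responsiveness`, `.prediction`,
`.synthetic`), and recorded trials can be supplied as long-format CSV
(`trial, frame, marker, x, y, z` + sampling-rate header) via
`gaitresp.io.read_markers_csv`.

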