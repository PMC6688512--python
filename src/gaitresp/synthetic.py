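"""Synthetic gait cohorts and marker-trajectory trials with known ground truth.

Two layers:

* :func:`generate_trial` renders one walking trial as 13 labelled 3D marker
  trajectories from a :class:`~gaitresp.types.GaitProfile`, built so that
  every parameter the pipeline extracts (step lengths, cadence, stance and
  double-support percentages, step width, speed, joint and trunk RoMs,
  spatial asymmetry) equals the generating profile up to marker noise and
  frame quantisation.  Ground-truth heel-strike/toe-off frames are returned
  alongside.

* :func:`generate_cohort` draws a patients-plus-controls cohort: clinical
  covariates, per-session gait parameters from configurable group
  distributions, and patient percent-change (delta) outcomes built as linear
  functions of the clinical covariates plus Gaussian noise, so regression
  recovery can be tested against a known truth.  Trials for any
  subject-session can be materialised on demand.

Geometry convention: +Y anterior, +Z vertical, +X subject's right; marker
positions in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from gaitresp.types import (
    MARKER_LABELS,
    SIDES,
    GaitError,
    GaitEvents,
    GaitProfile,
    MarkerTrajectorySet,
)

# Fixed anthropometry of the synthetic walker (mm); only segment *angles*
# and heel/toe positions are consumed downstream, so one body size suffices.
HIP_HEIGHT = 1000.0
PELVIS_HALF_WIDTH = 120.0
PELVIS_DEPTH = 120.0  # ASIS anterior of sacrum
THIGH_LENGTH = 420.0
SHANK_LENGTH = 400.0
FOOT_LENGTH = 150.0
TRUNK_LENGTH = 450.0
SHOULDER_HALF_WIDTH = 180.0
SWING_HEEL_LIFT = 60.0

#: Mean (neutral) segment postures, degrees; offsets do not enter any RoM.
HIP_MEAN_DEG = 10.0
KNEE_MEAN_DEG = 15.0

#: Sex coding used throughout (regression included): male=0, female=1.
SEX_CODING = {"M": 0.0, "F": 1.0}


def _unit_shape(phase: np.ndarray, harmonics: tuple[float, ...] = (1.0, 0.25),
                phase2: float = 0.6) -> np.ndarray:
    """Smooth periodic template with unique extrema per cycle, range == 1.

    ``phase`` is in stride cycles.  The range is normalised on a dense grid
    of one cycle so a curve scaled by ``rom`` has max-min == rom exactly
    (up to sampling of the trial itself).
    """
    def raw(p):
        return (harmonics[0] * np.sin(2 * np.pi * p)
                + harmonics[1] * np.sin(4 * np.pi * p + phase2))

    grid = raw(np.linspace(0.0, 1.0, 4001))
    lo, hi = grid.min(), grid.max()
    return (raw(phase) - lo) / (hi - lo) - 0.5


def _swing_ramp(tau: np.ndarray, ramp_frac: float) -> np.ndarray:
    """Normalised swing displacement 0->1 with trapezoidal velocity.

    Short velocity ramps (``ramp_frac`` of the swing) keep the heel's
    velocity transition at touch-down sharp, so the coordinate-based event
    detector localises heel strike to within a few frames.
    """
    r = ramp_frac
    peak = 1.0 / (1.0 - r)  # plateau velocity for unit displacement
    disp = np.where(
        tau < r,
        0.5 * peak * tau**2 / r,
        np.where(
            tau < 1.0 - r,
            0.5 * peak * r + peak * (tau - r),
            1.0 - 0.5 * peak * (1.0 - tau) ** 2 / r,
        ),
    )
    return np.clip(disp, 0.0, 1.0)


def generate_trial(profile: GaitProfile, n_strides: int = 8,
                   sampling_rate: float = 300.0, noise_sd: float = 1.0,
                   seed: int | np.random.Generator | None = 0,
                   trial_id: str = "trial",
                   ) -> tuple[MarkerTrajectorySet, GaitEvents]:
    """Render one walking trial; returns (trajectories, ground-truth events).

    The affected side of the profile maps to its ``affected_side``; the trial
    contains ``n_strides`` full strides per side plus lead-in/out so
    steady-state trimming has material to discard.
    """
    if n_strides < 5:
        raise GaitError("n_strides must be >= 5 for steady-state selection")
    if sampling_rate <= 0:
        raise GaitError("sampling_rate must be > 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))

    T = profile.stride_duration
    fs = sampling_rate
    stance_frac = profile.stance_pct / 100.0
    stride_len = (profile.step_length("left") + profile.step_length("right")) * 1000.0
    speed_mm = profile.speed * 1000.0

    t0 = 0.6 * T  # first left heel strike
    t_end = t0 + (n_strides + 0.5) * T + 0.6 * T
    n_frames = int(np.floor(t_end * fs)) + 1
    t = np.arange(n_frames) / fs

    # per-side heel-strike schedules and landing offsets; the offsets make
    # each side's step length (heel minus contralateral heel at touch-down)
    # equal the profile's value for that side.
    hs_t0 = {"left": t0, "right": t0 + 0.5 * T}
    offset = {"left": 0.0, "right": profile.step_length("right") * 1000.0}

    swing_frac = 1.0 - stance_frac
    ramp_frac = min(0.02 / (swing_frac * T), 0.25)

    heel_y: dict[str, np.ndarray] = {}
    heel_z: dict[str, np.ndarray] = {}
    for side in SIDES:
        local = (t - hs_t0[side]) / T
        m = np.floor(local)
        tau = local - m  # in-stride phase, 0 at heel strike
        base = m * stride_len + offset[side]
        in_swing = tau > stance_frac
        tau_sw = np.clip((tau - stance_frac) / swing_frac, 0.0, 1.0)
        heel_y[side] = base + in_swing * stride_len * _swing_ramp(tau_sw, ramp_frac)
        heel_z[side] = in_swing * SWING_HEEL_LIFT * np.sin(np.pi * tau_sw) ** 2

    # joint-angle curves: one shared unit template per side (half-stride
    # phase offset between sides) so the shank angle, which mixes hip and
    # knee, stays a scaled copy and every extracted RoM is exact.
    shape = {side: _unit_shape((t - hs_t0[side]) / T) for side in SIDES}
    hip = {s: profile.rom("hip", s) * shape[s] + HIP_MEAN_DEG for s in SIDES}
    knee_rom = {s: profile.rom("knee", s) for s in SIDES}
    thigh = hip  # pelvis is un-rotated, so thigh inclination == hip angle
    shank = {s: thigh[s] - (knee_rom[s] * shape[s] + KNEE_MEAN_DEG) for s in SIDES}
    ankle = {s: profile.rom("ankle", s) * shape[s] + (HIP_MEAN_DEG - KNEE_MEAN_DEG)
             for s in SIDES}
    foot_pitch = {s: ankle[s] - shank[s] for s in SIDES}

    # trunk oscillations: flex-ext at step frequency, bending/rotation at
    # stride frequency (one cycle per stride), each scaled to its RoM.
    stride_phase = (t - t0) / T
    sag = profile.trunk_rom_sagittal * _unit_shape(2.0 * stride_phase)
    frontal = profile.trunk_rom_frontal * _unit_shape(stride_phase)
    yaw = profile.trunk_rom_transverse * _unit_shape(stride_phase, phase2=1.9)

    sacrum_y = speed_mm * t
    half_width = profile.step_width * 1000.0 / 2.0
    heel_x = {"left": -half_width, "right": half_width}

    markers: dict[str, np.ndarray] = {}
    zeros = np.zeros_like(t)

    def stack(x, y, z):
        return np.column_stack([np.broadcast_to(x, t.shape),
                                np.broadcast_to(y, t.shape),
                                np.broadcast_to(z, t.shape)]).astype(float)

    markers["sacrum"] = stack(0.0, sacrum_y, HIP_HEIGHT)
    for side, sx in (("left", -1.0), ("right", 1.0)):
        p = side[0]
        asis = stack(sx * PELVIS_HALF_WIDTH, sacrum_y + PELVIS_DEPTH, HIP_HEIGHT)
        markers[f"{p}_asis"] = asis
        th = np.radians(thigh[side])
        knee = asis + stack(0.0, THIGH_LENGTH * np.sin(th),
                            -THIGH_LENGTH * np.cos(th))
        markers[f"{p}_knee"] = knee
        sh = np.radians(shank[side])
        markers[f"{p}_malleolus"] = knee + stack(
            0.0, SHANK_LENGTH * np.sin(sh), -SHANK_LENGTH * np.cos(sh))
        heel = stack(heel_x[side], heel_y[side], heel_z[side])
        markers[f"{p}_heel"] = heel
        fp = np.radians(foot_pitch[side])
        markers[f"{p}_toe"] = heel + stack(
            0.0, FOOT_LENGTH * np.cos(fp), FOOT_LENGTH * np.sin(fp))

    pelvis_centre_y = sacrum_y + 2.0 * PELVIS_DEPTH / 3.0
    v_z = TRUNK_LENGTH
    trunk_y = v_z * np.tan(np.radians(sag))
    trunk_x = v_z * np.tan(np.radians(frontal))
    mid_shoulder = stack(trunk_x, pelvis_centre_y + trunk_y, HIP_HEIGHT + v_z)
    yr = np.radians(yaw)
    shoulder_half = stack(SHOULDER_HALF_WIDTH * np.cos(yr),
                          SHOULDER_HALF_WIDTH * np.sin(yr), zeros)
    markers["l_acromion"] = mid_shoulder - shoulder_half
    markers["r_acromion"] = mid_shoulder + shoulder_half
    markers["c7"] = mid_shoulder + stack(0.0, 0.0, 80.0)

    if noise_sd > 0:
        for label in markers:
            markers[label] = markers[label] + rng.normal(
                0.0, noise_sd, size=(n_frames, 3))

    traj = MarkerTrajectorySet(trial_id, fs, markers)

    events = GaitEvents(
        heel_strikes={
            side: _event_frames(hs_t0[side], T, n_strides + 1, fs, n_frames)
            for side in SIDES},
        toe_offs={
            side: _event_frames(hs_t0[side] + stance_frac * T, T,
                                n_strides + 1, fs, n_frames)
            for side in SIDES},
    )
    return traj, events


def _event_frames(t_first: float, period: float, count: int,
                  fs: float, n_frames: int) -> np.ndarray:
    times = t_first + period * np.arange(count)
    frames = np.round(times * fs).astype(int)
    return frames[(frames >= 0) & (frames < n_frames)]


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

#: Group-level (mean, SD) of each gait variable per session, patients and
#: controls separately -- the study conditions the generator emulates.
DEFAULT_GROUP_MOMENTS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "patient": {
        "baseline": {
            "cadence": (102.307, 16.146),
            "speed": (0.777, 0.305),
            "stance_pct": (63.513, 3.954),
            "double_support_pct": (13.386, 3.610),
            "step_length_a": (0.411, 0.125),
            "step_length_na": (0.413, 0.121),
            "step_width": (0.164, 0.019),
            "spatial_asymmetry_pct": (12.526, 11.824),
            "hip_rom_a": (32.988, 8.449),
            "hip_rom_na": (33.039, 9.131),
            "knee_rom_a": (45.202, 2.074),
            "knee_rom_na": (48.567, 1.915),
            "ankle_rom_a": (23.730, 1.279),
            "ankle_rom_na": (24.267, 1.064),
            "trunk_rom_sagittal": (3.362, 1.365),
            "trunk_rom_frontal": (4.008, 1.857),
            "trunk_rom_transverse": (6.996, 3.169),
        },
        "followup": {
            "cadence": (107.143, 15.437),
            "speed": (0.864, 0.264),
            "stance_pct": (62.684, 3.801),
            "double_support_pct": (12.342, 3.653),
            "step_length_a": (0.447, 0.121),
            "step_length_na": (0.459, 0.110),
            "step_width": (0.168, 0.021),
            "spatial_asymmetry_pct": (7.229, 6.518),
            "hip_rom_a": (36.001, 8.792),
            "hip_rom_na": (35.901, 8.911),
            "knee_rom_a": (45.439, 2.647),
            "knee_rom_na": (49.876, 2.722),
            "ankle_rom_a": (23.992, 0.948),
            "ankle_rom_na": (25.408, 0.901),
            "trunk_rom_sagittal": (3.948, 2.597),
            "trunk_rom_frontal": (4.321, 2.355),
            "trunk_rom_transverse": (10.033, 5.822),
        },
    },
    "control": {
        "baseline": {
            "cadence": (88.280, 12.406),
            "speed": (0.786, 0.179),
            "stance_pct": (63.886, 2.149),
            "double_support_pct": (13.982, 1.803),
            "step_length_a": (0.487, 0.062),
            "step_length_na": (0.493, 0.056),
            "step_width": (0.156, 0.024),
            "spatial_asymmetry_pct": (6.764, 5.723),
            "hip_rom_a": (38.975, 3.726),
            "hip_rom_na": (39.923, 3.953),
            "knee_rom_a": (52.355, 1.597),
            "knee_rom_na": (54.075, 1.171),
            "ankle_rom_a": (26.849, 1.772),
            "ankle_rom_na": (26.833, 1.350),
            "trunk_rom_sagittal": (3.468, 0.945),
            "trunk_rom_frontal": (4.037, 1.589),
            "trunk_rom_transverse": (10.241, 3.758),
        },
        "followup": {
            "cadence": (95.573, 11.433),
            "speed": (0.870, 0.169),
            "stance_pct": (62.633, 2.016),
            "double_support_pct": (12.771, 1.804),
            "step_length_a": (0.518, 0.060),
            "step_length_na": (0.525, 0.060),
            "step_width": (0.159, 0.023),
            "spatial_asymmetry_pct": (5.496, 4.719),
            "hip_rom_a": (40.774, 4.120),
            "hip_rom_na": (42.414, 5.043),
            "knee_rom_a": (54.686, 1.443),
            "knee_rom_na": (56.963, 1.061),
            "ankle_rom_a": (26.977, 1.169),
            "ankle_rom_na": (29.157, 1.269),
            "trunk_rom_sagittal": (4.062, 1.848),
            "trunk_rom_frontal": (4.671, 2.532),
            "trunk_rom_transverse": (12.098, 4.586),
        },
    },
}

#: Linear clinical -> percent-change truth for the modelled outcomes.
#: Coefficients are on the Eq.-2 percent scale for the named predictors
#: (sex coded male=0/female=1); ``resid_sd`` is the Gaussian noise SD,
#: sized so explained variance is of the order the fitted models report.
DEFAULT_REGRESSION_TRUTH: dict[str, dict] = {
    "speed": {
        "intercept": 1.264,
        "coefs": {"updrs3": -0.018, "sex": -0.248, "baseline": -0.446},
        "resid_sd": 0.20,
    },
    "cadence": {
        "intercept": 69.212,
        "coefs": {"updrs2": -0.523, "sex": -8.518, "baseline": -0.402},
        "resid_sd": 7.6,
    },
    "step_length_a": {
        "intercept": 0.409,
        "coefs": {"updrs3": -0.006, "sex": -0.056, "baseline": -0.413},
        "resid_sd": 0.070,
    },
    "step_length_na": {
        "intercept": 0.421,
        "coefs": {"updrs3": -0.005, "sex": -0.077, "baseline": -0.297},
        "resid_sd": 0.068,
    },
    "trunk_rom_transverse": {
        "intercept": 39.059,
        "coefs": {"hy_stage": -2.170, "disease_duration": 0.392,
                  "age": -0.387, "baseline": -0.955},
        "resid_sd": 4.7,
    },
}

#: Within-subject session-to-session correlation for variables whose
#: follow-up is drawn from the follow-up distribution.
SESSION_CORRELATION = 0.7

SESSIONS = ("baseline", "followup")

#: Variables whose per-subject values define the GaitProfile directly.
PROFILE_VARIABLES = tuple(DEFAULT_GROUP_MOMENTS["patient"]["baseline"])


@dataclass
class CohortConfig:
    """Study conditions for a synthetic cohort."""

    n_patients: int = 36
    n_controls: int = 22
    n_trials_per_session: int = 6
    n_strides: int = 8
    sampling_rate: float = 300.0
    noise_sd_marker: float = 1.0
    trial_speed_cv: float = 0.05  # trial-to-trial speed variation
    group_moments: dict = field(
        default_factory=lambda: {g: {s: dict(v) for s, v in gs.items()}
                                 for g, gs in DEFAULT_GROUP_MOMENTS.items()})
    regression_truth: dict = field(
        default_factory=lambda: {k: {**v, "coefs": dict(v["coefs"])}
                                 for k, v in DEFAULT_REGRESSION_TRUTH.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_session < 6:
            raise GaitError("n_trials_per_session must be >= 6")
        if self.sampling_rate <= 0:
            raise GaitError("sampling_rate must be > 0")
        for group in self.group_moments.values():
            for session in group.values():
                for name, (_, sd) in session.items():
                    if sd <= 0:
                        raise GaitError(f"SD for {name} must be > 0")


@dataclass
class CohortData:
    """Generated cohort: clinical table, truth parameters, deltas, trials."""

    config: CohortConfig
    clinical: pd.DataFrame
    parameters: pd.DataFrame  # one row per subject x session, truth values
    deltas: pd.DataFrame  # patients only: variable, baseline, followup, delta_pct
    profiles: dict[tuple[str, str], GaitProfile]
    _trial_seed: Callable[[str, str, int], np.random.SeedSequence] = None

    def trials_for(self, subject_id: str, session: str):
        """Materialise this subject-session's marker trials (deterministic)."""
        profile = self.profiles[(subject_id, session)]
        out = []
        for k in range(self.config.n_trials_per_session):
            rng = np.random.default_rng(self._trial_seed(subject_id, session, k))
            traj, events = generate_trial(
                profile, self.config.n_strides, self.config.sampling_rate,
                self.config.noise_sd_marker, rng,
                trial_id=f"{subject_id}_{session}_t{k}")
            out.append((traj, events))
        return out

    def trial_speeds(self) -> pd.DataFrame:
        """Per-trial walking speeds (m/s) for speed matching."""
        cfg = self.config
        rows = []
        for (sid, session), profile in self.profiles.items():
            rng = np.random.default_rng(self._trial_seed(sid, session, 10_000))
            jitter = rng.normal(0.0, cfg.trial_speed_cv, cfg.n_trials_per_session)
            for k in range(cfg.n_trials_per_session):
                rows.append({"subject_id": sid, "session": session, "trial": k,
                             "speed": profile.speed * (1.0 + jitter[k])})
        return pd.DataFrame(rows)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float = -np.inf, hi: float = np.inf,
                      size=None) -> np.ndarray:
    """Resampling-based truncated normal (distributions here are far from
    their bounds, so rejection is cheap and keeps moments near-nominal)."""
    x = rng.normal(mean, sd, size=size)
    bad = (x < lo) | (x > hi)
    while np.any(bad):
        x = np.where(bad, rng.normal(mean, sd, size=size), x)
        bad = (x < lo) | (x > hi)
    return x


_VARIABLE_BOUNDS: dict[str, tuple[float, float]] = {
    "cadence": (40.0, 180.0),
    "speed": (0.15, 2.5),
    "stance_pct": (52.0, 74.0),
    "double_support_pct": (2.0, 24.0),
    "step_length_a": (0.08, 1.0),
    "step_length_na": (0.08, 1.0),
    "step_width": (0.05, 0.35),
    "spatial_asymmetry_pct": (0.2, 60.0),
    "hip_rom_a": (5.0, 70.0),
    "hip_rom_na": (5.0, 70.0),
    "knee_rom_a": (10.0, 80.0),
    "knee_rom_na": (10.0, 80.0),
    "ankle_rom_a": (5.0, 50.0),
    "ankle_rom_na": (5.0, 50.0),
    "trunk_rom_sagittal": (0.3, 20.0),
    "trunk_rom_frontal": (0.3, 20.0),
    "trunk_rom_transverse": (0.3, 30.0),
}


def _draw_clinical(rng: np.random.Generator, cfg: CohortConfig) -> pd.DataFrame:
    rows = []
    for i in range(cfg.n_patients):
        rows.append({
            "subject_id": f"P{i + 1:02d}",
            "group": "patient",
            "affected_side": rng.choice(["left", "right"]),
            "age": float(_truncated_normal(rng, 68.83, 9.85, 40.0, 90.0)),
            "sex": rng.choice(["F", "M"], p=[16 / 36, 20 / 36]),
            "disease_duration": float(_truncated_normal(rng, 7.56, 4.15, 0.5, 30.0)),
            "updrs2": float(_truncated_normal(rng, 12.61, 7.19, 0.0, 52.0)),
            "updrs3": float(_truncated_normal(rng, 15.78, 6.89, 1.0, 108.0)),
            "hy_stage": float(rng.choice([1.0, 1.5, 2.0, 2.5, 3.0],
                                         p=[0.10, 0.15, 0.25, 0.25, 0.25])),
            "led": float(_truncated_normal(rng, 571.92, 317.2, 0.0, 2500.0)),
        })
    for i in range(cfg.n_controls):
        rows.append({
            "subject_id": f"C{i + 1:02d}",
            "group": "control",
            "affected_side": "none",
            "age": float(rng.uniform(57.0, 75.0)),
            "sex": rng.choice(["F", "M"], p=[10 / 22, 12 / 22]),
            "disease_duration": 0.0,
            "updrs2": 0.0,
            "updrs3": 0.0,
            "hy_stage": 0.0,
            "led": 0.0,
        })
    return pd.DataFrame(rows)


def _draw_session_values(rng: np.random.Generator, moments: dict[str, tuple],
                         ) -> dict[str, float]:
    values = {}
    for name, (mean, sd) in moments.items():
        lo, hi = _VARIABLE_BOUNDS[name]
        values[name] = float(_truncated_normal(rng, mean, sd, lo, hi))
    return values


def _couple_asymmetry(values: dict[str, float]) -> dict[str, float]:
    """Make step lengths realise the drawn asymmetry index exactly.

    The affected side is the shorter one: given the drawn mean step length m
    and asymmetry r (%), set NA = 2m / (2 - r/100) and A = NA (1 - r/100).
    """
    r = values["spatial_asymmetry_pct"]
    m = 0.5 * (values["step_length_a"] + values["step_length_na"])
    na = 2.0 * m / (2.0 - r / 100.0)
    values["step_length_na"] = na
    values["step_length_a"] = na * (1.0 - r / 100.0)
    return values


def _values_to_profile(values: dict[str, float], affected_side: str) -> GaitProfile:
    """Trajectory-consistent profile from drawn truth values.

    Speed is derived from step length and cadence, and double support is
    stance - 50 (the value the periodic trial construction realises); the
    drawn speed/double-support values remain in the truth table as the
    statistical cohort conditions.
    """
    side = affected_side if affected_side in SIDES else "left"
    values = _couple_asymmetry(dict(values))
    return GaitProfile.with_derived_speed(
        step_length_a=values["step_length_a"],
        step_length_na=values["step_length_na"],
        cadence=values["cadence"],
        stance_pct=values["stance_pct"],
        double_support_pct=values["stance_pct"] - 50.0,
        step_width=values["step_width"],
        hip_rom_a=values["hip_rom_a"], hip_rom_na=values["hip_rom_na"],
        knee_rom_a=values["knee_rom_a"], knee_rom_na=values["knee_rom_na"],
        ankle_rom_a=values["ankle_rom_a"], ankle_rom_na=values["ankle_rom_na"],
        trunk_rom_sagittal=values["trunk_rom_sagittal"],
        trunk_rom_frontal=values["trunk_rom_frontal"],
        trunk_rom_transverse=values["trunk_rom_transverse"],
        affected_side=side,
    )


def generate_cohort(config: CohortConfig | None = None) -> CohortData:
    """Draw a full synthetic cohort under the configured study conditions.

    Patients' follow-up values for the modelled outcomes (speed, cadence,
    both step lengths, trunk rotation RoM) are ``baseline * (1 + delta/100)``
    with delta the configured linear function of the clinical covariates
    plus noise; every other variable's follow-up (spatial asymmetry
    included) is drawn from the follow-up group distribution with
    within-subject correlation 0.7, so both sessions' group moments match
    the configured conditions.
    """
    cfg = config or CohortConfig()
    master = np.random.SeedSequence(cfg.seed)
    rng_clin, rng_param = [np.random.default_rng(s) for s in master.spawn(2)]

    clinical = _draw_clinical(rng_clin, cfg)
    profiles: dict[tuple[str, str], GaitProfile] = {}
    param_rows = []
    delta_rows = []

    modelled = set(cfg.regression_truth)

    for _, subj in clinical.iterrows():
        sid = subj["subject_id"]
        group = subj["group"]
        mom_b = cfg.group_moments[group]["baseline"]
        mom_f = cfg.group_moments[group]["followup"]

        base = _couple_asymmetry(_draw_session_values(rng_param, mom_b))

        follow: dict[str, float] = {}
        if group == "patient":
            # modelled outcomes: percent change from the clinical truth model
            for var, truth in cfg.regression_truth.items():
                pred = truth["intercept"]
                for cov, beta in truth["coefs"].items():
                    if cov == "baseline":
                        x = base[var]
                    elif cov == "sex":
                        x = SEX_CODING[subj["sex"]]
                    else:
                        x = subj[cov]
                    pred += beta * x
                delta = pred + rng_param.normal(0.0, truth["resid_sd"])
                lo, hi = _VARIABLE_BOUNDS[var]
                follow[var] = float(np.clip(base[var] * (1.0 + delta / 100.0),
                                            lo, hi))
        # all remaining variables (and all control variables): correlated draw
        for name, (mean_f, sd_f) in mom_f.items():
            if name in follow:
                continue
            mean_b, sd_b = mom_b[name]
            lo, hi = _VARIABLE_BOUNDS[name]
            z = (base[name] - mean_b) / sd_b
            rho = SESSION_CORRELATION
            val = (mean_f + rho * sd_f * z
                   + np.sqrt(1.0 - rho**2) * sd_f * rng_param.normal())
            follow[name] = float(np.clip(val, lo, hi))
        if group == "control":
            # controls carry no modelled deltas, so their truth rows can be
            # made internally consistent (steps realise the asymmetry index)
            follow = _couple_asymmetry(follow)

        for session, values in (("baseline", base), ("followup", follow)):
            profiles[(sid, session)] = _values_to_profile(
                values, subj["affected_side"])
            param_rows.append({"subject_id": sid, "group": group,
                               "session": session, **values})

        if group == "patient":
            for var in sorted(set(base) | modelled):
                vb, vf = base[var], follow[var]
                delta_rows.append({
                    "subject_id": sid, "variable": var,
                    "value_baseline": vb, "value_10week": vf,
                    "delta_pct": 100.0 * (vf - vb) / vb,
                })

    seed = cfg.seed

    def trial_seed(sid: str, session: str, k: int) -> np.random.SeedSequence:
        sidx = int(sid[1:]) + (1000 if sid.startswith("C") else 0)
        return np.random.SeedSequence(
            (seed, sidx, SESSIONS.index(session), k))

    return CohortData(
        config=cfg,
        clinical=clinical,
        parameters=pd.DataFrame(param_rows),
        deltas=pd.DataFrame(delta_rows),
        profiles=profiles,
        _trial_seed=trial_seed,
    )
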