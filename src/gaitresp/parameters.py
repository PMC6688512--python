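"""Spatio-temporal gait variables and the spatial asymmetry index.

Per-trial values are computed over the retained steady-state step windows
and averaged into a per-subject, per-session parameter row (one row of the
reported parameter table).  Step windows are per-side half-open stride
intervals [HS_i, HS_{i+1}).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from gaitresp import kinematics as kin
from gaitresp.types import (
    SIDES,
    GaitError,
    GaitEvents,
    MarkerTrajectorySet,
    StepWindow,
    SubjectSessionParameters,
)

log = logging.getLogger(__name__)


def spatial_asymmetry(a_step: float, na_step: float) -> float:
    """Asymmetry index, percent: 100 * (1 - min/max) of the two step lengths.

    Symmetric in its arguments, 0 for equal steps, < 100 for positive steps.
    """
    if a_step <= 0 or na_step <= 0:
        raise GaitError("step lengths must be > 0")
    return 100.0 * (1.0 - min(a_step, na_step) / max(a_step, na_step))


@dataclass
class TrialParameters:
    """Per-trial spatio-temporal values over the retained windows."""

    trial_id: str
    cadence: float | None = None
    speed: float | None = None
    stance_pct: dict[str, float] = field(default_factory=dict)
    double_support_pct: dict[str, float] = field(default_factory=dict)
    step_length_m: dict[str, float] = field(default_factory=dict)
    step_width_m: float | None = None
    rom_deg: dict[str, float] = field(default_factory=dict)  # e.g. "hip_l"
    n_steps: int = 0


def _other(side: str) -> str:
    return "right" if side == "left" else "left"


def spatiotemporal(events: GaitEvents, traj: MarkerTrajectorySet,
                   windows: list[StepWindow]) -> TrialParameters:
    """Spatio-temporal variables of one trial over its retained windows.

    stance%% = (toe-off - heel-strike) / stride per side; double support%% =
    initial double support (own heel strike to contralateral toe-off) per
    stride; step length = anterior heel-to-heel distance at the window's
    closing heel strike; step width = mediolateral heel-to-heel distance at
    the same instants; speed = sacrum anterior displacement over the
    windows' span; cadence = steps per minute (two per stride window).
    """
    axis, sign = kin.detect_anterior_axis(traj)
    lat_axis = {0: 1, 1: 0}.get(axis)
    if lat_axis is None:
        raise GaitError("anterior axis detected as vertical")
    fs = traj.sampling_rate
    out = TrialParameters(trial_id=traj.trial_id)

    by_side: dict[str, list[StepWindow]] = {s: [] for s in SIDES}
    for w in windows:
        by_side[w.side].append(w)
    for side in SIDES:
        if len(by_side[side]) < 1:
            raise GaitError(f"no retained windows on {side} side")

    heel_y = {s: sign * traj.markers[f"{s[0]}_heel"][:, axis] for s in SIDES}
    heel_x = {s: traj.markers[f"{s[0]}_heel"][:, lat_axis] for s in SIDES}

    # stance-phase plateau of each heel (the foot is stationary from heel
    # strike to toe-off, so the median over the stance is the landing
    # position, immune to low-pass ringing at the contact corners)
    plateaus: dict[str, dict[int, tuple[float, float]]] = {}
    for side in SIDES:
        plateaus[side] = {}
        to_own = events.toe_offs[side]
        for hs in events.heel_strikes[side]:
            nxt = to_own[to_own > hs]
            stop = int(nxt[0]) if len(nxt) else len(heel_y[side])
            span = slice(int(hs), stop)
            plateaus[side][int(hs)] = (float(np.median(heel_y[side][span])),
                                       float(np.median(heel_x[side][span])))

    stride_durations: list[float] = []
    widths: list[float] = []
    for side in SIDES:
        stances, doubles, lengths = [], [], []
        to_own = events.toe_offs[side]
        to_contra = events.toe_offs[_other(side)]
        hs_contra = events.heel_strikes[_other(side)]
        for w in by_side[side]:
            stride = (w.stop - w.start) / fs
            stride_durations.append(stride)
            to = to_own[(to_own > w.start) & (to_own < w.stop)]
            if len(to) == 1:
                stances.append((to[0] - w.start) / (w.stop - w.start) * 100.0)
            else:
                log.warning("%s: %s stride at %d lacks a unique toe-off",
                            traj.trial_id, side, w.start)
            toc = to_contra[(to_contra > w.start) & (to_contra < w.stop)]
            if len(toc) >= 1:
                doubles.append((toc[0] - w.start) / (w.stop - w.start) * 100.0)
            else:
                log.warning("%s: %s stride at %d lacks contralateral toe-off",
                            traj.trial_id, side, w.start)
            # step of this side ends at the closing heel strike w.stop;
            # contralateral reference is the stance in progress at that time
            prev_c = hs_contra[hs_contra < w.stop]
            if len(prev_c):
                own_y, own_x = plateaus[side][w.stop]
                c_y, c_x = plateaus[_other(side)][int(prev_c[-1])]
                lengths.append((own_y - c_y) / 1000.0)
                widths.append(abs(own_x - c_x) / 1000.0)
            else:
                log.warning("%s: no contralateral heel strike before %d",
                            traj.trial_id, w.stop)
            out.n_steps += 1
        if stances:
            out.stance_pct[side] = float(np.mean(stances))
        if doubles:
            out.double_support_pct[side] = float(np.mean(doubles))
        if lengths:
            out.step_length_m[side] = float(np.mean(lengths))

    if stride_durations:
        out.cadence = 120.0 / float(np.mean(stride_durations))  # 2 steps/stride
    if widths:
        out.step_width_m = float(np.mean(widths))

    # speed over the union span of windows, from sacrum displacement
    start = min(w.start for w in windows)
    stop = max(w.stop for w in windows)
    sacrum_y = sign * traj.markers["sacrum"][:, axis]
    stop = min(stop, len(sacrum_y) - 1)
    out.speed = float((sacrum_y[stop] - sacrum_y[start]) / 1000.0
                      / ((stop - start) / fs))
    return out


def trial_roms(traj: MarkerTrajectorySet, windows: list[StepWindow]
               ) -> dict[str, float]:
    """Joint and trunk RoMs (degrees) over the retained windows."""
    by_side: dict[str, list[StepWindow]] = {s: [] for s in SIDES}
    for w in windows:
        by_side[w.side].append(w)
    roms: dict[str, float] = {}
    for side in SIDES:
        for joint in ("hip", "knee", "ankle"):
            series = kin.joint_angle_series(traj, joint, side)
            roms[f"{joint}_{side[0]}"] = kin.range_of_motion(series, by_side[side])
    all_windows = windows
    for plane, name in (("sagittal", "trunk_rom_sagittal"),
                        ("frontal", "trunk_rom_frontal"),
                        ("transverse", "trunk_rom_transverse")):
        series = kin.joint_angle_series(traj, "trunk", plane=plane)
        roms[name] = kin.range_of_motion(series, all_windows)
    return roms


def aggregate(trial_values: list[TrialParameters],
              trial_rom_values: list[dict[str, float]],
              subject_id: str, session: str,
              affected_side: str = "left") -> SubjectSessionParameters:
    """Mean over retained trials into one subject-session parameter row.

    The asymmetry index is computed from the per-side mean step lengths
    (primary); the mean of per-step indices is also reported as
    ``spatial_asymmetry_per_step_pct`` for heterogeneous-gait diagnostics.
    For controls (``affected_side='none'``) the index uses the same min/max
    form, which is side-agnostic.
    """
    if not trial_values:
        raise GaitError(f"{subject_id}/{session}: no retained trials")

    def mean_of(getter):
        vals = [v for v in (getter(t) for t in trial_values) if v is not None]
        return float(np.mean(vals)) if vals else np.nan

    values: dict[str, float] = {
        "cadence": mean_of(lambda t: t.cadence),
        "speed": mean_of(lambda t: t.speed),
        "step_width": mean_of(lambda t: t.step_width_m),
    }
    for side in SIDES:
        c = side[0]
        values[f"stance_pct_{c}"] = mean_of(lambda t, s=side: t.stance_pct.get(s))
        values[f"double_support_pct_{c}"] = mean_of(
            lambda t, s=side: t.double_support_pct.get(s))
        values[f"step_length_{c}"] = mean_of(
            lambda t, s=side: t.step_length_m.get(s))

    per_trial_asym = [
        spatial_asymmetry(t.step_length_m["left"], t.step_length_m["right"])
        for t in trial_values
        if "left" in t.step_length_m and "right" in t.step_length_m
    ]
    values["spatial_asymmetry_pct"] = spatial_asymmetry(
        values["step_length_l"], values["step_length_r"])
    values["spatial_asymmetry_per_step_pct"] = (
        float(np.mean(per_trial_asym)) if per_trial_asym else np.nan)

    rom_keys = trial_rom_values[0].keys() if trial_rom_values else []
    for key in rom_keys:
        vals = [r[key] for r in trial_rom_values if key in r]
        name = key if key.startswith("trunk") else f"{key.split('_')[0]}_rom_{key.split('_')[1]}"
        values[name] = float(np.mean(vals))

    n_steps = sum(t.n_steps for t in trial_values)
    return SubjectSessionParameters(subject_id, session, values, n_steps)


def extract_subject_session(trials: list[MarkerTrajectorySet],
                            subject_id: str, session: str,
                            affected_side: str = "none",
                            cutoff: float = 6.0,
                            event_method: str = "coordinate",
                            ) -> SubjectSessionParameters:
    """Full extraction chain for one subject-session's trials.

    Interpolate, filter, detect events, select steady-state windows,
    compute per-trial spatio-temporal values and RoMs, and aggregate.
    """
    prepared, all_events, ids = [], [], []
    for traj in trials:
        t = kin.interpolate_gaps(traj)
        t = kin.filter_trajectories(t, cutoff=cutoff)
        prepared.append(t)
        all_events.append(kin.detect_gait_events(t, method=event_method))
        ids.append(t.trial_id)
    retained = kin.select_steady_state(all_events, ids)
    trial_vals, trial_romvals = [], []
    for t, ev in zip(prepared, all_events):
        if t.trial_id not in retained:
            continue
        windows = retained[t.trial_id]
        trial_vals.append(spatiotemporal(ev, t, windows))
        trial_romvals.append(trial_roms(t, windows))
    return aggregate(trial_vals, trial_romvals, subject_id, session,
                     affected_side)


def parameters_frame(rows: list[SubjectSessionParameters],
                     extra: dict[str, dict] | None = None) -> pd.DataFrame:
    """Parameter-table DataFrame (one row per subject-session)."""
    records = []
    for r in rows:
        rec = {"subject_id": r.subject_id, "session": r.session,
               "n_steps_used": r.n_steps_used, **r.values}
        if extra and r.subject_id in extra:
            rec.update(extra[r.subject_id])
        records.append(rec)
    return pd.DataFrame(records)
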