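"""Marker trajectories to filtered signals, gait events, step windows and angles.

The processing chain mirrors standard optoelectronic gait-lab practice:
linear interpolation of short marker drop-outs, zero-lag Butterworth
low-pass filtering at 6 Hz, coordinate-based detection of heel-strike and
toe-off events from the heel/toe excursion relative to the sacrum, selection
of steady-state central steps, and sagittal-plane joint / 3-plane trunk
angles from the reduced marker set.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.signal import butter, filtfilt, find_peaks

from gaitresp.types import (
    SIDES,
    GaitError,
    GaitEvents,
    JointAngleSeries,
    MarkerTrajectorySet,
    StepWindow,
    TrialRejected,
)

log = logging.getLogger(__name__)

MAX_GAP_SECONDS = 0.1


def interpolate_gaps(traj: MarkerTrajectorySet,
                     max_gap_s: float = MAX_GAP_SECONDS) -> MarkerTrajectorySet:
    """Linearly fill NaN gaps in every marker channel.

    Gap runs longer than ``max_gap_s`` reject the trial (the drop-out is too
    long to reconstruct credibly); leading/trailing NaNs are treated as gaps
    of their run length.  Non-gap samples are returned unchanged.
    """
    max_run = int(round(max_gap_s * traj.sampling_rate))
    out = traj.copy()
    for label, arr in out.markers.items():
        missing = np.isnan(arr).any(axis=1)
        if not missing.any():
            continue
        if missing.all():
            raise TrialRejected(f"{traj.trial_id}: marker {label} entirely missing")
        runs = _nan_runs(missing)
        longest = max(stop - start for start, stop in runs)
        if longest > max_run:
            raise TrialRejected(
                f"{traj.trial_id}: marker {label} has a {longest}-frame gap "
                f"(> {max_run} frames = {max_gap_s} s)"
            )
        frac_missing = missing.mean()
        if frac_missing > 0.10:
            raise TrialRejected(
                f"{traj.trial_id}: marker {label} missing {frac_missing:.0%} of frames"
            )
        idx = np.arange(arr.shape[0])
        for axis in range(3):
            col = arr[:, axis]
            bad = np.isnan(col)
            col[bad] = np.interp(idx[bad], idx[~bad], col[~bad])
    return out


def _nan_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) runs of True in a boolean mask."""
    edges = np.flatnonzero(np.diff(np.concatenate(([0], mask.view(np.int8), [0]))))
    return list(zip(edges[::2], edges[1::2]))


def zero_lag_lowpass(signal: np.ndarray, sampling_rate: float,
                     cutoff: float = 6.0, order: int = 4,
                     strict_order: bool = False) -> np.ndarray:
    """Zero-lag Butterworth low-pass via forward-backward filtering.

    ``order`` is the *effective* order: by default a Butterworth of half the
    requested order is applied forward and backward (the dominant convention
    in gait analysis, where a "zero-lag fourth-order" filter means a 2nd-order
    design run twice).  ``strict_order=True`` instead applies the full
    ``order`` on each pass.

    The two passes square the magnitude response, so at the design cutoff the
    amplitude gain is 0.5 rather than the single-pass 1/sqrt(2).
    """
    signal = np.asarray(signal, dtype=float)
    if sampling_rate <= 2 * cutoff:
        raise GaitError("sampling_rate must exceed 2x cutoff")
    design_order = order if strict_order else order // 2
    if design_order < 1:
        raise GaitError("order must be >= 2 in effective mode")
    b, a = butter(design_order, cutoff / (sampling_rate / 2.0), btype="low")
    padlen = 3 * max(len(a), len(b))
    if signal.shape[-1] <= 3 * padlen:
        raise GaitError(
            f"series of length {signal.shape[-1]} too short for stable "
            f"zero-lag filtering (need > {3 * padlen})"
        )
    return filtfilt(b, a, signal, axis=-1)


def filter_trajectories(traj: MarkerTrajectorySet, cutoff: float = 6.0,
                        order: int = 4, strict_order: bool = False
                        ) -> MarkerTrajectorySet:
    """Apply the zero-lag low-pass to every coordinate of every marker."""
    out = traj.copy()
    for arr in out.markers.values():
        arr[:] = zero_lag_lowpass(arr.T, traj.sampling_rate, cutoff, order,
                                  strict_order).T
    return out


def detect_anterior_axis(traj: MarkerTrajectorySet) -> tuple[int, float]:
    """Axis (0..2) of largest net sacrum displacement and its sign.

    Makes the pipeline walk-direction agnostic: trials recorded walking in
    -Y or along X are handled identically.
    """
    sacrum = traj.markers["sacrum"]
    disp = sacrum[-1] - sacrum[0]
    axis = int(np.argmax(np.abs(disp)))
    return axis, float(np.sign(disp[axis]) or 1.0)


def detect_gait_events(traj: MarkerTrajectorySet,
                       method: str = "coordinate",
                       min_heel_strikes: int = 3) -> GaitEvents:
    """Heel-strike / toe-off detection from heel and toe excursions.

    Coordinate method: heel strike at local maxima of the heel anterior
    position relative to the sacrum; toe off at local minima of the toe
    anterior position relative to the sacrum.  A velocity-threshold fallback
    (``method='velocity'``) marks heel strike where heel anterior velocity
    falls below 10% of mean sacrum velocity and toe off where toe velocity
    rises above it.
    """
    axis, sign = detect_anterior_axis(traj)
    sacrum_y = sign * traj.markers["sacrum"][:, axis]
    fs = traj.sampling_rate
    min_dist = max(int(0.4 * fs), 1)  # strides are > 0.4 s apart

    heel_strikes: dict[str, np.ndarray] = {}
    toe_offs: dict[str, np.ndarray] = {}
    for side in SIDES:
        prefix = side[0]
        heel_rel = sign * traj.markers[f"{prefix}_heel"][:, axis] - sacrum_y
        toe_rel = sign * traj.markers[f"{prefix}_toe"][:, axis] - sacrum_y
        if method == "coordinate":
            hs, _ = find_peaks(heel_rel, distance=min_dist)
            to, _ = find_peaks(-toe_rel, distance=min_dist)
        elif method == "velocity":
            hs, to = _velocity_events(heel_rel, toe_rel, fs, min_dist)
        else:
            raise GaitError(f"unknown event detection method {method!r}")
        hs, to = _enforce_alternation(hs, to)
        if len(hs) < min_heel_strikes:
            raise TrialRejected(
                f"{traj.trial_id}: only {len(hs)} heel strikes on {side} side"
            )
        heel_strikes[side] = hs
        toe_offs[side] = to

    events = GaitEvents(heel_strikes, toe_offs)
    events.validate()
    return events


def _velocity_events(heel_rel: np.ndarray, toe_rel: np.ndarray,
                     fs: float, min_dist: int) -> tuple[np.ndarray, np.ndarray]:
    """Fallback: threshold crossings of relative anterior velocity."""
    heel_vel = np.gradient(heel_rel) * fs
    toe_vel = np.gradient(toe_rel) * fs
    thresh = 0.1 * np.std(heel_vel)
    # heel strike: downward crossing into stance (velocity drops below thresh)
    hs = np.flatnonzero((heel_vel[:-1] > thresh) & (heel_vel[1:] <= thresh)) + 1
    to = np.flatnonzero((toe_vel[:-1] <= thresh) & (toe_vel[1:] > thresh)) + 1
    hs = hs[np.concatenate(([True], np.diff(hs) >= min_dist))] if len(hs) else hs
    to = to[np.concatenate(([True], np.diff(to) >= min_dist))] if len(to) else to
    return hs, to


def _enforce_alternation(hs: np.ndarray, to: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Keep HS, TO, HS, ... starting at the first heel strike.

    Where two events of the same type occur consecutively the earlier one is
    kept (spurious extrema from noise come later in a flat region).
    """
    if len(hs) == 0:
        return hs, to
    to = to[to > hs[0]]
    kept_hs, kept_to = [int(hs[0])], []
    i = j = 0
    hs = hs[1:]
    expect = "TO"
    while True:
        if expect == "TO":
            while j < len(to) and kept_hs and to[j] <= kept_hs[-1]:
                j += 1
            if j >= len(to):
                break
            # discard heel strikes wrongly occurring before this toe-off
            while i < len(hs) and hs[i] < to[j]:
                i += 1
            kept_to.append(int(to[j]))
            j += 1
            expect = "HS"
        else:
            while i < len(hs) and hs[i] <= kept_to[-1]:
                i += 1
            if i >= len(hs):
                break
            kept_hs.append(int(hs[i]))
            i += 1
            expect = "TO"
    return np.asarray(kept_hs), np.asarray(kept_to)


def step_windows(events: GaitEvents, side: str, trial_id: str = ""
                 ) -> list[StepWindow]:
    """Half-open [HS_i, HS_{i+1}) windows of the given side."""
    hs = events.heel_strikes[side]
    return [StepWindow(side, int(a), int(b), trial_id)
            for a, b in zip(hs, hs[1:])]


def select_steady_state(trial_events: list[GaitEvents],
                        trial_ids: list[str] | None = None,
                        n_drop_lead_trials: int = 1,
                        n_edge_steps: int = 2,
                        n_central_steps: int = 2) -> dict[str, list[StepWindow]]:
    """Select steady-state step windows across a subject-session's trials.

    The first trial is treated as familiarisation and dropped.  Per retained
    trial and side, the first and last ``n_edge_steps`` steps (acceleration /
    deceleration) are excluded and the central ``n_central_steps`` of the
    remainder are kept; with an even number of candidates and no exact
    centre, the tie is broken toward the later pair.  Trials without enough
    steps on either side are excluded with a logged reason.

    Returns ``{trial_id: [StepWindow, ...]}`` for retained trials.
    """
    if len(trial_events) < 6:
        raise GaitError(
            f"need >= 6 trials per subject-session, got {len(trial_events)}"
        )
    if trial_ids is None:
        trial_ids = [f"trial{idx}" for idx in range(len(trial_events))]
    if len(set(trial_ids)) != len(trial_ids):
        raise GaitError("trial ids must be unique within a subject-session")

    retained: dict[str, list[StepWindow]] = {}
    for events, tid in list(zip(trial_events, trial_ids))[n_drop_lead_trials:]:
        windows: list[StepWindow] = []
        ok = True
        for side in SIDES:
            steps = step_windows(events, side, tid)
            usable = steps[n_edge_steps:len(steps) - n_edge_steps]
            if len(usable) < n_central_steps:
                log.warning("trial %s excluded: %d usable %s steps after "
                            "trimming", tid, len(usable), side)
                ok = False
                break
            start = _central_start(len(usable), n_central_steps)
            windows.extend(usable[start:start + n_central_steps])
        if ok:
            retained[tid] = windows
    return retained


def _central_start(n: int, k: int) -> int:
    """Start index of the central k of n items, ties broken toward later."""
    return int(np.ceil((n - k) / 2))


# ---------------------------------------------------------------------------
# Joint and trunk angles
# ---------------------------------------------------------------------------

def _sagittal_segment_angle(vec: np.ndarray, anterior: np.ndarray,
                            vertical: np.ndarray, pointing: str) -> np.ndarray:
    """Signed sagittal-plane angle of a segment, degrees.

    For downward-pointing segments (thigh, shank) the angle is 0 when
    vertical and positive when the distal end is anterior; for
    forward-pointing segments (foot, trunk-up uses its own convention) the
    angle is 0 when horizontal/vertical as appropriate.
    """
    y = vec @ anterior
    z = vec @ vertical
    if pointing == "down":
        return np.degrees(np.arctan2(y, -z))
    if pointing == "up":
        return np.degrees(np.arctan2(y, z))
    # forward-pointing (foot): pitch above the anterior axis
    return np.degrees(np.arctan2(z, y))


def _lab_axes(traj: MarkerTrajectorySet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    axis, sign = detect_anterior_axis(traj)
    anterior = np.zeros(3)
    anterior[axis] = sign
    vertical = np.array([0.0, 0.0, 1.0])
    if axis == 2:  # degenerate capture: walking along Z is not supported
        raise GaitError("anterior axis detected as vertical; check the trial")
    lateral = np.cross(anterior, vertical)
    return anterior, vertical, lateral


def joint_angle_series(traj: MarkerTrajectorySet, joint: str,
                       side: str = "none", plane: str = "sagittal"
                       ) -> JointAngleSeries:
    """Relative segment angles from the reduced marker set, degrees.

    Sagittal lower-limb angles follow a flexion-first rotation order: only
    the rotation about the mediolateral axis is reported, so the series is
    the difference of the two segments' sagittal-plane inclinations.
    Trunk flex-ext and lateral bending are the shoulder-girdle segment
    (pelvis-centre to mid-acromion) inclination relative to the pelvis
    vertical; trunk axial rotation is the yaw of the acromion line about the
    vertical, measured in the lab frame.
    """
    anterior, vertical, lateral = _lab_axes(traj)
    m = traj.markers
    prefix = side[0] if side in SIDES else None

    def seg(a: str, b: str) -> np.ndarray:
        v = m[b] - m[a]
        norms = np.linalg.norm(v, axis=1)
        if np.any(norms < 1e-9):
            raise GaitError(f"degenerate segment {a}->{b} (zero length)")
        return v

    if joint in ("hip", "knee", "ankle"):
        if plane != "sagittal":
            raise GaitError("lower-limb angles are reported in the sagittal plane only")
        if prefix is None:
            raise GaitError(f"{joint} angle requires side left/right")
        thigh = _sagittal_segment_angle(seg(f"{prefix}_asis", f"{prefix}_knee"),
                                        anterior, vertical, "down")
        if joint == "hip":
            pelvis_up = _sagittal_segment_angle(
                _pelvis_up_vector(m), anterior, vertical, "up")
            angles = thigh - pelvis_up
        elif joint == "knee":
            shank = _sagittal_segment_angle(
                seg(f"{prefix}_knee", f"{prefix}_malleolus"),
                anterior, vertical, "down")
            angles = thigh - shank
        else:  # ankle: foot pitch relative to shank inclination
            shank = _sagittal_segment_angle(
                seg(f"{prefix}_knee", f"{prefix}_malleolus"),
                anterior, vertical, "down")
            foot = _sagittal_segment_angle(seg(f"{prefix}_heel", f"{prefix}_toe"),
                                           anterior, vertical, "forward")
            angles = foot + shank
    elif joint == "trunk":
        pelvis_centre = (m["sacrum"] + m["l_asis"] + m["r_asis"]) / 3.0
        mid_shoulder = 0.5 * (m["l_acromion"] + m["r_acromion"])
        trunk_vec = mid_shoulder - pelvis_centre
        if np.any(np.linalg.norm(trunk_vec, axis=1) < 1e-9):
            raise GaitError("degenerate trunk segment")
        pelvis_up = _pelvis_up_vector(m)
        if plane == "sagittal":
            angles = (_sagittal_segment_angle(trunk_vec, anterior, vertical, "up")
                      - _sagittal_segment_angle(pelvis_up, anterior, vertical, "up"))
        elif plane == "frontal":
            angles = (np.degrees(np.arctan2(trunk_vec @ lateral, trunk_vec @ vertical))
                      - np.degrees(np.arctan2(pelvis_up @ lateral, pelvis_up @ vertical)))
        elif plane == "transverse":
            shoulder_line = m["r_acromion"] - m["l_acromion"]
            angles = np.degrees(np.arctan2(shoulder_line @ anterior,
                                           shoulder_line @ lateral))
        else:
            raise GaitError(f"unknown plane {plane!r}")
        side = "none"
    else:
        raise GaitError(f"unknown joint {joint!r}")

    return JointAngleSeries(joint, side, plane, angles, traj.sampling_rate)


def _pelvis_up_vector(m: dict[str, np.ndarray]) -> np.ndarray:
    """Proxy for the pelvis vertical axis: lateral x anterior-posterior."""
    ml = m["r_asis"] - m["l_asis"]
    ap = 0.5 * (m["r_asis"] + m["l_asis"]) - m["sacrum"]
    up = np.cross(ml, ap)
    norms = np.linalg.norm(up, axis=1, keepdims=True)
    if np.any(norms < 1e-9):
        raise GaitError("degenerate pelvis segment")
    return up / norms


def range_of_motion(series: JointAngleSeries,
                    windows: list[StepWindow] | None = None) -> float:
    """max - min of the angle series over the union of the step windows."""
    if windows is not None:
        if not windows:
            raise GaitError("empty window list")
        mask = np.zeros(len(series.angles_deg), dtype=bool)
        for w in windows:
            mask[w.start:w.stop] = True
        if not mask.any():
            raise GaitError("windows select no frames")
        values = series.angles_deg[mask]
    else:
        values = series.angles_deg
    return float(values.max() - values.min())
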