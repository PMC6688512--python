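"""Readers/writers and run configuration.

Marker trials travel as long-format CSV: columns ``trial, frame, marker,
x, y, z`` plus a ``# sampling_rate: <Hz>`` header comment.  Positions are
stored in mm; on read, metre-scaled files are auto-detected (coordinate
magnitudes) and converted.  The analysis configuration is a flat YAML
mapping validated against a documented schema.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gaitresp.types import MARKER_LABELS, GaitError, MarkerTrajectorySet

#: Accepted alternative marker spellings (vendor exports vary).
LABEL_ALIASES = {
    "lasis": "l_asis", "rasis": "r_asis", "sacr": "sacrum",
    "lhee": "l_heel", "rhee": "r_heel", "ltoe": "l_toe", "rtoe": "r_toe",
    "lkne": "l_knee", "rkne": "r_knee", "lmal": "l_malleolus",
    "rmal": "r_malleolus", "lsho": "l_acromion", "rsho": "r_acromion",
}


def normalize_label(label: str) -> str | None:
    key = label.strip().lower().replace("-", "_").replace(" ", "_")
    if key in MARKER_LABELS:
        return key
    return LABEL_ALIASES.get(key.replace("_", ""))


def write_markers_csv(traj: MarkerTrajectorySet, path: str | Path) -> None:
    """Long-format CSV with a sampling-rate header comment; mm units."""
    path = Path(path)
    frames = []
    for label, arr in traj.markers.items():
        df = pd.DataFrame(arr, columns=["x", "y", "z"])
        df.insert(0, "marker", label)
        df.insert(0, "frame", np.arange(arr.shape[0]))
        df.insert(0, "trial", traj.trial_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate: {traj.sampling_rate}\n")
        out.to_csv(fh, index=False, float_format="%.6f")


def read_markers_csv(path: str | Path,
                     sampling_rate: float | None = None) -> MarkerTrajectorySet:
    """Read a long-format marker CSV back into a trajectory set.

    Unknown marker labels are skipped with a warning; the mm-vs-m unit is
    auto-detected from coordinate magnitudes (a walking trial spans metres,
    so values must reach beyond 100 in mm but stay below 100 in m) and an
    ambiguous scale raises.
    """
    import logging
    log = logging.getLogger(__name__)
    path = Path(path)
    fs = sampling_rate
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            if "sampling_rate" in first:
                fs = float(first.split(":", 1)[1])
            df = pd.read_csv(fh)
        else:
            fh.seek(0)
            df = pd.read_csv(fh)
    if fs is None:
        raise GaitError(f"{path}: sampling rate neither in header nor supplied")
    required = {"trial", "frame", "marker", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise GaitError(f"{path}: malformed header, need columns {sorted(required)}")

    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    extent = np.nanmax(np.abs(coords)) if len(coords) else 0.0
    if extent > 50.0:
        scale = 1.0  # already mm
    elif extent > 0.05:
        scale = 1000.0  # metres
    else:
        raise GaitError(f"{path}: ambiguous coordinate units (extent {extent:g})")

    trial_ids = df["trial"].unique()
    if len(trial_ids) != 1:
        raise GaitError(f"{path}: expected one trial per file, got {len(trial_ids)}")
    markers: dict[str, np.ndarray] = {}
    n_frames = int(df["frame"].max()) + 1
    for label, sub in df.groupby("marker"):
        canonical = normalize_label(str(label))
        if canonical is None:
            log.warning("%s: unknown marker label %r skipped", path, label)
            continue
        arr = np.full((n_frames, 3), np.nan)
        idx = sub["frame"].to_numpy(dtype=int)
        arr[idx] = sub[["x", "y", "z"]].to_numpy(dtype=float) * scale
        markers[canonical] = arr
    if not markers:
        raise GaitError(f"{path}: no recognised markers")
    return MarkerTrajectorySet(str(trial_ids[0]), float(fs), markers)


@dataclass
class AnalysisConfig:
    """Validated run configuration for the end-to-end pipeline."""

    out_dir: str = "gaitresp_out"
    data_dir: str | None = None  # None -> simulate a cohort
    sampling_rate: float = 300.0
    filter_cutoff_hz: float = 6.0
    filter_order: int = 4
    filter_strict_order: bool = False
    speed_matching: bool = True
    normalization_k: float = 1.0
    removal_alpha: float = 0.10
    seed: int = 0
    n_patients: int = 36
    n_controls: int = 22
    n_trials_per_session: int = 6
    simulate_trajectories: bool = False  # False: parameter-level cohort
    n_trajectory_subjects: int = 2  # subjects run through full extraction

    def __post_init__(self) -> None:
        if self.sampling_rate <= 2 * self.filter_cutoff_hz:
            raise GaitError("sampling_rate must exceed twice the filter cutoff")
        if not 0 < self.removal_alpha <= 1:
            raise GaitError("removal_alpha must lie in (0, 1]")
        if self.normalization_k < 0:
            raise GaitError("normalization_k must be >= 0")
        if self.n_trials_per_session < 6:
            raise GaitError("n_trials_per_session must be >= 6")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise GaitError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))
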