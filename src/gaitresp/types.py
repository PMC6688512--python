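"""Core domain containers shared across the pipeline.

Coordinate convention (fixed throughout the package): +Y anterior (walking
direction), +Z vertical, +X to the subject's right.  Marker positions are
stored in millimetres; reported lengths are metres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Minimal marker dictionary: every variable the pipeline reports is
#: derivable from these 13 markers.
MARKER_LABELS = (
    "sacrum",
    "l_asis",
    "r_asis",
    "l_knee",
    "r_knee",
    "l_malleolus",
    "r_malleolus",
    "l_heel",
    "r_heel",
    "l_toe",
    "r_toe",
    "l_acromion",
    "r_acromion",
    "c7",
)

SIDES = ("left", "right")


class GaitError(ValueError):
    """Base class for domain validation errors."""


class TrialRejected(GaitError):
    """A trial failed a quality gate and is excluded from analysis."""


@dataclass(frozen=True)
class GaitProfile:
    """Ground-truth gait description for one subject at one session.

    ``step_length_a`` / ``step_length_na`` are the step lengths of the
    affected (most affected) and unaffected (least affected) sides in
    metres.  RoMs are sagittal-plane ranges in degrees except the trunk,
    which carries sagittal (flex-ext), frontal (bending) and transverse
    (rotation) ranges.  ``speed`` must equal
    ``mean(step_length) * cadence / 60`` (m/s); use
    :meth:`with_derived_speed` to construct a consistent profile.
    """

    step_length_a: float
    step_length_na: float
    cadence: float
    stance_pct: float
    double_support_pct: float
    step_width: float
    hip_rom_a: float
    hip_rom_na: float
    knee_rom_a: float
    knee_rom_na: float
    ankle_rom_a: float
    ankle_rom_na: float
    trunk_rom_sagittal: float
    trunk_rom_frontal: float
    trunk_rom_transverse: float
    speed: float
    affected_side: str = "left"

    _ROM_FIELDS = (
        "hip_rom_a", "hip_rom_na", "knee_rom_a", "knee_rom_na",
        "ankle_rom_a", "ankle_rom_na", "trunk_rom_sagittal",
        "trunk_rom_frontal", "trunk_rom_transverse",
    )

    def __post_init__(self) -> None:
        for name in ("step_length_a", "step_length_na", "cadence",
                     "step_width", "speed", *self._ROM_FIELDS):
            if getattr(self, name) <= 0:
                raise GaitError(f"{name} must be > 0")
        if not 50.0 < self.stance_pct < 75.0:
            raise GaitError("stance_pct must lie in (50, 75)")
        if not 0.0 < self.double_support_pct < self.stance_pct:
            raise GaitError("double_support_pct must lie in (0, stance_pct)")
        if self.affected_side not in SIDES:
            raise GaitError("affected_side must be 'left' or 'right'")
        expected = self.mean_step_length * self.cadence / 60.0
        if abs(self.speed - expected) > 1e-9:
            raise GaitError(
                f"inconsistent profile: speed {self.speed} != "
                f"mean_step*cadence/60 = {expected}"
            )

    @property
    def mean_step_length(self) -> float:
        return 0.5 * (self.step_length_a + self.step_length_na)

    @property
    def stride_duration(self) -> float:
        """Seconds per stride (two steps)."""
        return 120.0 / self.cadence

    @classmethod
    def with_derived_speed(cls, **kwargs) -> "GaitProfile":
        """Build a profile with speed derived from step length and cadence."""
        kwargs.pop("speed", None)
        mean_step = 0.5 * (kwargs["step_length_a"] + kwargs["step_length_na"])
        return cls(speed=mean_step * kwargs["cadence"] / 60.0, **kwargs)

    def step_length(self, side: str) -> float:
        return self.step_length_a if side == self.affected_side else self.step_length_na

    def rom(self, joint: str, side: str) -> float:
        suffix = "a" if side == self.affected_side else "na"
        return getattr(self, f"{joint}_rom_{suffix}")


@dataclass
class MarkerTrajectorySet:
    """Labelled 3D marker positions (mm) over frames at a fixed rate."""

    trial_id: str
    sampling_rate: float
    markers: dict[str, np.ndarray]  # label -> (n_frames, 3), mm; NaN = gap

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise GaitError("sampling_rate must be > 0")
        lengths = {m.shape[0] for m in self.markers.values()}
        if len(lengths) > 1:
            raise GaitError("all markers must share n_frames")
        for label, arr in self.markers.items():
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise GaitError(f"marker {label!r} must be (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return next(iter(self.markers.values())).shape[0]

    @property
    def labels(self) -> list[str]:
        return list(self.markers)

    def copy(self) -> "MarkerTrajectorySet":
        return MarkerTrajectorySet(
            self.trial_id, self.sampling_rate,
            {k: v.copy() for k, v in self.markers.items()},
        )


@dataclass
class GaitEvents:
    """Per-side heel-strike and toe-off frame indices (0-based).

    Events alternate per side and the first retained event is a heel
    strike; :meth:`validate` enforces both.
    """

    heel_strikes: dict[str, np.ndarray]  # side -> ordered frames
    toe_offs: dict[str, np.ndarray]

    def validate(self) -> None:
        for side in SIDES:
            hs = np.asarray(self.heel_strikes[side])
            to = np.asarray(self.toe_offs[side])
            if len(hs) == 0:
                raise GaitError(f"{side}: no heel strikes")
            if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
                raise GaitError(f"{side} events are not strictly increasing")
            if len(to) and to[0] <= hs[0]:
                raise GaitError(f"{side}: first retained event must be a heel strike")
            merged = sorted([(int(f), "HS") for f in hs] + [(int(f), "TO") for f in to])
            for (_, ta), (b, tb) in zip(merged, merged[1:]):
                if ta == tb:
                    raise GaitError(f"{side} events do not alternate near frame {b}")

    def n_strides(self, side: str) -> int:
        return max(len(self.heel_strikes[side]) - 1, 0)


@dataclass
class StepWindow:
    """Half-open frame window [start, stop) of one step of a given side."""

    side: str
    start: int
    stop: int
    trial_id: str = ""

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise GaitError("empty step window")


@dataclass
class JointAngleSeries:
    """One angle channel (degrees) aligned with its source trial frames."""

    joint: str  # hip | knee | ankle | trunk
    side: str  # left | right | none
    plane: str  # sagittal | frontal | transverse
    angles_deg: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if not np.all(np.isfinite(self.angles_deg)):
            raise GaitError("angle series contains non-finite values")


#: Canonical per-subject/session variable names (the reported parameter set).
PARAMETER_COLUMNS = (
    "cadence",
    "speed",
    "stance_pct_r",
    "stance_pct_l",
    "double_support_pct_r",
    "double_support_pct_l",
    "step_length_r",
    "step_length_l",
    "step_width",
    "spatial_asymmetry_pct",
    "hip_rom_r",
    "hip_rom_l",
    "knee_rom_r",
    "knee_rom_l",
    "ankle_rom_r",
    "ankle_rom_l",
    "trunk_rom_sagittal",
    "trunk_rom_frontal",
    "trunk_rom_transverse",
)


@dataclass
class SubjectSessionParameters:
    """The 19 reported gait variables for one subject at one session."""

    subject_id: str
    session: str  # baseline | followup
    values: dict[str, float] = field(default_factory=dict)
    n_steps_used: int = 0

    def __post_init__(self) -> None:
        v = self.values
        for side in ("r", "l"):
            st, ds = v.get(f"stance_pct_{side}"), v.get(f"double_support_pct_{side}")
            if st is not None and not 0 < st < 100:
                raise GaitError("stance_pct out of (0, 100)")
            if st is not None and ds is not None and ds >= st:
                raise GaitError("double support must be < stance")
        asym = v.get("spatial_asymmetry_pct")
        if asym is not None and not 0 <= asym <= 100:
            raise GaitError("spatial asymmetry out of [0, 100]")
        for key in ("speed", "cadence"):
            if v.get(key) is not None and v[key] <= 0:
                raise GaitError(f"{key} must be > 0")
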