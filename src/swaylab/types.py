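"""Shared domain containers.

Conventions used throughout the package:

* the four m-CTSIB conditions are EOSS, ECSS, EOFS, ECFS (eyes open/closed
  crossed with stable/foam surface), always in that test order;
* body axes are ML (medial-lateral), AP (anterior-posterior) and VT
  (vertical);
* sensor placements are ankle, lumbar, sternum, wrist and arm; lumbar and
  sternum sit on the midline (side "center"), the rest are worn on both
  sides and are relabeled dominant / non-dominant from handedness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidParameterError

CONDITIONS: tuple[str, ...] = ("EOSS", "ECSS", "EOFS", "ECFS")
PLACEMENTS: tuple[str, ...] = ("ankle", "lumbar", "sternum", "wrist", "arm")
CENTER_PLACEMENTS: tuple[str, ...] = ("lumbar", "sternum")
BILATERAL_PLACEMENTS: tuple[str, ...] = ("ankle", "wrist", "arm")
SIDES: tuple[str, ...] = ("left", "right", "center")
HANDEDNESS: tuple[str, ...] = ("right", "left")
AXES: tuple[str, ...] = ("ML", "AP", "VT")

#: the eight worn sensors of a session, in canonical order
SENSOR_SLOTS: tuple[tuple[str, str], ...] = (
    ("ankle", "left"),
    ("ankle", "right"),
    ("lumbar", "center"),
    ("sternum", "center"),
    ("wrist", "left"),
    ("wrist", "right"),
    ("arm", "left"),
    ("arm", "right"),
)


@dataclass
class COPTrace:
    """A timed 2-D center-of-pressure trajectory in inches.

    ``x`` is the medial-lateral displacement, ``y`` the anterior-posterior
    displacement, ``t`` uniformly spaced timestamps in seconds.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = self.t.size
        if not (self.x.size == self.y.size == n) or n < 2:
            raise InvalidParameterError(
                "COPTrace needs x, y, t of equal length >= 2"
            )
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise InvalidParameterError("COPTrace timestamps must increase")
        if not np.allclose(dt, 1.0 / self.fs, atol=1e-9):
            raise InvalidParameterError(
                "COPTrace timestamps must step uniformly by 1/fs"
            )

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class BalanceScore:
    """Per-condition ground-truth balance scores.

    ``pl`` is the COP path length in inches; ``av`` the average COP velocity
    in inches/second; ``av * duration_s == pl`` by construction.
    """

    condition: str
    pl: float
    av: float
    duration_s: float


@dataclass
class SensorRecording:
    """One sensor's raw tri-axial acceleration stream in device axes X/Y/Z.

    Device axes follow the study convention: X carries ML, Y carries AP and
    Z carries VT motion for every placement except the upper arm, where X
    carries AP and Y carries ML. :func:`swaylab.preprocessing.harmonize_axes`
    resolves this into body-axis labels.
    """

    subject_id: str
    placement: str
    side: str
    fs: float
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.placement not in PLACEMENTS:
            raise InvalidParameterError(f"unknown placement {self.placement!r}")
        if self.side not in SIDES:
            raise InvalidParameterError(f"unknown side {self.side!r}")
        for name in ("t", "x", "y", "z"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = self.t.size
        if not (self.x.size == self.y.size == self.z.size == n):
            raise InvalidParameterError("axes and time must have equal length")

    @property
    def n_samples(self) -> int:
        return self.t.size


@dataclass
class IMURecording:
    """A harmonized, per-condition tri-axial segment with body-axis labels."""

    subject_id: str
    placement: str
    role: str  # dominant / nondominant / center
    condition: str
    fs: float
    ml: np.ndarray
    ap: np.ndarray
    vt: np.ndarray

    def __post_init__(self) -> None:
        for name in ("ml", "ap", "vt"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.ml.size == self.ap.size == self.vt.size):
            raise InvalidParameterError("axes must have equal length")

    @property
    def n_samples(self) -> int:
        return self.ml.size

    def axis(self, name: str) -> np.ndarray:
        return {"ML": self.ml, "AP": self.ap, "VT": self.vt}[name]


@dataclass
class CueInterval:
    """Half-open [start_s, stop_s) interval labelling one condition."""

    condition: str
    start_s: float
    stop_s: float


@dataclass
class SessionManifest:
    """Per-subject description of one recording session."""

    subject_id: str
    handedness: str
    fs: float
    sensors: list[tuple[str, str, str]]  # (placement, side, file)
    cues: list[CueInterval]


@dataclass
class SubjectRecord:
    """One simulated subject: ground truth plus full sensor session streams."""

    subject_id: str
    handedness: str
    ability: float
    cop: dict[str, COPTrace] = field(default_factory=dict)
    scores: dict[str, BalanceScore] = field(default_factory=dict)
    #: full-session raw streams keyed by (placement, side)
    sessions: dict[tuple[str, str], SensorRecording] = field(default_factory=dict)
    cues: list[CueInterval] = field(default_factory=list)
    #: ground-truth sample range of each condition block within the session
    sample_ranges: dict[str, tuple[int, int]] = field(default_factory=dict)
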