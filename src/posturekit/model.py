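"""Domain types for pose-landmark records: captures, subjects, cohorts.

A :class:`PoseCapture` is one photo of one subject in one session, reduced to
33 labeled landmarks.  A :class:`SubjectRecord` bundles the captures of a
subject (up to three views per session) with the anthropometrics used by the
correlation analysis.  A :class:`Cohort` is a list of subjects plus a
provenance string (``"real"`` or ``"synthetic seed=..."``).

View classification follows the hip-midpoint / shoulder-hip-line mechanism:
a capture is *lateral* when the projected shoulder width collapses relative
to torso length, and frontal vs dorsal is decided by the x-ordering of the
labeled shoulders (a frontal photo mirrors anatomical left/right, so the
anatomical left shoulder sits at larger image x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import OrientationError
from .topology import GEOMETRY_LANDMARKS, LANDMARK_NAMES, N_LANDMARKS

#: default minimum landmark visibility for geometry input
DEFAULT_MIN_VISIBILITY = 0.5
#: lateral iff projected shoulder-width / torso-length is below this
LATERAL_WIDTH_RATIO = 0.35


@dataclass(frozen=True)
class Landmark:
    """One labeled pose landmark in image coordinates (pixels)."""

    name: str
    x: float
    y: float
    z: float = 0.0
    visibility: float = 1.0

    def __post_init__(self):
        if self.name not in LANDMARK_NAMES:
            raise ValueError(f"unknown landmark label {self.name!r}")
        if not (math.isfinite(self.x) and math.isfinite(self.y) and math.isfinite(self.z)):
            raise ValueError(f"non-finite coordinate for landmark {self.name!r}")
        if not 0.0 <= self.visibility <= 1.0:
            raise ValueError(
                f"visibility {self.visibility} outside [0, 1] for landmark {self.name!r}"
            )

    @property
    def xyz(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class PoseCapture:
    """One subject x view x session set of 33 labeled landmarks."""

    subject_id: str
    session: int
    view: str
    landmarks: dict[str, Landmark]
    image_size: tuple[int, int] | None = None

    def __post_init__(self):
        if self.view not in ("frontal", "dorsal", "lateral"):
            raise ValueError(f"unknown view {self.view!r}")
        if self.session < 1:
            raise ValueError("session must be >= 1")
        missing = [n for n in LANDMARK_NAMES if n not in self.landmarks]
        if missing:
            raise ValueError(
                f"capture {self.subject_id}/{self.view} is missing landmark(s): "
                + ", ".join(missing)
            )
        extra = [n for n in self.landmarks if n not in LANDMARK_NAMES]
        if extra:
            raise ValueError(
                f"capture {self.subject_id}/{self.view} has unknown label(s): "
                + ", ".join(extra)
            )
        if len(self.landmarks) != N_LANDMARKS:
            raise ValueError("capture must hold exactly 33 landmarks")

    def __getitem__(self, name: str) -> Landmark:
        return self.landmarks[name]


@dataclass
class SubjectRecord:
    """One participant: metadata plus all their captures."""

    subject_id: str
    sex: str | None = None  # "M" | "F" | None (unknown)
    age: float | None = None
    height: float | None = None  # cm
    weight: float | None = None  # kg
    captures: list[PoseCapture] = field(default_factory=list)

    def __post_init__(self):
        if self.sex is not None and self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M', 'F', or None, got {self.sex!r}")
        seen = set()
        for cap in self.captures:
            key = (cap.session, cap.view)
            if key in seen:
                raise ValueError(
                    f"subject {self.subject_id}: duplicate capture for session "
                    f"{cap.session} view {cap.view}"
                )
            seen.add(key)

    def capture(self, session: int, view: str) -> PoseCapture | None:
        for cap in self.captures:
            if cap.session == session and cap.view == view:
                return cap
        return None

    @property
    def sessions(self) -> list[int]:
        return sorted({c.session for c in self.captures})


@dataclass
class Cohort:
    """A list of subjects with unique ids."""

    subjects: list[SubjectRecord]
    provenance: str = "real"

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate subject ids: {dup}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self):
        return iter(self.subjects)

    def subject(self, subject_id: str) -> SubjectRecord:
        for s in self.subjects:
            if s.subject_id == subject_id:
                return s
        raise KeyError(subject_id)


def _midpoint(a: Landmark, b: Landmark) -> tuple[float, float]:
    return ((a.x + b.x) / 2.0, (a.y + b.y) / 2.0)


def detect_view(
    capture: PoseCapture,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
    lateral_ratio: float = LATERAL_WIDTH_RATIO,
) -> str:
    """Classify a capture as frontal, dorsal, or lateral.

    Lateral when the image-plane shoulder width is below ``lateral_ratio``
    times the torso length (shoulder midpoint to hip midpoint); otherwise the
    x-ordering of the labeled shoulders separates frontal (anatomical left at
    larger x: photos mirror) from dorsal.  Invariant under uniform translation
    and scaling of all coordinates.
    """
    required = ("left_shoulder", "right_shoulder", "left_hip", "right_hip")
    low = [n for n in required if capture[n].visibility < min_visibility]
    if low:
        raise OrientationError(
            "cannot determine orientation: low-visibility landmark(s) "
            + ", ".join(low)
        )
    ls, rs = capture["left_shoulder"], capture["right_shoulder"]
    sw = math.dist(ls.xy, rs.xy)
    smid = _midpoint(ls, rs)
    hmid = _midpoint(capture["left_hip"], capture["right_hip"])
    torso = math.dist(smid, hmid)
    if torso <= 0.0:
        raise OrientationError("degenerate torso: shoulder and hip midpoints coincide")
    if sw / torso < lateral_ratio:
        return "lateral"
    return "frontal" if ls.x > rs.x else "dorsal"


@dataclass(frozen=True)
class Finding:
    """One structured validation finding."""

    severity: str  # "error" | "warning"
    label: str
    message: str


def validate_capture(
    capture: PoseCapture,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
    strict_view: bool = False,
) -> list[Finding]:
    """Validate a capture; returns an empty list iff it is clean.

    Checks visibility of every landmark the geometry layer consumes, bounds
    of coordinates against ``image_size`` when present, and (optionally) that
    the declared view agrees with :func:`detect_view`.
    """
    findings: list[Finding] = []
    for name in GEOMETRY_LANDMARKS:
        lm = capture[name]
        if lm.visibility < min_visibility:
            findings.append(
                Finding(
                    "error",
                    name,
                    f"visibility {lm.visibility:.3f} below threshold {min_visibility}",
                )
            )
    if capture.image_size is not None:
        w, h = capture.image_size
        for name, lm in capture.landmarks.items():
            if not (0.0 <= lm.x <= w):
                findings.append(
                    Finding("warning", name, f"x={lm.x:.1f} outside [0, {w}]")
                )
            if not (0.0 <= lm.y <= h):
                findings.append(
                    Finding("warning", name, f"y={lm.y:.1f} outside [0, {h}]")
                )
    if strict_view:
        try:
            detected = detect_view(capture, min_visibility)
        except OrientationError as exc:
            findings.append(Finding("error", "view", str(exc)))
        else:
            if detected != capture.view:
                findings.append(
                    Finding(
                        "error",
                        "view",
                        f"declared view {capture.view!r} but detected {detected!r}",
                    )
                )
    return findings
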