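"""Postural parameters from pose landmarks.

Computes the 22 postural parameters of the analysis from a subject's
frontal, dorsal, and lateral captures:

* 7 body joint angles (degrees), computed on full (x, y, z) triples per side
  in each coronal view and fused with the circular mean over
  {frontal-left, frontal-right, dorsal-left, dorsal-right};
* 7 horizontal inclinations (degrees): the acute angle between a bilateral
  landmark line and the image horizontal, an asymmetry index, computed per
  coronal view and averaged arithmetically;
* 4 vertical inclinations (degrees): neck and trunk-forward from the lateral
  view, body imbalance (ankle-midpoint to shoulder-midpoint lean) and leg
  inclination from the coronal views;
* 4 body vector lengths in pixel distance (pd), image-plane (x, y) Euclidean.

Joint angle segment definitions (side-symmetric; "180 - " marks deviation
from a straight segment):

================== ==========================================================
shoulder_adduction angle at the shoulder: shoulder->elbow vs shoulder->hip
elbow_extension    180 - angle at the elbow: elbow->shoulder vs elbow->wrist
hip_adduction      180 - angle at the hip: hip->shoulder vs hip->knee
hip_extension      180 - same angle restricted to the sagittal (z-y) plane
knee_varus_valgus  180 - coronal (x-y) angle at the knee: knee->hip vs
                   knee->ankle
knee_extension     180 - sagittal (z-y) angle at the knee
ankle_flexion      angle at the ankle: ankle->knee vs ankle->foot_index
================== ==========================================================

All outputs are invariant under uniform translation of image coordinates;
angles are additionally invariant under uniform scaling, while vectors scale
linearly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    DegenerateSegmentError,
    InsufficientDataError,
    ParameterComputationError,
    UndefinedMeanError,
    WrongViewError,
)
from .model import DEFAULT_MIN_VISIBILITY, PoseCapture, SubjectRecord
from .topology import LINE_PAIRS, SIDES

log = logging.getLogger(__name__)

JOINT_ANGLE_PARAMS = (
    "shoulder_adduction",
    "elbow_extension",
    "hip_adduction",
    "hip_extension",
    "knee_varus_valgus",
    "knee_extension",
    "ankle_flexion",
)
HORIZONTAL_PARAMS = tuple(LINE_PAIRS)  # ear/shoulder/elbow/wrist/hip/knee/ankle _line
VERTICAL_PARAMS = (
    "neck_inclination",
    "trunk_forward_inclination",
    "body_imbalance",
    "leg_inclination",
)
VECTOR_PARAMS = (
    "shoulder_hip_difference",
    "torso_vector",
    "total_arm_vector",
    "total_leg_vector",
)
#: all parameters, in report row order
PARAMETER_NAMES = JOINT_ANGLE_PARAMS + HORIZONTAL_PARAMS + VERTICAL_PARAMS + VECTOR_PARAMS

#: parameters with test-retest reliability rows (vectors are excluded)
RELIABILITY_PARAMS = JOINT_ANGLE_PARAMS + HORIZONTAL_PARAMS + VERTICAL_PARAMS

_EPS = 1e-12


# ---------------------------------------------------------------------------
# primitives


def angle_between(u, v) -> float:
    """Angle between two vectors in degrees, in [0, 180].

    Equivalent to the arc-cosine of the clamped normalized dot product but
    computed as atan2(|u x v|, u . v), which stays well-conditioned near 0
    and 180 degrees.  Raises :class:`DegenerateSegmentError` on a
    zero-length input.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu < _EPS or nv < _EPS:
        raise DegenerateSegmentError("zero-length segment in angle computation")
    dot = float(np.dot(u, v))
    if u.size == 2:
        cross = abs(u[0] * v[1] - u[1] * v[0])
    else:
        cross = float(np.linalg.norm(np.cross(u, v)))
    return math.degrees(math.atan2(cross, dot))


def circular_mean(angles_deg, return_resultant: bool = False):
    """Circular mean of angles in degrees, mapped to [0, 360).

    Robust to 0/360 wraparound.  Raises :class:`UndefinedMeanError` when the
    resultant length is numerically zero (e.g. {0, 180}).  With
    ``return_resultant=True`` also returns the mean resultant length R in
    [0, 1] as a dispersion diagnostic.
    """
    a = np.radians(np.asarray(list(angles_deg), dtype=float))
    if a.size == 0:
        raise UndefinedMeanError("circular mean of an empty list")
    s = float(np.mean(np.sin(a)))
    c = float(np.mean(np.cos(a)))
    r = math.hypot(s, c)
    if r < 1e-9:
        raise UndefinedMeanError("circular mean undefined: zero resultant length")
    mean = math.degrees(math.atan2(s, c)) % 360.0
    if mean >= 360.0:  # a negative epsilon wraps to float 360.0 exactly
        mean = 0.0
    if return_resultant:
        return mean, r
    return mean


def _acute_from_axis(da: float, db: float) -> float:
    """Acute angle (deg) of a segment against an image axis: da along the
    axis, db across it."""
    if abs(da) < _EPS and abs(db) < _EPS:
        raise DegenerateSegmentError("coincident points")
    return math.degrees(math.atan2(abs(db), abs(da)))


def horizontal_inclination(left, right) -> float:
    """Acute angle in [0, 90] between the left-right segment (image-plane
    projection) and the image horizontal axis.  Symmetric in argument order."""
    ax, ay = _xy(left)
    bx, by = _xy(right)
    return _acute_from_axis(bx - ax, by - ay)


def vertical_inclination(top, bottom) -> float:
    """Acute angle in [0, 90] between the segment (image-plane projection)
    and the image vertical axis."""
    ax, ay = _xy(top)
    bx, by = _xy(bottom)
    return _acute_from_axis(by - ay, bx - ax)


def _xy(p):
    if hasattr(p, "xy"):
        return p.xy
    x, y = p[0], p[1]
    return float(x), float(y)


# ---------------------------------------------------------------------------
# per-capture computations


@dataclass
class ViewAngles:
    """Raw per-side joint angles (degrees) of one coronal capture."""

    view: str
    angles: dict[str, dict[str, float]]  # parameter -> side -> degrees

    def values_for(self, parameter: str) -> list[float]:
        return [self.angles[parameter][s] for s in SIDES]


def _p(capture: PoseCapture, name: str) -> np.ndarray:
    lm = capture[name]
    return np.array([lm.x, lm.y, lm.z], dtype=float)


def _check_visibility(capture: PoseCapture, names, min_visibility: float, parameter: str):
    low = [n for n in names if capture[n].visibility < min_visibility]
    if low:
        raise ParameterComputationError(
            f"{parameter}: low-visibility landmark(s) {', '.join(low)} in "
            f"{capture.view} capture of subject {capture.subject_id}",
            parameters=[parameter],
        )


def _plane(v: np.ndarray, plane: str) -> np.ndarray:
    if plane == "xy":
        return v[:2]
    if plane == "zy":
        return v[[2, 1]]
    raise ValueError(plane)


def joint_angles(
    capture: PoseCapture, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> ViewAngles:
    """Per-side raw joint angles for the 7 joint parameters of one coronal
    capture, using the segment definitions in the module docstring."""
    if capture.view not in ("frontal", "dorsal"):
        raise WrongViewError(
            f"joint angles require a coronal capture, got {capture.view!r}"
        )
    out: dict[str, dict[str, float]] = {p: {} for p in JOINT_ANGLE_PARAMS}
    for side in SIDES:

        def L(base: str) -> str:
            return f"{side}_{base}"

        needed = [
            L(b)
            for b in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle", "foot_index")
        ]
        _check_visibility(capture, needed, min_visibility, f"joint_angles[{side}]")
        sh = _p(capture, L("shoulder"))
        el = _p(capture, L("elbow"))
        wr = _p(capture, L("wrist"))
        hp = _p(capture, L("hip"))
        kn = _p(capture, L("knee"))
        an = _p(capture, L("ankle"))
        ft = _p(capture, L("foot_index"))

        out["shoulder_adduction"][side] = angle_between(el - sh, hp - sh)
        out["elbow_extension"][side] = 180.0 - angle_between(sh - el, wr - el)
        out["hip_adduction"][side] = 180.0 - angle_between(sh - hp, kn - hp)
        out["hip_extension"][side] = 180.0 - angle_between(
            _plane(sh - hp, "zy"), _plane(kn - hp, "zy")
        )
        out["knee_varus_valgus"][side] = 180.0 - angle_between(
            _plane(hp - kn, "xy"), _plane(an - kn, "xy")
        )
        out["knee_extension"][side] = 180.0 - angle_between(
            _plane(hp - kn, "zy"), _plane(an - kn, "zy")
        )
        out["ankle_flexion"][side] = angle_between(kn - an, ft - an)
    return ViewAngles(view=capture.view, angles=out)


def fuse_views(
    frontal: ViewAngles | None,
    dorsal: ViewAngles | None,
    average_sides: bool = True,
) -> dict[str, float]:
    """Fuse coronal joint angles with the circular mean.

    Per parameter the circular mean is taken over {frontal-left,
    frontal-right, dorsal-left, dorsal-right}; a missing view falls back to
    the other with a logged warning.  With ``average_sides=False`` the keys
    are ``parameter.side`` and fusion runs over views only.
    """
    views = [v for v in (frontal, dorsal) if v is not None]
    if not views:
        raise InsufficientDataError("no coronal view available for fusion")
    if len(views) == 1:
        log.warning("only the %s view available; fusing without its mirror", views[0].view)
    fused: dict[str, float] = {}
    for param in JOINT_ANGLE_PARAMS:
        if average_sides:
            fused[param] = circular_mean(
                [a for v in views for a in v.values_for(param)]
            )
        else:
            for side in SIDES:
                fused[f"{param}.{side}"] = circular_mean(
                    [v.angles[param][side] for v in views]
                )
    return fused


def horizontal_inclinations(
    capture: PoseCapture, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> dict[str, float]:
    """The 7 bilateral-line horizontal inclinations of one coronal capture."""
    if capture.view not in ("frontal", "dorsal"):
        raise WrongViewError(
            f"horizontal inclinations require a coronal capture, got {capture.view!r}"
        )
    out = {}
    for param, (lname, rname) in LINE_PAIRS.items():
        _check_visibility(capture, (lname, rname), min_visibility, param)
        out[param] = horizontal_inclination(capture[lname], capture[rname])
    return out


def vector_lengths(
    capture: PoseCapture, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> dict[str, float]:
    """The 4 body-vector parameters (pixel distance) of one coronal capture.

    Distances are image-plane (x, y) Euclidean; arm and leg totals are
    averaged over sides, and shoulder_hip_difference is shoulder width minus
    hip width.
    """
    if capture.view not in ("frontal", "dorsal"):
        raise WrongViewError(
            f"vector lengths require a coronal capture, got {capture.view!r}"
        )
    needed = [
        f"{s}_{b}"
        for s in SIDES
        for b in ("shoulder", "elbow", "wrist", "hip", "knee", "ankle")
    ]
    _check_visibility(capture, needed, min_visibility, "vector_lengths")

    def xy(name: str) -> np.ndarray:
        return np.array(capture[name].xy)

    def d(a: str, b: str) -> float:
        return float(np.linalg.norm(xy(a) - xy(b)))

    smid = (xy("left_shoulder") + xy("right_shoulder")) / 2.0
    hmid = (xy("left_hip") + xy("right_hip")) / 2.0
    arm = [d(f"{s}_shoulder", f"{s}_elbow") + d(f"{s}_elbow", f"{s}_wrist") for s in SIDES]
    leg = [d(f"{s}_hip", f"{s}_knee") + d(f"{s}_knee", f"{s}_ankle") for s in SIDES]
    return {
        "shoulder_hip_difference": d("left_shoulder", "right_shoulder")
        - d("left_hip", "right_hip"),
        "torso_vector": float(np.linalg.norm(smid - hmid)),
        "total_arm_vector": float(np.mean(arm)),
        "total_leg_vector": float(np.mean(leg)),
    }


def lateral_parameters(
    capture: PoseCapture, min_visibility: float = DEFAULT_MIN_VISIBILITY
) -> tuple[float, float]:
    """(neck_inclination, trunk_forward_inclination) from a lateral capture.

    Uses the camera-facing side, identified as the side whose shoulder has
    the smaller depth (z increases away from the camera); ties fall back to
    the left side.
    """
    if capture.view != "lateral":
        raise WrongViewError(f"lateral parameters require a lateral capture, got {capture.view!r}")
    side = "left" if capture["left_shoulder"].z <= capture["right_shoulder"].z else "right"
    names = [f"{side}_{b}" for b in ("ear", "shoulder", "hip")]
    _check_visibility(capture, names, min_visibility, "lateral_parameters")
    ear, sh, hp = (capture[n] for n in names)
    return vertical_inclination(ear, sh), vertical_inclination(sh, hp)


# ---------------------------------------------------------------------------
# profile assembly


@dataclass
class PostureProfile:
    """The named postural parameters of one subject x session.

    ``values`` maps every parameter name to degrees (angles, inclinations)
    or pixel distance (vectors); parameters that could not be computed (e.g.
    a missing lateral capture) are NaN and listed in ``missing``.
    """

    subject_id: str
    session: int
    values: dict[str, float]
    missing: tuple[str, ...] = field(default_factory=tuple)

    def __getitem__(self, parameter: str) -> float:
        return self.values[parameter]

    def as_array(self) -> np.ndarray:
        return np.array([self.values[p] for p in PARAMETER_NAMES], dtype=float)


def _cap_mean(per_capture: list[dict[str, float]], param: str) -> float:
    return float(np.mean([c[param] for c in per_capture]))


def compute_profile(
    subject: SubjectRecord,
    session: int = 1,
    min_visibility: float = DEFAULT_MIN_VISIBILITY,
) -> PostureProfile:
    """Assemble the full postural profile of one subject session.

    Requires at least one coronal capture; neck/trunk parameters come from
    the lateral capture and are flagged absent (NaN) when it is missing.
    """
    frontal = subject.capture(session, "frontal")
    dorsal = subject.capture(session, "dorsal")
    lateral = subject.capture(session, "lateral")
    coronal = [c for c in (frontal, dorsal) if c is not None]
    if not coronal:
        raise InsufficientDataError(
            f"subject {subject.subject_id} session {session}: no coronal capture"
        )

    failed: list[str] = []
    values: dict[str, float] = {}

    try:
        fused = fuse_views(
            joint_angles(frontal, min_visibility) if frontal else None,
            joint_angles(dorsal, min_visibility) if dorsal else None,
        )
        values.update(fused)
    except ParameterComputationError as exc:
        failed.extend(exc.parameters or JOINT_ANGLE_PARAMS)

    try:
        per_cap = [horizontal_inclinations(c, min_visibility) for c in coronal]
        for param in HORIZONTAL_PARAMS:
            values[param] = _cap_mean(per_cap, param)
    except ParameterComputationError as exc:
        failed.extend(exc.parameters or HORIZONTAL_PARAMS)

    try:
        per_cap = [vector_lengths(c, min_visibility) for c in coronal]
        for param in VECTOR_PARAMS:
            values[param] = _cap_mean(per_cap, param)
    except ParameterComputationError as exc:
        failed.extend(exc.parameters or VECTOR_PARAMS)

    # whole-body vertical inclinations from the coronal views
    try:
        imb, leg = [], []
        for cap in coronal:
            _check_visibility(
                cap,
                [f"{s}_{b}" for s in SIDES for b in ("shoulder", "hip", "ankle")],
                min_visibility,
                "body_imbalance/leg_inclination",
            )
            smid = (np.array(cap["left_shoulder"].xy) + np.array(cap["right_shoulder"].xy)) / 2
            amid = (np.array(cap["left_ankle"].xy) + np.array(cap["right_ankle"].xy)) / 2
            imb.append(vertical_inclination(amid, smid))
            leg.append(
                float(
                    np.mean(
                        [
                            vertical_inclination(cap[f"{s}_hip"], cap[f"{s}_ankle"])
                            for s in SIDES
                        ]
                    )
                )
            )
        values["body_imbalance"] = float(np.mean(imb))
        values["leg_inclination"] = float(np.mean(leg))
    except ParameterComputationError as exc:
        failed.extend(["body_imbalance", "leg_inclination"])

    absent: list[str] = []
    if lateral is None:
        log.warning(
            "subject %s session %d: no lateral capture; neck/trunk parameters absent",
            subject.subject_id,
            session,
        )
        absent.extend(["neck_inclination", "trunk_forward_inclination"])
    else:
        try:
            neck, trunk = lateral_parameters(lateral, min_visibility)
            values["neck_inclination"] = neck
            values["trunk_forward_inclination"] = trunk
        except ParameterComputationError:
            failed.extend(["neck_inclination", "trunk_forward_inclination"])

    if failed:
        raise ParameterComputationError(
            f"subject {subject.subject_id} session {session}: could not compute "
            + ", ".join(sorted(set(failed))),
            parameters=sorted(set(failed)),
        )
    for param in absent:
        values[param] = float("nan")
    return PostureProfile(
        subject_id=subject.subject_id,
        session=session,
        values=values,
        missing=tuple(absent),
    )


def profiles_to_frame(profiles) -> "pandas.DataFrame":
    """Profiles -> tidy table: one row per subject x session, one column per
    parameter (report row order), units encoded in the column name suffix."""
    import pandas as pd

    rows = []
    for prof in profiles:
        row = {"subject_id": prof.subject_id, "session": prof.session}
        row.update({p: prof.values.get(p, float("nan")) for p in PARAMETER_NAMES})
        rows.append(row)
    return pd.DataFrame(rows)
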