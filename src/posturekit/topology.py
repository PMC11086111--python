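"""The 33-point whole-body landmark topology used by markerless pose estimators.

Coordinates are image coordinates: ``x`` increases rightward, ``y`` increases
DOWNWARD (origin at the top-left corner), and ``z`` is a pixel-scaled depth
relative to the hip midpoint, increasing away from the camera.  Left/right in
landmark names is always ANATOMICAL left/right, regardless of the view the
photo was taken from.
"""

from __future__ import annotations

LANDMARK_NAMES: tuple[str, ...] = (
    "nose",
    "left_eye_inner",
    "left_eye",
    "left_eye_outer",
    "right_eye_inner",
    "right_eye",
    "right_eye_outer",
    "left_ear",
    "right_ear",
    "mouth_left",
    "mouth_right",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_pinky",
    "right_pinky",
    "left_index",
    "right_index",
    "left_thumb",
    "right_thumb",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_heel",
    "right_heel",
    "left_foot_index",
    "right_foot_index",
)

N_LANDMARKS = len(LANDMARK_NAMES)
LANDMARK_INDEX: dict[str, int] = {name: i for i, name in enumerate(LANDMARK_NAMES)}

VIEWS = ("frontal", "dorsal", "lateral")
CORONAL_VIEWS = ("frontal", "dorsal")

SIDES = ("left", "right")

#: bilateral landmark pairs whose connecting line defines a horizontal
#: inclination (asymmetry) parameter, in report order
LINE_PAIRS: dict[str, tuple[str, str]] = {
    "ear_line": ("left_ear", "right_ear"),
    "shoulder_line": ("left_shoulder", "right_shoulder"),
    "elbow_line": ("left_elbow", "right_elbow"),
    "wrist_line": ("left_wrist", "right_wrist"),
    "hip_line": ("left_hip", "right_hip"),
    "knee_line": ("left_knee", "right_knee"),
    "ankle_line": ("left_ankle", "right_ankle"),
}

#: landmarks the geometry layer actually consumes (visibility-gated)
GEOMETRY_LANDMARKS: tuple[str, ...] = (
    "left_ear",
    "right_ear",
    "left_shoulder",
    "right_shoulder",
    "left_elbow",
    "right_elbow",
    "left_wrist",
    "right_wrist",
    "left_hip",
    "right_hip",
    "left_knee",
    "right_knee",
    "left_ankle",
    "right_ankle",
    "left_foot_index",
    "right_foot_index",
)
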