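"""Normative reference values for healthy young adults.

Per-sex means and SDs of the postural parameters, per-parameter test-retest
reliability (ICC(3,2), SEM, MDC95), the two posture-type mixture observed in
the body-vector lengths (CG1: shorter segments, similar shoulder and hip
widths; CG2: longer segments, notably wider shoulders), and the cohort
anthropometrics.  These are the published normative statistics for a cohort
of 200 healthy 18-30 year olds (84 men, 116 women) and serve as the default
configuration of the synthetic-cohort generator.

Angles and inclinations in degrees; vector lengths in pixel distance (pd);
heights in cm.
"""

from __future__ import annotations

from .geometry import (
    JOINT_ANGLE_PARAMS,
    HORIZONTAL_PARAMS,
    PARAMETER_NAMES,
    RELIABILITY_PARAMS,
    VECTOR_PARAMS,
    VERTICAL_PARAMS,
)

#: per-sex (mean, SD) of every postural parameter, report row order
SEX_NORMS: dict[str, dict[str, tuple[float, float]]] = {
    "M": {
        "shoulder_adduction": (16.1, 1.9),
        "elbow_extension": (7.6, 3.6),
        "hip_adduction": (9.9, 2.2),
        "hip_extension": (3.4, 2.3),
        "knee_varus_valgus": (2.6, 1.0),
        "knee_extension": (2.7, 1.7),
        "ankle_flexion": (68.6, 5.3),
        "ear_line": (2.0, 1.5),
        "shoulder_line": (1.2, 0.7),
        "elbow_line": (1.2, 0.9),
        "wrist_line": (1.3, 0.9),
        "hip_line": (1.2, 0.8),
        "knee_line": (2.2, 1.3),
        "ankle_line": (1.9, 1.4),
        "neck_inclination": (13.6, 3.2),
        "trunk_forward_inclination": (2.3, 1.4),
        "body_imbalance": (0.9, 0.4),
        "leg_inclination": (1.8, 0.6),
        "shoulder_hip_difference": (83.8, 14.9),
        "torso_vector": (292.3, 26.3),
        "total_arm_vector": (297.5, 33.4),
        "total_leg_vector": (388.7, 32.4),
    },
    "F": {
        "shoulder_adduction": (14.1, 1.5),
        "elbow_extension": (4.4, 2.1),
        "hip_adduction": (6.7, 1.5),
        "hip_extension": (2.5, 1.7),
        "knee_varus_valgus": (2.2, 0.9),
        "knee_extension": (2.7, 1.8),
        "ankle_flexion": (72.9, 4.9),
        "ear_line": (2.0, 1.2),
        "shoulder_line": (1.2, 0.9),
        "elbow_line": (1.3, 0.9),
        "wrist_line": (1.5, 0.9),
        "hip_line": (1.5, 1.0),
        "knee_line": (2.1, 1.4),
        "ankle_line": (2.0, 1.3),
        "neck_inclination": (15.4, 3.3),
        "trunk_forward_inclination": (1.5, 1.1),
        "body_imbalance": (1.3, 0.6),
        "leg_inclination": (1.8, 0.6),
        "shoulder_hip_difference": (63.4, 13.3),
        "torso_vector": (244.7, 29.5),
        "total_arm_vector": (257.3, 32.9),
        "total_leg_vector": (358.2, 32.4),
    },
}

#: published test-retest ICC(3,2) per parameter (vectors carry none)
REFERENCE_ICC: dict[str, float] = {
    "shoulder_adduction": 0.94,
    "elbow_extension": 0.93,
    "hip_adduction": 0.95,
    "hip_extension": 0.78,
    "knee_varus_valgus": 0.93,
    "knee_extension": 0.84,
    "ankle_flexion": 0.85,
    "ear_line": 0.79,
    "shoulder_line": 0.73,
    "elbow_line": 0.85,
    "wrist_line": 0.83,
    "hip_line": 0.84,
    "knee_line": 0.67,
    "ankle_line": 0.80,
    "neck_inclination": 0.93,
    "trunk_forward_inclination": 0.77,
    "body_imbalance": 0.90,
    "leg_inclination": 0.80,
}

#: published SEM per parameter (degrees), used for worked examples
REFERENCE_SEM: dict[str, float] = {
    "shoulder_adduction": 0.22,
    "elbow_extension": 0.60,
    "hip_adduction": 0.16,
    "hip_extension": 0.81,
    "knee_varus_valgus": 0.17,
    "knee_extension": 0.68,
    "ankle_flexion": 0.67,
    "ear_line": 0.49,
    "shoulder_line": 0.48,
    "elbow_line": 0.33,
    "wrist_line": 0.34,
    "hip_line": 0.36,
    "knee_line": 0.83,
    "ankle_line": 0.67,
    "neck_inclination": 0.89,
    "trunk_forward_inclination": 0.43,
    "body_imbalance": 0.12,
    "leg_inclination": 0.23,
}

#: the two posture types found in the body-vector lengths, per-cluster
#: (mean, SD) in pd; sex-independent by the study's finding
CLUSTER_VECTOR_NORMS: dict[str, dict[str, tuple[float, float]]] = {
    "CG1": {
        "shoulder_hip_difference": (57.5, 7.0),
        "torso_vector": (233.4, 16.2),
        "total_arm_vector": (241.2, 14.1),
        "total_leg_vector": (342.6, 19.4),
    },
    "CG2": {
        "shoulder_hip_difference": (86.6, 10.7),
        "torso_vector": (295.9, 21.6),
        "total_arm_vector": (307.7, 23.4),
        "total_leg_vector": (400.3, 22.2),
    },
}

#: cohort anthropometrics: (mean, SD) height in cm, weight kg, age years
HEIGHT_NORMS = {"M": (175.0, 6.4), "F": (163.0, 6.1)}
WEIGHT_NORMS = {"M": (68.2, 10.8), "F": (54.4, 3.9)}
AGE_NORMS = {"M": (25.9, 5.2), "F": (24.1, 4.8)}

#: cohort composition: 84 men of 200 participants
MALE_FRACTION = 84 / 200

__all__ = [
    "SEX_NORMS",
    "REFERENCE_ICC",
    "REFERENCE_SEM",
    "CLUSTER_VECTOR_NORMS",
    "HEIGHT_NORMS",
    "WEIGHT_NORMS",
    "AGE_NORMS",
    "MALE_FRACTION",
    "JOINT_ANGLE_PARAMS",
    "HORIZONTAL_PARAMS",
    "VERTICAL_PARAMS",
    "VECTOR_PARAMS",
    "PARAMETER_NAMES",
    "RELIABILITY_PARAMS",
]
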