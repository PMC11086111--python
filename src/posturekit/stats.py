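"""Inferential layer: normality gating, two-group comparisons with effect
sizes, height-posture correlation, and test-retest reliability.

Conventions

* Normality is tested per parameter per group with Shapiro-Wilk at alpha
  0.05; both groups normal -> classical pooled-variance Student's t (a Welch
  option is available), otherwise Mann-Whitney U (two-sided).
* Cohen's d uses the average-variance denominator
  d = (mean_b - mean_a) / sqrt((sd_a^2 + sd_b^2) / 2); this is the form that
  reproduces the reported effect sizes from group means and SDs, and it is
  deliberately not configurable.
* Reliability: ICC(3,k) is the two-way mixed-effects, consistency,
  average-of-k-measurements intraclass correlation,
  (MS_subjects - MS_error) / MS_subjects from the two-way ANOVA
  decomposition.  SEM = SD_pooled * sqrt(1 - ICC) with SD_pooled the SD of
  all n x k measurements after centering each session (consistency-
  compatible); MDC95 = 1.96 * sqrt(2) * SEM.
* Raw p-values are reported (stars at 0.05/0.01/0.001); an optional Holm
  adjustment is off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import (
    IncompleteDesignError,
    InsufficientSampleError,
    InsufficientVarianceError,
    InvalidInputError,
    PairingError,
)
from .geometry import PARAMETER_NAMES, RELIABILITY_PARAMS

ALPHA = 0.05
#: Pearson correlations are flagged relevant only when p < 0.05 and r > 0.45
RELEVANCE_R = 0.45
MDC_FACTOR = 1.96 * math.sqrt(2.0)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# normality and two-group comparison


def normality_gate(values) -> tuple[float, float, bool]:
    """Shapiro-Wilk (W, p, is_normal) with is_normal = (p >= 0.05)."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientSampleError(f"normality test needs n >= 3, got {x.size}")
    if np.ptp(x) == 0.0:
        raise InsufficientVarianceError("constant sample: normality test undefined")
    w, p = sps.shapiro(x)
    return float(w), float(p), bool(p >= ALPHA)


def cohens_d(mean_a: float, sd_a: float, mean_b: float, sd_b: float) -> float:
    """Signed Cohen's d with the average-variance denominator.

    Positive when the second-listed group has the larger mean, matching the
    (group 1, group 2) column orientation of the report tables.
    """
    if sd_a <= 0.0 or sd_b <= 0.0:
        raise InvalidInputError("Cohen's d undefined for non-positive SDs")
    return (mean_b - mean_a) / math.sqrt((sd_a**2 + sd_b**2) / 2.0)


@dataclass
class GroupComparison:
    """Two-group summary for one parameter."""

    parameter: str
    groups: tuple[str, str]
    n: tuple[int, int]
    means: tuple[float, float]
    sds: tuple[float, float]
    test: str  # "student_t" | "welch_t" | "mann_whitney_u"
    p_value: float
    cohens_d: float

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def compare_groups(
    a,
    b,
    parameter: str = "",
    groups: tuple[str, str] = ("A", "B"),
    welch: bool = False,
) -> GroupComparison:
    """Compare two samples with the normality-gated test and attach d.

    Student's t (pooled variance, two-sided) when both samples pass the
    Shapiro-Wilk gate, else Mann-Whitney U.  ``welch=True`` swaps the
    pooled-variance t for Welch's t.
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size < 3 or y.size < 3:
        raise InsufficientSampleError("both groups need n >= 3")
    if np.ptp(x) == 0.0 and np.ptp(y) == 0.0 and x[0] == y[0]:
        # identical constant samples: no evidence of a difference
        return GroupComparison(
            parameter, groups, (x.size, y.size),
            (float(x.mean()), float(y.mean())),
            (float(x.std(ddof=1)), float(y.std(ddof=1))),
            "student_t", 1.0, 0.0,
        )
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InsufficientVarianceError("degenerate (constant) sample")
    _, _, x_normal = normality_gate(x)
    _, _, y_normal = normality_gate(y)
    if x_normal and y_normal:
        test = "welch_t" if welch else "student_t"
        _, p = sps.ttest_ind(x, y, equal_var=not welch)
    else:
        test = "mann_whitney_u"
        _, p = sps.mannwhitneyu(x, y, alternative="two-sided")
    mx, my = float(x.mean()), float(y.mean())
    sx, sy = float(x.std(ddof=1)), float(y.std(ddof=1))
    d = 0.0 if mx == my else cohens_d(mx, sx, my, sy)
    return GroupComparison(
        parameter, groups, (x.size, y.size), (mx, my), (sx, sy), test, float(p), d
    )


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjusted p-values (optional; reports default to raw)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    m = p.size
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(1.0, running)
    return adj


# ---------------------------------------------------------------------------
# correlations


@dataclass
class CorrelationResult:
    pair: tuple[str, str]
    pearson_r: float
    p_value: float
    relevant: bool


def pearson_with_relevance(x, y, pair=("x", "y")) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientSampleError("paired observations with n >= 3 required")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise InsufficientVarianceError("zero variance: correlation undefined")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(
        tuple(pair), float(r), float(p), bool(p < ALPHA and r > RELEVANCE_R)
    )


def height_correlations(profile_frame, heights) -> list[CorrelationResult]:
    """Pearson r of every postural parameter against body height.

    ``profile_frame`` is the tidy profile table (one row per subject, see
    :func:`posturekit.geometry.profiles_to_frame`), ``heights`` a matching
    sequence in cm.  Parameters with missing values are skipped.
    """
    h = np.asarray(heights, dtype=float)
    results = []
    for param in PARAMETER_NAMES:
        if param not in profile_frame:
            continue
        vals = np.asarray(profile_frame[param], dtype=float)
        keep = np.isfinite(vals) & np.isfinite(h)
        if keep.sum() < 3:
            continue
        results.append(
            pearson_with_relevance(h[keep], vals[keep], pair=("height", param))
        )
    return results


# ---------------------------------------------------------------------------
# reliability


def icc_3k(measurements) -> float:
    """ICC(3,k): two-way mixed effects, consistency, average of k measures.

    ``measurements`` is an n-subjects x k-sessions matrix with no missing
    cells; returns (MS_subjects - MS_error) / MS_subjects.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2:
        raise IncompleteDesignError("measurements must be an n x k matrix")
    n, k = m.shape
    if n < 3 or k < 2:
        raise InsufficientSampleError(f"ICC needs n >= 3 subjects and k >= 2 sessions, got {n} x {k}")
    if not np.all(np.isfinite(m)):
        raise IncompleteDesignError("missing cells in the measurement matrix")
    grand = m.mean()
    subj_means = m.mean(axis=1)
    sess_means = m.mean(axis=0)
    ms_subjects = k * np.sum((subj_means - grand) ** 2) / (n - 1)
    resid = m - subj_means[:, None] - sess_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))
    if ms_subjects == 0.0:
        raise InsufficientVarianceError("no between-subject variance: ICC undefined")
    return float((ms_subjects - ms_error) / ms_subjects)


def sem_from_icc(sd_pooled: float, icc: float) -> float:
    """Standard error of measurement, SD_pooled * sqrt(1 - ICC)."""
    if not 0.0 <= icc <= 1.0:
        raise InvalidInputError(f"ICC {icc} outside [0, 1]")
    if sd_pooled < 0.0:
        raise InvalidInputError("sd_pooled must be >= 0")
    return sd_pooled * math.sqrt(1.0 - icc)


def mdc95(sem: float) -> float:
    """Minimal detectable change at 95% confidence, 1.96 * sqrt(2) * SEM."""
    if sem < 0.0:
        raise InvalidInputError("SEM must be >= 0")
    return MDC_FACTOR * sem


def session_centered_sd(measurements) -> float:
    """SD of all n x k measurements after centering each session
    (consistency-compatible pooling across sessions)."""
    m = np.asarray(measurements, dtype=float)
    centered = m - m.mean(axis=0, keepdims=True)
    return float(centered.std(ddof=1))


@dataclass
class ReliabilityRow:
    parameter: str
    icc_3k: float
    sem: float
    mdc95: float
    n_subjects: int
    k_sessions: int


def reliability_table(session1_profiles, session2_profiles) -> list[ReliabilityRow]:
    """Per-parameter ICC(3,k), SEM, and MDC95 from two matched sessions.

    Vector-length parameters carry no reliability row (matching the report
    layout); subjects present in only one session raise a pairing error
    listing the orphans.
    """
    s1 = {p.subject_id: p for p in session1_profiles}
    s2 = {p.subject_id: p for p in session2_profiles}
    orphans = sorted(set(s1) ^ set(s2))
    if orphans:
        raise PairingError(
            f"unmatched subject ids between sessions: {', '.join(orphans)}",
            orphans=orphans,
        )
    ids = sorted(s1)
    if len(ids) < 3:
        raise InsufficientSampleError(f"reliability needs n >= 3 subjects, got {len(ids)}")
    rows = []
    for param in RELIABILITY_PARAMS:
        m = np.array([[s1[i][param], s2[i][param]] for i in ids], dtype=float)
        keep = np.all(np.isfinite(m), axis=1)
        mk = m[keep]
        if mk.shape[0] < 3:
            continue
        icc = icc_3k(mk)
        sem = sem_from_icc(session_centered_sd(mk), max(0.0, min(1.0, icc)))
        rows.append(
            ReliabilityRow(
                parameter=param,
                icc_3k=icc,
                sem=sem,
                mdc95=mdc95(sem),
                n_subjects=int(mk.shape[0]),
                k_sessions=2,
            )
        )
    return rows


# ---------------------------------------------------------------------------
# report assembly


def comparison_table(profile_frame, labels, group_names, welch: bool = False):
    """Per-parameter :func:`compare_groups` over a tidy profile table.

    ``labels`` assigns each row of ``profile_frame`` to one of the two
    ``group_names``; rows with missing parameter values are dropped per
    parameter.  Returns a list of :class:`GroupComparison`.
    """
    labels = np.asarray(labels)
    out = []
    for param in PARAMETER_NAMES:
        if param not in profile_frame:
            continue
        vals = np.asarray(profile_frame[param], dtype=float)
        keep = np.isfinite(vals)
        a = vals[keep & (labels == group_names[0])]
        b = vals[keep & (labels == group_names[1])]
        if a.size < 3 or b.size < 3:
            continue
        out.append(
            compare_groups(a, b, parameter=param, groups=tuple(group_names), welch=welch)
        )
    return out


def comparison_frame(comparisons):
    """GroupComparison list -> report DataFrame (display rounding: means/SDs
    to 1 decimal, d to 2)."""
    import pandas as pd

    rows = []
    for c in comparisons:
        rows.append(
            {
                "parameter": c.parameter,
                f"{c.groups[0]}_mean": round(c.means[0], 1),
                f"{c.groups[0]}_sd": round(c.sds[0], 1),
                f"{c.groups[1]}_mean": round(c.means[1], 1),
                f"{c.groups[1]}_sd": round(c.sds[1], 1),
                "test": c.test,
                "p_value": c.p_value,
                "sig": c.stars,
                "cohens_d": round(c.cohens_d, 2),
            }
        )
    return pd.DataFrame(rows)


def reliability_frame(rows):
    """ReliabilityRow list -> report DataFrame (ICC/SEM/MDC to 2 decimals)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "icc_3k": round(r.icc_3k, 2),
                "sem": round(r.sem, 2),
                "mdc95": round(r.mdc95, 2),
                "n": r.n_subjects,
                "k": r.k_sessions,
            }
            for r in rows
        ]
    )
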