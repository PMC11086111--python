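"""Synthetic posture cohorts with the statistical structure the analysis
assumes.

The generator draws, per subject:

* angle and inclination parameters from per-sex normal distributions
  (normative means and SDs), truncated at zero;
* the four body-vector lengths from a sex-INDEPENDENT two-component
  mixture (the two posture types CG1/CG2), so that cluster discovery has a
  ground truth that is not just sex;
* height per sex, coupled to the vector lengths through a Gaussian copula
  whose within-sex coefficient is calibrated analytically so the POOLED
  height-vector Pearson correlation hits the requested target;
* retest sessions as parameter = truth + e with independent Gaussian
  measurement error per session, its SD derived from the target ICC(3,k)
  by inverse Spearman-Brown, so the estimated ICC recovers the target.

Landmark-level cohorts are synthesized by the stick-figure inverse
(:mod:`posturekit.skeleton`): at zero jitter the measurement pipeline
recovers every generated parameter exactly, which is the core identity the
test suite leans on.  A few per-parameter guards keep independently drawn
parameters jointly realizable by a standing skeleton (see
``_apply_feasibility_guards``); a draw the skeleton solver still rejects is
resampled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import PoseInfeasibleError, SpecError
from .geometry import PARAMETER_NAMES, VECTOR_PARAMS
from .model import Cohort, SubjectRecord
from .norms import (
    AGE_NORMS,
    CLUSTER_VECTOR_NORMS,
    HEIGHT_NORMS,
    MALE_FRACTION,
    REFERENCE_ICC,
    SEX_NORMS,
    WEIGHT_NORMS,
)
from .skeleton import (
    DEFAULT_PROPORTIONS,
    Proportions,
    SIGNED_PARAMS,
    StickFigure,
    figure_to_capture,
    implied_thigh_tilt,
    leg_inclination_band,
)

ANGLE_PARAMS = tuple(p for p in PARAMETER_NAMES if p not in VECTOR_PARAMS)


@dataclass(frozen=True)
class SyntheticSpec:
    """Configuration of the synthetic cohort generator.

    Defaults encode the study conditions: a 200-subject cohort (42% men), a
    balanced two-cluster vector mixture, height-vector correlation targets
    of 0.5 (pooled), per-parameter retest reliability at the published
    ICC(3,2) values for a 90-subject retest subgroup, and 0.5 px landmark
    jitter (calibrated so extracted retest ICCs land in the observed
    0.67-0.95 range on top of the parameter-level session noise).
    """

    n_subjects: int = 200
    male_fraction: float = MALE_FRACTION
    seed: int = 0
    sex_norms: dict = field(default_factory=lambda: {s: dict(v) for s, v in SEX_NORMS.items()})
    cluster_norms: dict = field(
        default_factory=lambda: {c: dict(v) for c, v in CLUSTER_VECTOR_NORMS.items()}
    )
    cluster_weight: float = 0.5  # probability of CG1
    height_norms: dict = field(default_factory=lambda: dict(HEIGHT_NORMS))
    vector_height_r: float = 0.5  # pooled Pearson target, all four vectors
    target_icc: dict = field(default_factory=lambda: dict(REFERENCE_ICC))
    retest_n: int = 90
    jitter_sd: float = 0.5  # px
    proportions: Proportions = DEFAULT_PROPORTIONS

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise SpecError("n_subjects must be >= 1")
        if not 0.0 < self.cluster_weight < 1.0:
            raise SpecError("cluster mixture weight must be in (0, 1)")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise SpecError("male_fraction must be in [0, 1]")
        if abs(self.vector_height_r) >= 1.0:
            raise SpecError("|vector-height correlation target| must be < 1")
        for sex, norms in self.sex_norms.items():
            for name, (mu, sd) in norms.items():
                if sd < 0:
                    raise SpecError(f"negative SD for {sex}/{name}")
        for name, icc in self.target_icc.items():
            if not 0.0 < icc <= 1.0:
                raise SpecError(f"target ICC for {name} must be in (0, 1]")
        if self.jitter_sd < 0:
            raise SpecError("jitter_sd must be >= 0")


@dataclass
class GroundTruth:
    """Everything the generator knows about its cohort.

    ``profiles`` is the n x 22 matrix of true (noiseless) parameters;
    ``session_profiles`` maps session -> per-subject measured parameter
    matrices (truth + session measurement error, before landmark jitter).
    """

    spec: SyntheticSpec
    subject_ids: list[str]
    sex: np.ndarray  # "M"/"F" per subject
    cluster: np.ndarray  # "CG1"/"CG2" per subject
    height: np.ndarray  # cm
    age: np.ndarray
    weight: np.ndarray
    profiles: np.ndarray  # (n, 22) true parameters, PARAMETER_NAMES order
    session_profiles: dict[int, np.ndarray]
    signs: list[dict[str, int]]  # construction signs per subject
    resampled: int = 0  # draws rejected by the skeleton feasibility guard

    def profile_frame(self, session: int | None = None):
        """True (or per-session) parameters as a tidy DataFrame."""
        import pandas as pd

        mat = self.profiles if session is None else self.session_profiles[session]
        df = pd.DataFrame(mat, columns=list(PARAMETER_NAMES))
        df.insert(0, "subject_id", self.subject_ids[: mat.shape[0]])
        df.insert(1, "sex", self.sex[: mat.shape[0]])
        df.insert(2, "cluster", self.cluster[: mat.shape[0]])
        df.insert(3, "height", self.height[: mat.shape[0]])
        return df


def _truncated_normal(rng, mu, sd, lo=0.0):
    """One draw from N(mu, sd) conditioned on >= lo (rejection; the guard
    region is far in the tail for every parameter used here)."""
    if sd == 0.0:
        return max(mu, lo)
    for _ in range(200):
        v = rng.normal(mu, sd)
        if v >= lo:
            return v
    return lo


def pooled_sd(norms_by_group: dict[str, tuple[float, float]], weights: dict[str, float]) -> float:
    """SD of a mixture of normals: E[var] + var of means."""
    mean = sum(weights[g] * norms_by_group[g][0] for g in norms_by_group)
    var = sum(
        weights[g] * (norms_by_group[g][1] ** 2 + (norms_by_group[g][0] - mean) ** 2)
        for g in norms_by_group
    )
    return math.sqrt(var)


def _vector_copula_calibration(spec: SyntheticSpec):
    """Calibrate the height-vector Gaussian copula analytically.

    Height enters the vectors through two channels, both driven by the
    subject's within-sex height z-score: (a) the posture-type assignment
    loads on it with coefficient rho_c (taller subjects are likelier to be
    the long-segment type; the assignment stays independent of sex and its
    marginal weight is preserved), and (b) a within-cluster coefficient
    r_w per vector.  The pooled Pearson correlation with height is matched
    to the target by first-order moment matching:

        cov(z, v) = rho_c * phi(c0) * (mu_CG2 - mu_CG1) + r_w * E[sd_c]

    with c0 the assignment threshold.  rho_c is chosen just large enough
    that every within-cluster coefficient stays small.
    Returns (rho_c, {vector: r_w}, E[z|cluster], SD[z|cluster]).
    """
    from scipy.stats import norm

    w_sex = {"M": spec.male_fraction, "F": 1.0 - spec.male_fraction}
    sd_hp = pooled_sd(spec.height_norms, w_sex)
    mean_sd_hw = sum(w_sex[s] * spec.height_norms[s][1] for s in w_sex)
    w_cl = {"CG1": spec.cluster_weight, "CG2": 1.0 - spec.cluster_weight}
    c0 = norm.ppf(spec.cluster_weight)
    phi0 = norm.pdf(c0)

    need, dmu, esd = {}, {}, {}
    for name in VECTOR_PARAMS:
        mu1, sd1 = spec.cluster_norms["CG1"][name]
        mu2, sd2 = spec.cluster_norms["CG2"][name]
        sd_vp = pooled_sd({c: spec.cluster_norms[c][name] for c in w_cl}, w_cl)
        need[name] = spec.vector_height_r * sd_hp * sd_vp / mean_sd_hw
        dmu[name] = mu2 - mu1
        esd[name] = w_cl["CG1"] * sd1 + w_cl["CG2"] * sd2

    def cond_moments(rho):
        """E[z|c] and SD[z|c] for both clusters at assignment loading rho."""
        p1 = spec.cluster_weight
        lam1 = -phi0 / p1  # E[latent | latent < c0]
        lam2 = phi0 / (1.0 - p1)
        v1 = 1.0 + c0 * lam1 - lam1**2
        v2 = 1.0 + c0 * lam2 - lam2**2
        m = {"CG1": rho * lam1, "CG2": rho * lam2}
        s = {
            "CG1": math.sqrt(1.0 - rho**2 + rho**2 * v1),
            "CG2": math.sqrt(1.0 - rho**2 + rho**2 * v2),
        }
        return m, s

    # prefer the assignment channel: within-cluster coupling inflates the
    # clusters along their separation direction and blurs recovery, so
    # rho_c is chosen to leave only a small within-cluster remainder
    rho_c = 0.0
    if phi0 > 0:
        for _ in range(3):  # s_z depends on rho_c: short fixed point
            _, s_tmp = cond_moments(rho_c)
            cand = 0.0
            for name in VECTOR_PARAMS:
                if abs(dmu[name]) > 1e-9:
                    eff = sum(
                        w_cl[c] * spec.cluster_norms[c][name][1] * s_tmp[c]
                        for c in w_cl
                    )
                    cand = max(cand, (need[name] - 0.15 * eff) / (phi0 * dmu[name]))
            rho_c = min(max(cand, 0.0), 0.95)
    m_z, s_z = cond_moments(rho_c)
    r_w = {}
    for name in VECTOR_PARAMS:
        # within-cluster channel uses the cluster-centered, cluster-scaled
        # height score (conditional vector moments stay exactly on target),
        # which costs an efficiency factor E[sd_c * SD(z|c)]
        eff = sum(
            w_cl[c] * spec.cluster_norms[c][name][1] * s_z[c] for c in w_cl
        )
        if eff < 1e-12:  # degenerate (zero-SD) clusters: no within channel
            r_w[name] = 0.0
            continue
        r = (need[name] - rho_c * phi0 * dmu[name]) / eff
        if abs(r) >= 0.97:
            raise SpecError(
                f"height-vector correlation target {spec.vector_height_r} "
                f"is infeasible for {name}"
            )
        r_w[name] = r
    return rho_c, r_w, m_z, s_z


def _apply_feasibility_guards(p: dict[str, float], rng) -> bool:
    """Adjust a parameter draw in place so a standing skeleton can realize
    it; returns False for draws that must be rejected outright.

    Guards: hip extension cannot consume the whole 3-D hip-adduction angle;
    the mean leg inclination is clipped into the band reachable given the
    hip/knee/imbalance targets; strongly crossing legs are rejected.
    """
    p["hip_extension"] = min(p["hip_extension"], 0.9 * p["hip_adduction"])
    lo, hi = leg_inclination_band(
        p["hip_adduction"],
        p["hip_extension"],
        p["knee_varus_valgus"],
        p["body_imbalance"],
        p["shoulder_hip_difference"],
        p["torso_vector"],
    )
    margin = min(0.5, (hi - lo) / 2.5) if hi > lo else 0.0
    p["leg_inclination"] = min(
        max(p["leg_inclination"], lo + margin), max(lo + margin, hi - margin)
    )
    tau = implied_thigh_tilt(
        p["hip_adduction"],
        p["hip_extension"],
        p["shoulder_hip_difference"],
        p["torso_vector"],
    )
    return abs(tau) + p["body_imbalance"] <= 9.5


def _draw_cluster(spec: SyntheticSpec, z_height: float, rng) -> str:
    """Posture-type assignment loading on the height z-score (coefficient
    rho_c); the marginal weight of CG1 equals ``spec.cluster_weight`` and
    the assignment is independent of sex."""
    from scipy.stats import norm

    rho = spec._copula[0]
    latent = rho * z_height + math.sqrt(1.0 - rho**2) * rng.normal()
    return "CG1" if latent < norm.ppf(spec.cluster_weight) else "CG2"


def _draw_subject_parameters(spec: SyntheticSpec, sex: str, cluster: str, z_height: float, rng):
    """One subject's 22 true parameters (dict) given sex, cluster, and the
    height z-score driving the vector copula."""
    _, r_w, m_z, s_z = spec._copula  # cached by sample_parameters
    z_c = (z_height - m_z[cluster]) / s_z[cluster]  # cluster-conditioned score
    p: dict[str, float] = {}
    for name in ANGLE_PARAMS:
        mu, sd = spec.sex_norms[sex][name]
        p[name] = _truncated_normal(rng, mu, sd, lo=0.05)
    for name in VECTOR_PARAMS:
        mu, sd = spec.cluster_norms[cluster][name]
        z = r_w[name] * z_c + math.sqrt(1.0 - r_w[name] ** 2) * rng.normal()
        val = mu + sd * z
        if name != "shoulder_hip_difference":
            val = max(val, 0.3 * mu)  # physical floor, ~2.3 SD out
        p[name] = val
    return p


def sample_parameters(spec: SyntheticSpec, rng: np.random.Generator | None = None) -> GroundTruth:
    """Draw the full ground truth of a cohort (no landmarks yet)."""
    spec.validate()
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    object.__setattr__(spec, "_copula", _vector_copula_calibration(spec))

    n = spec.n_subjects
    ids = [f"S{i:04d}" for i in range(n)]
    n_male = int(round(spec.male_fraction * n))
    sex = np.array(["M"] * n_male + ["F"] * (n - n_male))
    rng.shuffle(sex)
    cluster = np.empty(n, dtype=object)

    heights = np.empty(n)
    ages = np.empty(n)
    weights = np.empty(n)
    profiles = np.empty((n, len(PARAMETER_NAMES)))
    signs: list[dict[str, int]] = []
    resampled = 0
    for i in range(n):
        s = str(sex[i])
        mu_h, sd_h = spec.height_norms[s]
        for _ in range(200):
            z = rng.normal()
            cl = _draw_cluster(spec, z, rng)
            p = _draw_subject_parameters(spec, s, cl, z, rng)
            if _apply_feasibility_guards(p, rng):
                break
            resampled += 1
        else:
            raise SpecError("could not draw a feasible subject in 200 attempts")
        cluster[i] = cl
        heights[i] = mu_h + sd_h * z
        ages[i] = _truncated_normal(rng, *AGE_NORMS[s], lo=18.0)
        weights[i] = _truncated_normal(rng, *WEIGHT_NORMS[s], lo=30.0)
        profiles[i] = [p[name] for name in PARAMETER_NAMES]
        signs.append({k: int(rng.choice([-1, 1])) for k in SIGNED_PARAMS})
    cluster = cluster.astype(str)

    truth = GroundTruth(
        spec=spec,
        subject_ids=ids,
        sex=sex,
        cluster=cluster,
        height=heights,
        age=ages,
        weight=weights,
        profiles=profiles,
        session_profiles={},
        signs=signs,
        resampled=resampled,
    )
    truth.session_profiles[1] = make_session(truth, rng)
    return truth


def _truncated_moments(mu: float, sd: float, lo: float) -> tuple[float, float]:
    """Mean and SD of N(mu, sd) conditioned on >= lo."""
    from scipy.stats import norm

    if sd == 0.0:
        return max(mu, lo), 0.0
    alpha = (lo - mu) / sd
    z = 1.0 - norm.cdf(alpha)
    if z < 1e-12:
        return lo, 0.0
    lam = norm.pdf(alpha) / z
    mean = mu + sd * lam
    var = sd**2 * (1.0 + alpha * lam - lam**2)
    return mean, math.sqrt(max(var, 0.0))


def session_error_sd(spec: SyntheticSpec, k: int = 2) -> np.ndarray:
    """Per-parameter measurement-error SD implied by the target ICC(3,k).

    ICC1 = ICC_k / (k - (k-1) ICC_k) (inverse Spearman-Brown), then
    sigma_e = sigma_between * sqrt((1 - ICC1)/ICC1), with sigma_between the
    marginal (sex- or cluster-mixture) SD of the parameter as actually
    sampled — i.e. using the truncated-normal moments, since the zero floor
    shrinks the realized spread of the small-magnitude angles.  Parameters
    without a reliability target get zero error.
    """
    w_sex = {"M": spec.male_fraction, "F": 1.0 - spec.male_fraction}
    w_cl = {"CG1": spec.cluster_weight, "CG2": 1.0 - spec.cluster_weight}
    sds = np.zeros(len(PARAMETER_NAMES))
    for j, name in enumerate(PARAMETER_NAMES):
        icc_k = spec.target_icc.get(name)
        if icc_k is None:
            continue
        if name in VECTOR_PARAMS:
            sigma_b = pooled_sd({c: spec.cluster_norms[c][name] for c in w_cl}, w_cl)
        else:
            trunc = {
                s: _truncated_moments(*spec.sex_norms[s][name], lo=0.05)
                for s in w_sex
            }
            sigma_b = pooled_sd(trunc, w_sex)
        icc_1 = icc_k / (k - (k - 1) * icc_k)
        sds[j] = sigma_b * math.sqrt((1.0 - icc_1) / icc_1)
    return sds


def make_session(truth: GroundTruth, rng: np.random.Generator, n_subjects: int | None = None) -> np.ndarray:
    """Measured parameters of one session: truth + N(0, sigma_e) per
    parameter, independent across sessions, floored at a small positive
    value for the angle parameters."""
    spec = truth.spec
    n = truth.profiles.shape[0] if n_subjects is None else n_subjects
    sds = session_error_sd(spec)
    measured = truth.profiles[:n] + rng.normal(size=(n, len(PARAMETER_NAMES))) * sds
    for j, name in enumerate(PARAMETER_NAMES):
        if name not in VECTOR_PARAMS:
            measured[:, j] = np.maximum(measured[:, j], 1e-3)
    return measured


def make_retest(truth: GroundTruth, rng: np.random.Generator | None = None) -> np.ndarray:
    """Session-2 measured parameters for the retest subgroup (the first
    ``spec.retest_n`` subjects), stored in ``truth.session_profiles[2]``."""
    if rng is None:
        rng = np.random.default_rng(truth.spec.seed + 1)
    m = make_session(truth, rng, n_subjects=min(truth.spec.retest_n, len(truth.subject_ids)))
    truth.session_profiles[2] = m
    return m


def _subject_captures(spec, sid, params, sign, session, rng):
    """Synthesize the three views for one subject session; the measured
    parameter vector is first clamped into the skeleton-feasible band and
    written back, so the stored session profile and the landmarks agree."""
    p = {name: float(v) for name, v in zip(PARAMETER_NAMES, params)}
    if not _apply_feasibility_guards(p, rng):
        raise PoseInfeasibleError(f"subject {sid}: crossing-leg session draw")
    params[:] = [p[name] for name in PARAMETER_NAMES]
    fig = StickFigure(p, signs=sign, proportions=spec.proportions)
    return [
        figure_to_capture(fig, view, sid, session, spec.jitter_sd, rng)
        for view in ("frontal", "dorsal", "lateral")
    ]


def generate_cohort(spec: SyntheticSpec) -> tuple[Cohort, GroundTruth]:
    """Full landmark-level cohort: session-1 captures for every subject and
    session-2 captures for the retest subgroup, plus the ground truth.

    A subject whose measured parameter set the stick-figure solver cannot
    realize is redrawn (fresh parameters); the count is recorded in
    ``GroundTruth.resampled``.  Fully reproducible from ``spec.seed``.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    truth = sample_parameters(spec, rng)
    make_retest(truth, rng)
    subjects = []
    n_retest = truth.session_profiles[2].shape[0]
    for i, sid in enumerate(truth.subject_ids):
        for attempt in range(30):
            try:
                captures = _subject_captures(
                    spec, sid, truth.session_profiles[1][i], truth.signs[i], 1, rng
                )
                if i < n_retest:
                    captures += _subject_captures(
                        spec, sid, truth.session_profiles[2][i], truth.signs[i], 2, rng
                    )
                break
            except PoseInfeasibleError:
                truth.resampled += 1
                _redraw_subject(spec, truth, i, rng)
        else:
            raise PoseInfeasibleError(f"subject {sid}: no feasible pose in 30 redraws")
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                sex=str(truth.sex[i]),
                age=float(truth.age[i]),
                height=float(truth.height[i]),
                weight=float(truth.weight[i]),
                captures=captures,
            )
        )
    cohort = Cohort(subjects=subjects, provenance=f"synthetic seed={spec.seed}")
    return cohort, truth


def _redraw_subject(spec, truth, i, rng):
    """Replace subject i's parameter draw (and dependent sessions)."""
    s = str(truth.sex[i])
    mu_h, sd_h = spec.height_norms[s]
    for _ in range(200):
        z = rng.normal()
        cl = _draw_cluster(spec, z, rng)
        p = _draw_subject_parameters(spec, s, cl, z, rng)
        if _apply_feasibility_guards(p, rng):
            break
    truth.cluster[i] = cl
    truth.height[i] = mu_h + sd_h * z
    truth.profiles[i] = [p[name] for name in PARAMETER_NAMES]
    truth.signs[i] = {k: int(rng.choice([-1, 1])) for k in SIGNED_PARAMS}
    sds = session_error_sd(spec)
    for sess, mat in truth.session_profiles.items():
        if i < mat.shape[0]:
            row = truth.profiles[i] + rng.normal(size=len(PARAMETER_NAMES)) * sds
            for j, name in enumerate(PARAMETER_NAMES):
                if name not in VECTOR_PARAMS:
                    row[j] = max(row[j], 1e-3)
            mat[i] = row


def spec_from_dict(doc: dict) -> SyntheticSpec:
    """Build a SyntheticSpec from a plain dict (JSON/YAML config)."""
    known = {f for f in SyntheticSpec.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise SpecError(f"unknown synthetic spec field(s): {', '.join(sorted(unknown))}")
    return SyntheticSpec(**doc)
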