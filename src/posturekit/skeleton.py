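"""Forward stick-figure synthesis: landmarks from postural parameters.

Builds a 3-D skeleton in a body frame (X = anatomical left, Y = up, Z =
forward, hip midpoint at the origin, pixel units) that reproduces a given
set of postural parameters EXACTLY (to solver precision), then projects it
to frontal / dorsal / lateral photos in y-down image coordinates.  This is
the inverse of :mod:`posturekit.geometry` at zero landmark jitter, which is
what makes every pipeline stage testable end to end.

Construction outline.  Torso scale, bilateral line placements (ear,
shoulder, hip) and the sagittal angles are closed form.  Joint-angle
parameters that the measurement layer folds over sides (left/right mean)
are realized by giving the two sides explicitly positive per-side targets
``target * (1 +- tanh(u))`` whose mean is the parameter by construction;
the per-side thigh tilt then follows from the hip-adduction target (a
bracketed 1-D root), the shank tilt from the varus/valgus bend, the
per-side thigh fraction from the leg-inclination target (linear), and the
arm tilts from shoulder-adduction/elbow-extension (planar, closed form).
What remains — four limb line tilts (elbow, wrist, knee, ankle) and the
whole-body lean — is a small smooth square system in the asymmetry
parameters and the shoulder-midpoint offset, solved with a damped
Newton-type root finder.  Sign/branch choices (which side bends which way)
are retried over a small ladder of configurations, and the solution is
verified against the folded extraction before acceptance; an
irreconcilable parameter combination raises :class:`PoseInfeasibleError`.

View projections (image x rightward, y DOWN, z away from camera,
hip-midpoint-relative):

* frontal:  (cx + X, cy - Y, -Z)   — the photo mirrors anatomical left/right
* dorsal:   (cx - X, cy - Y, +Z)
* lateral:  (cx + Z, cy - Y, -X)   — camera on the subject's left
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import PoseInfeasibleError
from .model import Landmark, PoseCapture
from .topology import LANDMARK_NAMES

DEG = math.pi / 180.0

#: synthesized photo size (pixels)
IMAGE_SIZE = (800, 1400)
_CX, _CY = 400.0, 700.0  # hip midpoint position in the image


@dataclass(frozen=True)
class Proportions:
    """Skeleton proportions not constrained by the scored parameters.

    They shape the figure (and therefore the landmarks) but cancel out of
    every scored parameter; all ratios are relative to torso length or the
    width they subdivide.
    """

    hip_width_ratio: float = 0.48  # hip width / torso length
    ear_width_ratio: float = 0.38  # ear separation / shoulder width
    neck_height_ratio: float = 0.30  # head-centre height above shoulders / torso
    forearm_upper_ratio: float = 0.82  # forearm length / upper-arm length
    foot_length_ratio: float = 0.20  # ankle->toe length / torso


DEFAULT_PROPORTIONS = Proportions()

#: line-tilt / lean parameters that carry a construction sign (the scored
#: parameter is the unsigned acute angle)
SIGNED_PARAMS = (
    "ear_line",
    "shoulder_line",
    "elbow_line",
    "wrist_line",
    "hip_line",
    "knee_line",
    "ankle_line",
    "body_imbalance",
)


def _angle3d_deg(u: np.ndarray, v: np.ndarray) -> float:
    c = float(np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v)))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))


def _seg_dir(side: float, tilt: float, sag: float) -> np.ndarray:
    """Downward segment direction with coronal tilt ``tilt`` (radians,
    positive = outward for this side) and sagittal tilt ``sag`` (positive =
    forward), normalized so its (x, y) projection has unit length."""
    return np.array(
        [side * math.sin(tilt), -math.cos(tilt), math.cos(tilt) * math.tan(sag)]
    )


def _thigh_tilt(chi: float, h_deg: float, sag: float) -> float:
    """Coronal thigh tilt (radians) realizing a 3-D hip angle of ``h_deg``
    against a trunk line whose downward extension has outward tilt ``chi``,
    with fixed thigh sagittal tilt ``sag``.  Uses the outward branch
    (thigh on the outer side of the extended trunk line).

    A target below the sagittal floor asin(cos(chi) sin(|sag|)) is clamped
    to the floor; the caller detects the mismatch in its extraction check.
    """
    floor = math.degrees(math.asin(math.cos(chi) * math.sin(abs(sag)))) if sag else 0.0
    h_eff = max(h_deg, floor * (1.0 + 1e-9) + 1e-9)
    t2 = math.tan(sag) ** 2

    def g(tau: float) -> float:
        return math.cos(tau - chi) - ch * math.sqrt(1.0 + t2 * math.cos(tau) ** 2)

    for _ in range(40):
        ch = math.cos(h_eff * DEG)
        lo, hi = chi, chi + (h_eff + 45.0) * DEG
        if g(lo) >= 0.0:
            return brentq(g, lo, hi, xtol=1e-15, rtol=8.9e-16)
        h_eff += max(1e-9, (h_eff - floor) * 2.0)  # numeric floor edge: back off
    raise PoseInfeasibleError("hip angle bracket failed")


def implied_thigh_tilt(
    hip_adduction: float,
    hip_extension: float,
    shoulder_hip_difference: float,
    torso_vector: float,
) -> float:
    """Signed outward thigh tilt (degrees) implied by the hip-adduction
    target: the thigh direction is slaved to the trunk line (whose tilt the
    shoulder-hip width difference fixes), minus the sagittal share consumed
    by hip extension."""
    sigma = math.atan2(shoulder_hip_difference / 2.0, torso_vector) / DEG
    sf = math.asin(math.cos(sigma * DEG) * math.sin(abs(hip_extension) * DEG)) / DEG
    cor = math.sqrt(max(hip_adduction**2 - sf**2, 0.0))
    return cor - sigma


def leg_inclination_band(
    hip_adduction: float,
    hip_extension: float,
    knee_varus_valgus: float,
    body_imbalance: float,
    shoulder_hip_difference: float,
    torso_vector: float,
    u_lo: float = 0.25,
    u_max: float = 0.75,
) -> tuple[float, float]:
    """Reachable [min, max] mean leg inclination (degrees) of a standing
    figure given the other coronal parameters.

    A body-imbalance target forces an antisymmetric left/right trunk-line
    perturbation of its own size, so the per-side thigh tilts sit at
    tau +- d; the shank can then bend each side by the same shared fraction
    u of the varus/valgus angle (the knee line pins the left/right thigh
    split).  u is restricted to a central range: the edges correspond to a
    near-degenerate thigh/shank split, which would make the knee parameters
    hypersensitive to landmark jitter.  The synthetic sampler uses this
    band to draw jointly feasible parameter sets.
    """
    tau = implied_thigh_tilt(
        hip_adduction, hip_extension, shoulder_hip_difference, torso_vector
    )
    k = knee_varus_valgus
    # realizing a body lean takes a trunk-line perturbation ~1.5x its size
    # (the ankle midpoint partially follows the shoulder offset)
    d = 1.5 * abs(body_imbalance)
    a, b = abs(tau + d), abs(tau - d)
    cands = {u_lo, u_max}
    if k > 1e-9:
        for kink in (a / k, b / k):
            if u_lo < kink < u_max:
                cands.add(kink)
    floor = min(0.5 * (abs(a - k * u) + abs(b - k * u)) for u in cands)
    ceil = 0.5 * (a + b) + k * u_max
    return floor, ceil


@dataclass
class _Solution:
    """Solved per-side pose variables (radians / fractions / pixels)."""

    tau_t: tuple[float, float]  # thigh coronal tilt (left, right), outward +
    tau_s: tuple[float, float]  # shank coronal tilt
    r: tuple[float, float]  # per-side thigh fraction of leg length
    leg: tuple[float, float]  # per-side leg length (mean = parameter)
    tau_u: tuple[float, float]  # upper-arm coronal tilt
    tau_f: tuple[float, float]  # forearm coronal tilt
    ua: tuple[float, float]  # per-side upper-arm length
    arm: tuple[float, float]  # per-side arm length (mean = parameter)
    x_m: float  # shoulder-midpoint lateral offset


class StickFigure:
    """One solved skeleton for a full set of postural parameters.

    ``params`` maps all 22 parameter names to target values (degrees / pd);
    ``signs`` optionally fixes the construction sign (+-1) of the line-tilt
    parameters (default +1).
    """

    def __init__(
        self,
        params: dict[str, float],
        signs: dict[str, int] | None = None,
        proportions: Proportions = DEFAULT_PROPORTIONS,
    ):
        self.params = dict(params)
        self.signs = {p: 1 for p in SIGNED_PARAMS}
        if signs:
            self.signs.update(signs)
        self.prop = proportions
        self._fc = self._frame_constants()
        self._solve()
        self.points = self._build(self._solution)

    # -- fixed geometry -----------------------------------------------------

    def _frame_constants(self):
        p, pr = self.params, self.prop
        t = p["torso_vector"]
        w_h = pr.hip_width_ratio * t
        w_s = w_h + p["shoulder_hip_difference"]
        if w_s <= 0 or w_h <= 0 or t <= 0:
            raise PoseInfeasibleError("non-positive torso/width scale")
        th_h = self.signs["hip_line"] * p["hip_line"] * DEG
        th_s = self.signs["shoulder_line"] * p["shoulder_line"] * DEG
        phi_t = -p["hip_extension"] * DEG  # thigh tilts backward
        phi_s = phi_t + p["knee_extension"] * DEG  # shank forward relative
        leg = p["total_leg_vector"]
        arm = p["total_arm_vector"]
        ua = arm / (1.0 + pr.forearm_upper_ratio)
        fa = arm - ua
        return t, w_h, w_s, th_h, th_s, phi_t, phi_s, leg, ua, fa

    def _torso_points(self, x_m: float):
        t, w_h, w_s, th_h, th_s = self._fc[:5]
        y_m = math.sqrt(max(t * t - x_m * x_m, 1.0))
        half_h = np.array([math.cos(th_h) * w_h / 2, math.sin(th_h) * w_h / 2, 0.0])
        half_s = np.array([math.cos(th_s) * w_s / 2, math.sin(th_s) * w_s / 2, 0.0])
        mid_s = np.array([x_m, y_m, 0.0])
        return {
            "left_hip": half_h,
            "right_hip": -half_h,
            "left_shoulder": mid_s + half_s,
            "right_shoulder": mid_s - half_s,
        }

    # -- pose for given asymmetry parameters ---------------------------------

    def _pose(self, y: np.ndarray) -> _Solution:
        """Per-side pose variables for solver vector
        y = [r, delta_r, delta_leg (px), delta_ua (px), delta_arm (px),
        x_m (px)]; the branch configuration lives in ``self._branch``.

        Joint-angle targets are realized identically on both sides (their
        left/right fold is then trivially exact); left/right line tilts are
        driven by antisymmetric limb-length and thigh-split asymmetries,
        which all cancel from the side-averaged length parameters.
        """
        p = self.params
        b_kvv, b_arm = self._branch
        r, delta_r, delta_leg, delta_ua, delta_arm, x_m = y
        phi_t = self._fc[5]
        leg, arm = p["total_leg_vector"], p["total_arm_vector"]
        rho = self.prop.forearm_upper_ratio
        torso = self._torso_points(x_m)

        h = p["hip_adduction"]
        sa = p["shoulder_adduction"]
        kvv = p["knee_varus_valgus"]
        ee = p["elbow_extension"]

        tau_t, tau_s, tau_u, tau_f = [], [], [], []
        for i, (s, tag) in enumerate(((1.0, "left"), (-1.0, "right"))):
            hip, sh = torso[f"{tag}_hip"], torso[f"{tag}_shoulder"]
            d = hip - sh  # trunk, pointing down
            chi = math.atan2(s * d[0], -d[1])  # outward tilt of trunk-down line
            tt = _thigh_tilt(chi, h, phi_t)
            tau_t.append(tt)
            tau_s.append(tt + b_kvv[i] * kvv * DEG)
            tu = chi + b_arm[i] * sa * DEG
            tau_u.append(tu)
            tau_f.append(tu - ee * DEG)
        ua = arm / (1.0 + rho)
        return _Solution(
            tau_t=tuple(tau_t),
            tau_s=tuple(tau_s),
            r=(float(r + delta_r), float(r - delta_r)),
            leg=(leg + delta_leg, leg - delta_leg),
            tau_u=tuple(tau_u),
            tau_f=tuple(tau_f),
            ua=(ua + delta_ua, ua - delta_ua),
            arm=(arm + delta_arm, arm - delta_arm),
            x_m=float(x_m),
        )

    def _limb_points(self, sol: _Solution) -> dict[str, np.ndarray]:
        phi_t, phi_s = self._fc[5:7]
        pts = self._torso_points(sol.x_m)
        for i, (s, tag) in enumerate(((1.0, "left"), (-1.0, "right"))):
            hip, sh = pts[f"{tag}_hip"], pts[f"{tag}_shoulder"]
            a = sol.r[i] * sol.leg[i]
            b = sol.leg[i] - a
            knee = hip + a * _seg_dir(s, sol.tau_t[i], phi_t)
            ankle = knee + b * _seg_dir(s, sol.tau_s[i], phi_s)
            ua = sol.ua[i]
            fa = sol.arm[i] - ua
            elbow = sh + ua * _seg_dir(s, sol.tau_u[i], 0.0)
            wrist = elbow + fa * _seg_dir(s, sol.tau_f[i], 0.0)
            pts[f"{tag}_knee"] = knee
            pts[f"{tag}_ankle"] = ankle
            pts[f"{tag}_elbow"] = elbow
            pts[f"{tag}_wrist"] = wrist
        return pts

    @staticmethod
    def _line_tilt(pts: dict[str, np.ndarray], base: str) -> float:
        d = pts[f"left_{base}"] - pts[f"right_{base}"]
        return math.degrees(math.atan2(d[1], d[0]))

    @staticmethod
    def _body_lean(pts: dict[str, np.ndarray]) -> float:
        mid_sh = (pts["left_shoulder"] + pts["right_shoulder"]) / 2
        mid_an = (pts["left_ankle"] + pts["right_ankle"]) / 2
        lean = mid_sh - mid_an
        return math.degrees(math.atan2(lean[0], lean[1]))

    @staticmethod
    def _leg_tilts(pts: dict[str, np.ndarray]) -> list[float]:
        """Signed outward hip->ankle tilt per side (degrees)."""
        out = []
        for s, tag in ((1.0, "left"), (-1.0, "right")):
            d = pts[f"{tag}_ankle"] - pts[f"{tag}_hip"]
            out.append(math.degrees(math.atan2(s * d[0], -d[1])))
        return out

    def _residual(self, y: np.ndarray) -> np.ndarray:
        p, sg = self.params, self.signs
        pts = self._limb_points(self._pose(y))
        nu = self._leg_tilts(pts)
        s1, s2 = self._nu_signs  # fixed per attempt: keeps the fold smooth
        return np.array(
            [
                0.5 * (s1 * nu[0] + s2 * nu[1]) - p["leg_inclination"],
                self._line_tilt(pts, "knee") - sg["knee_line"] * p["knee_line"],
                self._line_tilt(pts, "ankle") - sg["ankle_line"] * p["ankle_line"],
                self._line_tilt(pts, "elbow") - sg["elbow_line"] * p["elbow_line"],
                self._line_tilt(pts, "wrist") - sg["wrist_line"] * p["wrist_line"],
                self._body_lean(pts) - sg["body_imbalance"] * p["body_imbalance"],
            ]
        )

    def _extraction_error(self, sol: _Solution) -> float:
        """Max |extracted - target| over the coronal parameters, folding
        per-side values exactly as the measurement layer does."""
        p = self.params
        pts = self._limb_points(sol)
        hip_add, sh_add = [], []
        nu = [abs(v) for v in self._leg_tilts(pts)]
        for i, (s, tag) in enumerate(((1.0, "left"), (-1.0, "right"))):
            hip, sh = pts[f"{tag}_hip"], pts[f"{tag}_shoulder"]
            knee, ankle = pts[f"{tag}_knee"], pts[f"{tag}_ankle"]
            elbow = pts[f"{tag}_elbow"]
            hip_add.append(180.0 - _angle3d_deg(sh - hip, knee - hip))
            sh_add.append(_angle3d_deg(elbow - sh, hip - sh))
        kvv = [abs(sol.tau_s[i] - sol.tau_t[i]) / DEG for i in range(2)]
        ee = [abs(sol.tau_u[i] - sol.tau_f[i]) / DEG for i in range(2)]
        errs = [
            np.mean(hip_add) - p["hip_adduction"],
            np.mean(kvv) - p["knee_varus_valgus"],
            np.mean(nu) - p["leg_inclination"],
            np.mean(sh_add) - p["shoulder_adduction"],
            np.mean(ee) - p["elbow_extension"],
            abs(self._line_tilt(pts, "knee")) - p["knee_line"],
            abs(self._line_tilt(pts, "ankle")) - p["ankle_line"],
            abs(self._line_tilt(pts, "elbow")) - p["elbow_line"],
            abs(self._line_tilt(pts, "wrist")) - p["wrist_line"],
            abs(self._body_lean(pts)) - p["body_imbalance"],
        ]
        return float(np.max(np.abs(errs)))

    def _branch_configs(self):
        """Candidate branch configurations: (b_kvv, b_arm) per-side shank
        bend and arm outward/inward directions, most plausible first."""
        configs = []
        for bk in ((1.0, 1.0), (-1.0, -1.0), (1.0, -1.0), (-1.0, 1.0)):
            for b_arm in ((1.0, 1.0), (-1.0, -1.0)):
                configs.append((bk, b_arm))
        return configs

    def _start_points(self, config) -> list[tuple[float, float, tuple[float, float]]]:
        """Starting points (r0, x_m0, per-side leg-tilt signs) for one
        branch configuration.

        Analytic candidates solve the piecewise-linear leg-inclination
        equation in the shank-bend fraction u = 1 - r, with the per-side
        thigh tilts split by the body-imbalance-driven shoulder offset
        (x_m ~ +-1.5 * imbalance, in trunk-length units); defaults with
        probed signs are appended.
        """
        p = self.params
        b_kvv, _ = config
        tau = implied_thigh_tilt(
            p["hip_adduction"],
            p["hip_extension"],
            p["shoulder_hip_difference"],
            p["torso_vector"],
        )
        k = p["knee_varus_valgus"]
        li = p["leg_inclination"]
        d = 1.5 * p["body_imbalance"]
        t = p["torso_vector"]
        starts: list[tuple[float, float, tuple[float, float]]] = []
        for d_sign in (self.signs["body_imbalance"], -self.signs["body_imbalance"]):
            # x_m < 0 raises the left thigh tilt (tau + d) and vice versa
            x_m0 = -d_sign * d * DEG * t
            tau_side = (tau + d_sign * d, tau - d_sign * d)
            for s1 in (1.0, -1.0):
                for s2 in (1.0, -1.0):
                    denom = (s1 * b_kvv[0] + s2 * b_kvv[1]) * k
                    if abs(denom) < 1e-9:
                        continue
                    u = (2 * li - s1 * tau_side[0] - s2 * tau_side[1]) / denom
                    if not 0.03 <= u <= 0.97:
                        continue
                    if (
                        s1 * (tau_side[0] + b_kvv[0] * k * u) < -1e-9
                        or s2 * (tau_side[1] + b_kvv[1] * k * u) < -1e-9
                    ):
                        continue
                    starts.append((round(1.0 - u, 3), x_m0, (s1, s2)))
        x_hat = -self.signs["body_imbalance"] * d * DEG * t
        for r0 in (0.525, 0.12, 0.88):
            starts.append((r0, x_hat, None))
        seen: list[tuple] = []
        for cand in starts:
            if not any(
                abs(cand[0] - s[0]) < 0.02 and abs(cand[1] - s[1]) < 1.0
                and cand[2] == s[2]
                for s in seen
            ):
                seen.append(cand)
        return seen[:10]

    def _solve(self, tol: float = 1e-8):
        leg = self.params["total_leg_vector"]
        arm = self.params["total_arm_vector"]
        ua = arm / (1.0 + self.prop.forearm_upper_ratio)
        bounds = (
            np.array([0.02, -0.45, -0.10 * leg, -0.30 * ua, -0.12 * arm, -120.0]),
            np.array([0.98, 0.45, 0.10 * leg, 0.30 * ua, 0.12 * arm, 120.0]),
        )
        best_err = math.inf
        last_exc = None
        fallback = None  # valid solution with an extreme thigh fraction
        for config in self._branch_configs():
            self._branch = config
            for r0, x_m0, nu_signs in self._start_points(config):
                y0 = np.array([r0, 0.0, 0.0, 0.0, 0.0, x_m0])
                try:
                    # per-side leg-tilt signs are fixed per attempt so the
                    # leg-inclination residual has no absolute-value fold;
                    # a wrong guess fails the extraction check below
                    if nu_signs is None:
                        self._nu_signs = (1.0, 1.0)
                        nu0 = self._leg_tilts(self._limb_points(self._pose(y0)))
                        nu_signs = tuple(1.0 if v >= 0 else -1.0 for v in nu0)
                    self._nu_signs = nu_signs
                    fit = least_squares(
                        self._residual,
                        y0,
                        bounds=bounds,
                        method="trf",
                        x_scale="jac",
                        xtol=3e-16,
                        ftol=3e-16,
                        gtol=3e-16,
                        max_nfev=300,
                    )
                    pose = self._pose(fit.x)
                    err = self._extraction_error(pose)
                except (PoseInfeasibleError, ValueError) as exc:
                    last_exc = exc
                    continue
                if err < best_err:
                    best_err = err
                if err < tol:
                    # a near-degenerate thigh/shank split (or crossed-in
                    # arms) makes small angles hypersensitive to landmark
                    # jitter; such poses are rejected as infeasible rather
                    # than accepted, so the generator resamples the subject
                    r_val = float(fit.x[0])
                    if not 0.15 <= r_val <= 0.88:
                        continue
                    if config[1] == (1.0, 1.0):  # arms hang outward: accept
                        self._solution = pose
                        self.max_residual = err
                        return
                    score = abs(r_val - 0.525)
                    if fallback is None or score < fallback[1]:
                        fallback = (pose, score, err)
        if fallback is not None:
            self._solution = fallback[0]
            self.max_residual = fallback[2]
            return
        msg = (
            "no stick-figure pose reproduces this parameter combination "
            f"(best residual {best_err:.2e})"
        )
        if math.isinf(best_err) and last_exc is not None:
            msg = f"{msg}; {last_exc}"
        raise PoseInfeasibleError(msg)

    # -- full landmark set --------------------------------------------------

    def _build(self, sol: _Solution) -> dict[str, np.ndarray]:
        p, pr, sg = self.params, self.prop, self.signs
        t, w_h, w_s = self._fc[:3]
        pts = self._limb_points(sol)

        # head: ears on their tilted line, face landmarks cosmetic
        mid_s = (pts["left_shoulder"] + pts["right_shoulder"]) / 2
        head = mid_s + np.array([0.0, pr.neck_height_ratio * t, 0.0])
        w_e = pr.ear_width_ratio * w_s
        th_e = sg["ear_line"] * p["ear_line"] * DEG
        half_e = np.array([math.cos(th_e) * w_e / 2, math.sin(th_e) * w_e / 2, 0.0])
        pts["left_ear"] = head + half_e
        pts["right_ear"] = head - half_e
        fz = 0.30 * w_e  # face landmarks sit forward of the ear line
        pts["nose"] = head + np.array([0.0, 0.05 * t, fz])
        for s, tag in ((1.0, "left"), (-1.0, "right")):
            eye = head + np.array([s * 0.18 * w_e, 0.07 * t, 0.9 * fz])
            pts[f"{tag}_eye"] = eye
            pts[f"{tag}_eye_inner"] = eye + np.array([-s * 0.06 * w_e, 0.0, 0.0])
            pts[f"{tag}_eye_outer"] = eye + np.array([s * 0.06 * w_e, 0.0, 0.0])
            pts[f"mouth_{tag}"] = head + np.array([s * 0.12 * w_e, 0.01 * t, 0.9 * fz])

        # hands: just beyond the wrist along the forearm
        for i, (s, tag) in enumerate(((1.0, "left"), (-1.0, "right"))):
            d = _seg_dir(s, sol.tau_f[i], 0.0)
            wrist = pts[f"{tag}_wrist"]
            pts[f"{tag}_pinky"] = wrist + 0.07 * t * d + np.array([-s * 4.0, 0, 0])
            pts[f"{tag}_index"] = wrist + 0.08 * t * d + np.array([s * 4.0, 0, 2.0])
            pts[f"{tag}_thumb"] = wrist + 0.05 * t * d + np.array([s * 2.0, 0, 6.0])

        # feet: toe placed to realize the ankle flexion angle exactly
        af = p["ankle_flexion"] * DEG
        f_len = pr.foot_length_ratio * t
        fwd = np.array([0.0, 0.0, 1.0])
        for tag in ("left", "right"):
            ankle, knee = pts[f"{tag}_ankle"], pts[f"{tag}_knee"]
            k = knee - ankle
            k = k / np.linalg.norm(k)
            w = fwd - np.dot(fwd, k) * k
            w = w / np.linalg.norm(w)
            pts[f"{tag}_foot_index"] = ankle + f_len * (math.cos(af) * k + math.sin(af) * w)
            pts[f"{tag}_heel"] = ankle - 0.35 * f_len * w - 0.08 * f_len * k
        return pts

    # -- lateral figure -----------------------------------------------------

    def lateral_points(self) -> dict[str, np.ndarray]:
        """Sagittal-posed skeleton for the lateral photo.

        Neck and trunk-forward inclinations are realized exactly on the
        camera-facing (left) side; everything else is a plausible sagittal
        pose and never scored from this view.
        """
        p, pr = self.params, self.prop
        t, w_h, w_s, _, _, phi_t, phi_s, leg, ua, fa = self._fc
        tf = p["trunk_forward_inclination"] * DEG
        ni = p["neck_inclination"] * DEG
        r = float(np.mean(self._solution.r))
        a = r * leg
        b = leg - a
        n_len = pr.neck_height_ratio * t
        pts: dict[str, np.ndarray] = {}
        trunk = np.array([0.0, math.cos(tf), math.sin(tf)])
        neck = np.array([0.0, math.cos(ni), math.sin(ni)])
        for s, tag in ((1.0, "left"), (-1.0, "right")):
            hip = np.array([s * w_h / 2, 0.0, 0.0])
            sh = hip + t * trunk
            ear = sh + n_len * neck
            pts[f"{tag}_hip"] = hip
            pts[f"{tag}_shoulder"] = sh
            pts[f"{tag}_ear"] = ear
            elbow = sh + ua * np.array([0.0, -math.cos(0.06), math.sin(0.06)])
            wrist = elbow + fa * np.array([0.0, -math.cos(0.10), math.sin(0.10)])
            pts[f"{tag}_elbow"] = elbow
            pts[f"{tag}_wrist"] = wrist
            pts[f"{tag}_pinky"] = wrist + np.array([0.0, -0.06 * t, 0.01 * t])
            pts[f"{tag}_index"] = wrist + np.array([0.0, -0.065 * t, 0.025 * t])
            pts[f"{tag}_thumb"] = wrist + np.array([0.0, -0.045 * t, 0.035 * t])
            knee = hip + a * np.array([0.0, -math.cos(phi_t), math.sin(phi_t)])
            ankle = knee + b * np.array([0.0, -math.cos(phi_s), math.sin(phi_s)])
            pts[f"{tag}_knee"] = knee
            pts[f"{tag}_ankle"] = ankle
            k = (knee - ankle) / np.linalg.norm(knee - ankle)
            fwd = np.array([0.0, 0.0, 1.0])
            w = fwd - np.dot(fwd, k) * k
            w = w / np.linalg.norm(w)
            af = p["ankle_flexion"] * DEG
            f_len = pr.foot_length_ratio * t
            pts[f"{tag}_foot_index"] = ankle + f_len * (
                math.cos(af) * k + math.sin(af) * w
            )
            pts[f"{tag}_heel"] = ankle - 0.35 * f_len * w - 0.08 * f_len * k
        head = (pts["left_ear"] + pts["right_ear"]) / 2
        pts["nose"] = head + np.array([0.0, 0.01 * t, 0.10 * t])
        for s, tag in ((1.0, "left"), (-1.0, "right")):
            eye = head + np.array([s * 0.05 * w_h, 0.03 * t, 0.09 * t])
            pts[f"{tag}_eye"] = eye
            pts[f"{tag}_eye_inner"] = eye + np.array([-s * 2.0, 0.0, 1.0])
            pts[f"{tag}_eye_outer"] = eye + np.array([s * 2.0, 0.0, -1.0])
            pts[f"mouth_{tag}"] = head + np.array([s * 0.04 * w_h, -0.01 * t, 0.09 * t])
        return pts


def _project(point: np.ndarray, view: str) -> tuple[float, float, float]:
    X, Y, Z = (float(v) for v in point)
    if view == "frontal":
        return _CX + X, _CY - Y, -Z
    if view == "dorsal":
        return _CX - X, _CY - Y, Z
    if view == "lateral":
        return _CX + Z, _CY - Y, -X
    raise ValueError(view)


def figure_to_capture(
    figure: StickFigure,
    view: str,
    subject_id: str,
    session: int = 1,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PoseCapture:
    """Project a solved skeleton to one photo view, with optional isotropic
    Gaussian landmark jitter (pixels) on every image coordinate."""
    pts = figure.lateral_points() if view == "lateral" else figure.points
    if jitter_sd > 0.0 and rng is None:
        raise ValueError("jitter requires an rng")
    noise = (
        rng.normal(0.0, jitter_sd, size=(len(LANDMARK_NAMES), 3))
        if jitter_sd > 0.0
        else np.zeros((len(LANDMARK_NAMES), 3))
    )
    landmarks = {}
    for i, name in enumerate(LANDMARK_NAMES):
        x, y, z = _project(pts[name], view)
        landmarks[name] = Landmark(
            name=name,
            x=x + noise[i, 0],
            y=y + noise[i, 1],
            z=z + noise[i, 2],
            visibility=1.0,
        )
    return PoseCapture(
        subject_id=subject_id,
        session=session,
        view=view,
        landmarks=landmarks,
        image_size=IMAGE_SIZE,
    )


def synthesize_capture(
    params: dict[str, float],
    view: str,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
    signs: dict[str, int] | None = None,
    subject_id: str = "synthetic",
    session: int = 1,
    proportions: Proportions = DEFAULT_PROPORTIONS,
) -> PoseCapture:
    """One-shot convenience: solve a stick figure for ``params`` and project
    it to ``view``.  Prefer :class:`StickFigure` + :func:`figure_to_capture`
    when generating several views of the same subject."""
    fig = StickFigure(params, signs=signs, proportions=proportions)
    return figure_to_capture(fig, view, subject_id, session, jitter_sd, rng)
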