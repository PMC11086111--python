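"""End-to-end study pipeline: cohort -> profiles -> statistics -> posture
types, with file outputs and a reproducibility manifest.

``run_full_analysis`` executes the three analysis layers in order —
postural-parameter extraction, inferential statistics (sex comparison,
height correlations, test-retest reliability), and the unsupervised layer
(PCA, five clustering algorithms with elbow/silhouette model selection,
cluster-stratified comparison) — writing CSV/JSON artifacts plus a JSON
manifest (config hash, package version, seed, per-stage timing and status).
Every output is regenerable bit-identically from the manifest's config and
seed (timestamps live only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
from pydantic import BaseModel, Field, field_validator

from . import __version__
from .errors import PostureKitError
from .geometry import PARAMETER_NAMES, compute_profile, profiles_to_frame
from .io import read_captures
from .model import DEFAULT_MIN_VISIBILITY
from .multivariate import (
    CLUSTER_METHODS,
    cluster,
    cluster_stratified_comparison,
    elbow_curve,
    run_pca,
    select_components,
)
from .stats import (
    comparison_frame,
    comparison_table,
    height_correlations,
    reliability_frame,
    reliability_table,
)
from .synthetic import SyntheticSpec, generate_cohort, spec_from_dict

log = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one full analysis run."""

    input_path: str | None = None  # landmark CSV/JSON; None -> synthetic
    synthetic: dict = Field(default_factory=dict)  # SyntheticSpec overrides
    seed: int = 0
    min_visibility: float = DEFAULT_MIN_VISIBILITY
    welch: bool = False
    holm: bool = False
    pca_scaling: str = "none"  # "none" | "zscore"
    retention: float = 0.90
    cluster_methods: list[str] = Field(default_factory=lambda: list(CLUSTER_METHODS))
    cluster_k: int | None = None  # None -> elbow-method choice
    out_dir: str = "results/run"

    @field_validator("retention")
    @classmethod
    def _check_retention(cls, v):
        if not 0.0 < v <= 1.0:
            raise ValueError("retention must be in (0, 1]")
        return v

    @field_validator("pca_scaling")
    @classmethod
    def _check_scaling(cls, v):
        if v not in ("none", "zscore"):
            raise ValueError("pca_scaling must be 'none' or 'zscore'")
        return v

    @field_validator("cluster_methods")
    @classmethod
    def _check_methods(cls, v):
        bad = set(v) - set(CLUSTER_METHODS)
        if bad:
            raise ValueError(f"unknown clustering method(s): {sorted(bad)}")
        return v

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(manifest, name):
    manifest["stages"].append({"name": name, "status": "running", "seconds": None})
    return time.time(), manifest["stages"][-1]


def _finish(entry, t0, status="ok", error=None):
    entry["status"] = status
    entry["seconds"] = round(time.time() - t0, 3)
    if error:
        entry["error"] = error


def acquire_cohort(config: RunConfig):
    """Load a landmark cohort from file or generate a synthetic one.

    Returns (cohort, ground_truth_or_None).
    """
    if config.input_path:
        return read_captures(config.input_path), None
    doc = dict(config.synthetic)
    doc.setdefault("seed", config.seed)
    spec = spec_from_dict(doc)
    cohort, truth = generate_cohort(spec)
    return cohort, truth


def extract_profiles(cohort, min_visibility=DEFAULT_MIN_VISIBILITY):
    """All computable subject x session profiles of a cohort."""
    profiles = []
    for subject in cohort:
        for session in subject.sessions:
            profiles.append(compute_profile(subject, session, min_visibility))
    return profiles


def run_full_analysis(config: RunConfig) -> dict:
    """Run all stages and write artifacts under ``config.out_dir``.

    Returns the manifest dict (also written to ``manifest.json``).  A stage
    failure is recorded in the manifest with a structured error and stops
    dependent stages; the manifest's ``status`` is then "partial" or
    "failed".
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "config": config.model_dump(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": [],
        "status": "ok",
    }

    # ---- stage 1: cohort ------------------------------------------------
    t0, entry = _stage(manifest, "cohort")
    try:
        cohort, truth = acquire_cohort(config)
        entry["n_subjects"] = len(cohort)
        entry["provenance"] = cohort.provenance
        _finish(entry, t0)
    except (PostureKitError, OSError, ValueError) as exc:
        _finish(entry, t0, "failed", str(exc))
        manifest["status"] = "failed"
        _write_manifest(manifest, out)
        return manifest

    # ---- stage 2: profiles ----------------------------------------------
    t0, entry = _stage(manifest, "profiles")
    try:
        profiles = extract_profiles(cohort, config.min_visibility)
        frame = profiles_to_frame(profiles)
        meta = {
            s.subject_id: (s.sex, s.height, s.age, s.weight) for s in cohort
        }
        frame.insert(2, "sex", [meta[i][0] for i in frame["subject_id"]])
        frame.insert(3, "height", [meta[i][1] for i in frame["subject_id"]])
        frame.to_csv(out / "profiles.csv", index=False)
        entry["n_profiles"] = len(profiles)
        missing_lateral = sum(1 for p in profiles if p.missing)
        if missing_lateral:
            entry["profiles_missing_lateral"] = missing_lateral
        _finish(entry, t0)
    except PostureKitError as exc:
        _finish(entry, t0, "failed", str(exc))
        manifest["status"] = "failed"
        _write_manifest(manifest, out)
        return manifest

    s1 = frame[frame.session == 1].reset_index(drop=True)

    # ---- stage 3: inferential statistics --------------------------------
    t0, entry = _stage(manifest, "statistics")
    try:
        have_sex = s1["sex"].isin(["M", "F"]).all()
        if have_sex:
            comps = comparison_table(s1, s1["sex"], ("M", "F"), welch=config.welch)
            comparison_frame(comps).to_csv(out / "sex_comparison.csv", index=False)
            entry["n_sex_rows"] = len(comps)
        heights = s1["height"].to_numpy(dtype=float)
        if np.isfinite(heights).all():
            corrs = height_correlations(s1, heights)
            import pandas as pd

            pd.DataFrame(
                [
                    {
                        "parameter": c.pair[1],
                        "pearson_r": round(c.pearson_r, 3),
                        "p_value": c.p_value,
                        "relevant": c.relevant,
                    }
                    for c in corrs
                ]
            ).to_csv(out / "height_correlations.csv", index=False)
        retest_ids = set(frame[frame.session == 2]["subject_id"])
        if len(retest_ids) >= 3:
            p1 = [p for p in profiles if p.session == 1 and p.subject_id in retest_ids]
            p2 = [p for p in profiles if p.session == 2]
            rows = reliability_table(p1, p2)
            reliability_frame(rows).to_csv(out / "reliability.csv", index=False)
            entry["n_retest"] = len(retest_ids)
        _finish(entry, t0)
    except PostureKitError as exc:
        _finish(entry, t0, "failed", str(exc))
        manifest["status"] = "partial"

    # ---- stage 4: PCA + clustering --------------------------------------
    t0, entry = _stage(manifest, "multivariate")
    try:
        cols = [p for p in PARAMETER_NAMES if s1[p].notna().all()]
        x = s1[cols].to_numpy(dtype=float)
        pca = run_pca(x, scaling=config.pca_scaling)
        m = select_components(pca, config.retention)
        entry["n_components"] = m
        entry["variance_ratios"] = [round(float(v), 3) for v in pca.explained_variance_ratio[:4]]
        scores = pca.scores[:, :m]
        import pandas as pd

        pd.DataFrame(
            scores, columns=[f"PC{j + 1}" for j in range(m)]
        ).assign(subject_id=s1["subject_id"]).to_csv(out / "pca_scores.csv", index=False)

        ec = elbow_curve(scores, range(1, min(9, len(s1))), seed=config.seed)
        k = config.cluster_k or ec.knee
        results = {}
        for method in config.cluster_methods:
            results[method] = cluster(scores, method, n_clusters=k, seed=config.seed)
        label_frame = pd.DataFrame(
            {
                "subject_id": s1["subject_id"],
                **{m_: results[m_].labels for m_ in results},
            }
        )
        label_frame.to_csv(out / "cluster_labels.csv", index=False)
        summary = {
            "elbow": {"ks": ec.ks, "wcss": ec.wcss, "knee": ec.knee, "low_confidence": ec.low_confidence},
            "k_used": k,
            "silhouettes": {
                m_: (None if r.silhouette is None else round(r.silhouette, 3))
                for m_, r in results.items()
            },
            "n_clusters": {m_: r.n_clusters for m_, r in results.items()},
        }
        scored = [
            (r.silhouette, m_) for m_, r in results.items() if r.silhouette is not None
        ]
        if scored:
            best = max(scored)[1]
            summary["best_method"] = best
            entry["best_method"] = best
            entry["best_silhouette"] = round(float(max(scored)[0]), 3)
            if results[best].n_clusters == 2:
                comps, named = cluster_stratified_comparison(s1, results[best].labels)
                comparison_frame(comps).to_csv(out / "cluster_comparison.csv", index=False)
                label_frame[f"{best}_named"] = named
                label_frame.to_csv(out / "cluster_labels.csv", index=False)
        with open(out / "cluster_summary.json", "w") as fh:
            json.dump(summary, fh, indent=1)
        _finish(entry, t0)
    except PostureKitError as exc:
        _finish(entry, t0, "failed", str(exc))
        manifest["status"] = "partial"

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
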