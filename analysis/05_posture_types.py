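#!/usr/bin/env python
"""Unsupervised posture typing: PCA, clustering, stratified comparison.

Covariance PCA over the 22 parameters, component count by 90% variance
retention, elbow-method k, the five clustering algorithms with silhouette
scores, and the full per-parameter comparison between the two groups of
the best-scoring method (CG1 = smaller shoulder-hip difference).
"""

import json
from pathlib import Path

import pandas as pd

from posturekit.geometry import PARAMETER_NAMES
from posturekit.multivariate import (
    CLUSTER_METHODS,
    cluster,
    cluster_stratified_comparison,
    elbow_curve,
    run_pca,
    select_components,
)
from posturekit.stats import comparison_frame

BASE = Path(__file__).resolve().parents[1] / "results"
SEED = 20230315


def main() -> None:
    frame = pd.read_csv(BASE / "profiles.csv")
    s1 = frame[frame.session == 1].reset_index(drop=True)
    x = s1[list(PARAMETER_NAMES)].to_numpy()

    pca = run_pca(x, scaling="none")
    m = select_components(pca, 0.90)
    ratios = [round(float(v), 3) for v in pca.explained_variance_ratio[:4]]
    print(f"variance ratios {ratios}; retaining {m} components for >= 90%")
    scores = pca.scores[:, :m]

    ec = elbow_curve(scores, range(1, 9), seed=SEED)
    print(f"elbow-method knee at k = {ec.knee}"
          + (" (low confidence)" if ec.low_confidence else ""))

    sils = {}
    results = {}
    for method in CLUSTER_METHODS:
        res = cluster(scores, method, n_clusters=ec.knee, seed=SEED)
        results[method] = res
        sils[method] = None if res.silhouette is None else round(res.silhouette, 3)
    print("silhouette scores:", sils)
    best = max((s, m_) for m_, s in sils.items() if s is not None)[1]
    print(f"best method: {best}")

    with open(BASE / "cluster_summary.json", "w") as fh:
        json.dump(
            {"variance_ratios": ratios, "n_components": m, "knee": ec.knee,
             "silhouettes": sils, "best_method": best},
            fh, indent=1,
        )

    res = results[best]
    if res.n_clusters == 2:
        comps, named = cluster_stratified_comparison(s1, res.labels)
        table = comparison_frame(comps)
        table.to_csv(BASE / "cluster_comparison.csv", index=False)
        pd.DataFrame({"subject_id": s1.subject_id, "cluster": named}).to_csv(
            BASE / "cluster_labels.csv", index=False
        )
        vec = table[table.parameter.str.contains("vector|difference")]
        print("\nvector parameters by posture type:")
        print(vec.to_string(index=False))
    else:
        print(f"best method found {res.n_clusters} clusters; no 2-group table")


if __name__ == "__main__":
    main()
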