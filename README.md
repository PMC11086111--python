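# posturekit

Markerless posture analysis from pose landmarks: postural parameters,
normative statistics, and unsupervised posture typing.

Modern pose estimators turn a single photo into 33 labeled body landmarks
(x, y in pixels, a hip-relative depth z, a visibility score). `posturekit`
is the analysis layer that sits on top of such records, built for the
study design used in normative posture research: each participant is
photographed in the anatomical zero position from the frontal, dorsal,
and lateral views, a subgroup is re-photographed a week later, and the
cohort is analyzed in three layers —

1. **Geometry** — 22 postural parameters per subject: 7 body joint angles
   (fused across views and sides with the circular mean), 7 horizontal
   line inclinations (asymmetry indices), 4 vertical inclinations, and 4
   body-vector lengths in pixel distance (pd);
2. **Inferential statistics** — Shapiro–Wilk-gated Student's t /
   Mann–Whitney comparisons with Cohen's d
   (d = (m₂ − m₁)/√((s₁² + s₂²)/2)), Pearson height correlations
   (relevant iff p < 0.05 and r > 0.45), and test-retest reliability:
   ICC(3,k) = (MS_subjects − MS_error)/MS_subjects, SEM = SD·√(1 − ICC),
   MDC95 = 1.96·√2·SEM;
3. **Posture typing** — covariance PCA with 90% variance retention,
   five clustering algorithms (k-means, mean-shift, Ward, complete,
   average) with elbow/silhouette model selection, and a per-parameter
   comparison between the two discovered posture types.

Because photo cohorts of this kind are rarely shareable, the package
includes a first-class synthetic-cohort generator: a stick-figure
synthesizer that is the exact inverse of the geometry layer (at zero
landmark jitter the pipeline recovers every generated parameter to
< 10⁻⁶ degrees), with sex-specific normative parameter distributions, a
sex-independent two-type body-vector mixture, height–vector coupling, and
ICC-calibrated retest noise. See `docs/methods.md` for the full model.

## Worked example

The `analysis/` scripts replicate the full study on a synthetic cohort
(n = 200, 84 men / 116 women, 90 retests, 0.5 px landmark jitter):

```sh
python analysis/01_generate_cohort.py   # landmark cohort -> results/cohort/
python analysis/02_extract_profiles.py  # 22 parameters per subject/session
python analysis/03_sex_differences.py
python analysis/04_reliability.py
python analysis/05_posture_types.py
```

`03` prints the large sex effects — e.g. (this cohort)

```
         parameter  M_mean  M_sd  F_mean  F_sd           test      p_value sig  cohens_d
shoulder_adduction    15.9   2.0    14.0   1.6      student_t 2.284358e-11 ***     -1.00
     hip_adduction     9.9   2.3     6.4   1.6 mann_whitney_u 2.216729e-20 ***     -1.78
```

men show larger shoulder/hip adduction angles (d signed as F − M), while
the horizontal inclinations show no sex difference. `04` reports ICC(3,2)
between 0.60 and 0.96 with SEM/MDC95 per parameter (knee line weakest,
hip adduction 0.96/SEM 0.52°/MDC95 1.44°). `05` finds two posture types
regardless of sex and prints their body-vector contrast:

```
              parameter  CG1_mean  CG1_sd  CG2_mean  CG2_sd  ...  cohens_d
shoulder_hip_difference      58.7     6.3      87.1    10.3  ...      3.32
       total_arm_vector     239.7    13.5     307.8    23.5  ...      3.55
```

CG1 collects shorter body segments with similar shoulder and hip widths;
CG2 longer segments with notably wider shoulders — a distinction far
stronger than any sex difference in the same parameters.

The same pipeline is scriptable via the CLI (`posturekit generate`,
`profile`, `stats`, `cluster`, `analyze --synthetic 200 --seed 7 --out
run/`) and, for real data, accepts landmark CSV/JSON files in the dialect
documented in `posturekit.io` (one row per landmark:
`subject_id,session,view,landmark,x,y,z,visibility`).

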