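#!/usr/bin/env python
"""Sex differences and height correlations.

Per parameter: Shapiro-Wilk gate, pooled Student's t or Mann-Whitney U,
Cohen's d (average-variance denominator), plus Pearson correlations of
every parameter with body height (relevant iff p < 0.05 and r > 0.45).
"""

from pathlib import Path

import pandas as pd

from posturekit.stats import comparison_frame, comparison_table, height_correlations

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    frame = pd.read_csv(BASE / "profiles.csv")
    s1 = frame[frame.session == 1].reset_index(drop=True)

    comps = comparison_table(s1, s1["sex"], ("M", "F"))
    table = comparison_frame(comps)
    table.to_csv(BASE / "sex_comparison.csv", index=False)
    big = table[table.cohens_d.abs() >= 0.8]
    print("sex comparison (|d| >= 0.8):")
    print(big.to_string(index=False))

    corrs = height_correlations(s1, s1["height"].to_numpy())
    ctab = pd.DataFrame(
        [
            {"parameter": c.pair[1], "pearson_r": round(c.pearson_r, 3),
             "p_value": c.p_value, "relevant": c.relevant}
            for c in corrs
        ]
    )
    ctab.to_csv(BASE / "height_correlations.csv", index=False)
    print("\nheight-relevant parameters (p < 0.05 and r > 0.45):")
    print(ctab[ctab.relevant].to_string(index=False))


if __name__ == "__main__":
    main()
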