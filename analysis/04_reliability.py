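#!/usr/bin/env python
"""Test-retest reliability of the posture parameters.

ICC(3,k) (two-way mixed, consistency, average of the k=2 sessions), SEM,
and MDC95 per parameter over the retest subgroup; vector lengths carry no
reliability row.
"""

from pathlib import Path

import pandas as pd

from posturekit.geometry import PARAMETER_NAMES, PostureProfile
from posturekit.stats import reliability_frame, reliability_table

BASE = Path(__file__).resolve().parents[1] / "results"


def _profiles(frame):
    return [
        PostureProfile(
            subject_id=row.subject_id,
            session=int(row.session),
            values={p: getattr(row, p) for p in PARAMETER_NAMES},
        )
        for row in frame.itertuples()
    ]


def main() -> None:
    frame = pd.read_csv(BASE / "profiles.csv")
    retest_ids = set(frame[frame.session == 2].subject_id)
    s1 = frame[(frame.session == 1) & frame.subject_id.isin(retest_ids)]
    s2 = frame[frame.session == 2]
    rows = reliability_table(_profiles(s1), _profiles(s2))
    table = reliability_frame(rows)
    table.to_csv(BASE / "reliability.csv", index=False)
    print(f"reliability over {len(retest_ids)} retest subjects:")
    print(table.to_string(index=False))
    print(
        f"\nICC(3,2) range: {table.icc_3k.min():.2f} - {table.icc_3k.max():.2f}"
    )


if __name__ == "__main__":
    main()
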