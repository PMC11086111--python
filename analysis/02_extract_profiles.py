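#!/usr/bin/env python
"""Extract the postural parameters from the landmark cohort.

Reads the landmark file written by 01, computes all 22 parameters per
subject and session (circular-mean fusion of the frontal/dorsal joint
angles, lateral neck/trunk inclinations, pixel-distance body vectors),
and writes the tidy profile table the statistical scripts consume.
"""

from pathlib import Path

from posturekit.geometry import profiles_to_frame
from posturekit.io import read_captures
from posturekit.pipeline import extract_profiles

BASE = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = read_captures(BASE / "cohort" / "cohort.csv")
    profiles = extract_profiles(cohort)
    frame = profiles_to_frame(profiles)
    meta = {s.subject_id: (s.sex, s.height) for s in cohort}
    frame.insert(2, "sex", [meta[i][0] for i in frame["subject_id"]])
    frame.insert(3, "height", [meta[i][1] for i in frame["subject_id"]])
    out = BASE / "profiles.csv"
    frame.to_csv(out, index=False)
    n1 = (frame.session == 1).sum()
    n2 = (frame.session == 2).sum()
    print(f"extracted {n1} session-1 and {n2} retest profiles -> {out}")


if __name__ == "__main__":
    main()
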