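"""Readers and writers for landmark cohorts (CSV and JSON dialects).

CSV dialect: one row per landmark with header
``subject_id,session,view,landmark,x,y,z,visibility`` plus optional subject
metadata columns (``sex,age,height,weight``) repeated on every row of the
subject.  Unknown extra columns are ignored with a logged warning.

JSON dialect: an object with a ``captures`` array (one object per capture:
``{subject_id, session, view, image_size, landmarks: {label: [x, y, z,
visibility]}}``), an optional ``subjects`` metadata array, and a
``provenance`` string.  A bare array of capture objects is also accepted.

Both writers emit a deterministic ordering (cohort order, session ascending,
frontal/dorsal/lateral, topology label order) and full float precision, so a
write/read round trip is exact.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path

from .errors import FormatError, LandmarkParseError
from .model import Cohort, Landmark, PoseCapture, SubjectRecord
from .topology import LANDMARK_NAMES, VIEWS

log = logging.getLogger(__name__)

_CSV_CORE = ["subject_id", "session", "view", "landmark", "x", "y", "z", "visibility"]
_CSV_META = ["sex", "age", "height", "weight"]


def _ordered_captures(cohort: Cohort):
    view_rank = {v: i for i, v in enumerate(VIEWS)}
    for subject in cohort:
        caps = sorted(subject.captures, key=lambda c: (c.session, view_rank[c.view]))
        for cap in caps:
            yield subject, cap


def write_captures(cohort: Cohort, path: str | Path, format: str = "csv") -> None:
    """Write a cohort to ``path`` in the CSV or JSON dialect."""
    path = Path(path)
    if format == "csv":
        _write_csv(cohort, path)
    elif format == "json":
        _write_json(cohort, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_csv(cohort: Cohort, path: Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_CORE + _CSV_META)
        for subject, cap in _ordered_captures(cohort):
            meta = [
                subject.sex or "",
                "" if subject.age is None else repr(float(subject.age)),
                "" if subject.height is None else repr(float(subject.height)),
                "" if subject.weight is None else repr(float(subject.weight)),
            ]
            for name in LANDMARK_NAMES:
                lm = cap[name]
                writer.writerow(
                    [
                        subject.subject_id,
                        cap.session,
                        cap.view,
                        name,
                        repr(float(lm.x)),
                        repr(float(lm.y)),
                        repr(float(lm.z)),
                        repr(float(lm.visibility)),
                    ]
                    + meta
                )


def _write_json(cohort: Cohort, path: Path) -> None:
    subjects = []
    captures = []
    for subject in cohort:
        subjects.append(
            {
                "subject_id": subject.subject_id,
                "sex": subject.sex,
                "age": subject.age,
                "height": subject.height,
                "weight": subject.weight,
            }
        )
    for subject, cap in _ordered_captures(cohort):
        captures.append(
            {
                "subject_id": subject.subject_id,
                "session": cap.session,
                "view": cap.view,
                "image_size": list(cap.image_size) if cap.image_size else None,
                "landmarks": {
                    name: [
                        float(cap[name].x),
                        float(cap[name].y),
                        float(cap[name].z),
                        float(cap[name].visibility),
                    ]
                    for name in LANDMARK_NAMES
                },
            }
        )
    doc = {"provenance": cohort.provenance, "subjects": subjects, "captures": captures}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def read_captures(path: str | Path, format: str | None = None) -> Cohort:
    """Read a cohort from a CSV or JSON landmark file.

    ``format`` defaults to the file suffix.  Raises :class:`FormatError` for
    schema violations (naming subject, view, and label) and
    :class:`LandmarkParseError` (with the line number) for bad numerics.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format == "csv":
        return _read_csv(path)
    if format == "json":
        return _read_json(path)
    raise ValueError(f"unknown format {format!r}")


def _build_cohort(subject_rows, provenance: str) -> Cohort:
    """subject_rows: ordered dict subject_id -> (meta dict, ordered capture dict)."""
    subjects = []
    for sid, (meta, caps) in subject_rows.items():
        captures = []
        for (session, view), (landmarks, image_size) in caps.items():
            missing = [n for n in LANDMARK_NAMES if n not in landmarks]
            if missing:
                raise FormatError(
                    f"subject {sid} session {session} view {view}: missing "
                    "landmark label(s): " + ", ".join(missing)
                )
            captures.append(
                PoseCapture(
                    subject_id=sid,
                    session=session,
                    view=view,
                    landmarks=landmarks,
                    image_size=image_size,
                )
            )
        subjects.append(SubjectRecord(subject_id=sid, captures=captures, **meta))
    return Cohort(subjects=subjects, provenance=provenance)


def _parse_float(value: str, field: str, lineno: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise LandmarkParseError(
            f"line {lineno}: non-numeric {field} value {value!r}"
        ) from None


def _read_csv(path: Path) -> Cohort:
    subject_rows: dict[str, tuple[dict, dict]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, header required")
        missing_cols = [c for c in _CSV_CORE if c not in reader.fieldnames]
        if missing_cols:
            raise FormatError(f"{path}: missing column(s): {', '.join(missing_cols)}")
        extra = [c for c in reader.fieldnames if c not in _CSV_CORE + _CSV_META]
        if extra:
            log.warning("%s: ignoring unknown column(s): %s", path, ", ".join(extra))
        for row in reader:
            lineno = reader.line_num
            sid = row["subject_id"]
            view = row["view"]
            if view not in VIEWS:
                raise FormatError(f"line {lineno}: unknown view {view!r}")
            name = row["landmark"]
            if name not in LANDMARK_NAMES:
                raise FormatError(
                    f"subject {sid} view {view}: unknown landmark label {name!r} "
                    f"(line {lineno})"
                )
            try:
                session = int(row["session"])
            except ValueError:
                raise LandmarkParseError(
                    f"line {lineno}: non-integer session {row['session']!r}"
                ) from None
            lm = Landmark(
                name=name,
                x=_parse_float(row["x"], "x", lineno),
                y=_parse_float(row["y"], "y", lineno),
                z=_parse_float(row["z"], "z", lineno),
                visibility=_parse_float(row["visibility"], "visibility", lineno),
            )
            meta, caps = subject_rows.setdefault(sid, ({}, {}))
            sex = row.get("sex") or None
            if sex is not None:
                meta["sex"] = sex
            for fld in ("age", "height", "weight"):
                val = row.get(fld)
                if val:
                    meta[fld] = _parse_float(val, fld, lineno)
            landmarks, _ = caps.setdefault((session, view), ({}, None))
            if name in landmarks:
                raise FormatError(
                    f"subject {sid} session {session} view {view}: duplicate "
                    f"landmark label {name!r} (line {lineno})"
                )
            landmarks[name] = lm
    return _build_cohort(subject_rows, provenance="real")


def _read_json(path: Path) -> Cohort:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if isinstance(doc, list):
        doc = {"provenance": "real", "subjects": [], "captures": doc}
    known_keys = {"provenance", "subjects", "captures"}
    extra = set(doc) - known_keys
    if extra:
        log.warning("%s: ignoring unknown key(s): %s", path, ", ".join(sorted(extra)))
    subject_rows: dict[str, tuple[dict, dict]] = {}
    for entry in doc.get("subjects", []):
        meta = {
            k: entry.get(k)
            for k in ("sex", "age", "height", "weight")
            if entry.get(k) is not None
        }
        subject_rows.setdefault(entry["subject_id"], (meta, {}))
    for i, cap in enumerate(doc.get("captures", [])):
        sid = cap["subject_id"]
        view = cap["view"]
        if view not in VIEWS:
            raise FormatError(f"capture #{i}: unknown view {view!r}")
        session = int(cap["session"])
        image_size = tuple(cap["image_size"]) if cap.get("image_size") else None
        landmarks = {}
        for name, vals in cap["landmarks"].items():
            if name not in LANDMARK_NAMES:
                raise FormatError(
                    f"subject {sid} view {view}: unknown landmark label {name!r}"
                )
            try:
                x, y, z, vis = (float(v) for v in vals)
            except (TypeError, ValueError):
                raise LandmarkParseError(
                    f"subject {sid} view {view} landmark {name}: bad coordinate "
                    f"array {vals!r}"
                ) from None
            landmarks[name] = Landmark(name=name, x=x, y=y, z=z, visibility=vis)
        meta, caps = subject_rows.setdefault(sid, ({}, {}))
        if (session, view) in caps:
            raise FormatError(
                f"subject {sid}: duplicate capture for session {session} view {view}"
            )
        caps[(session, view)] = (landmarks, image_size)
    return _build_cohort(subject_rows, provenance=doc.get("provenance", "real"))
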