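"""Landmark file I/O and the 18-landmark molar schema.

Three text dialects are supported for landmark coordinates:

``csv_long``
    One row per landmark with columns
    ``specimen_id, landmark_name, x, y, z`` (coordinates in mm).
``tps``
    The 3D variant of the TPS grammar: each record opens with
    ``LM3=<k>``, followed by k whitespace-separated coordinate rows and
    an ``ID=<specimen>`` line.
``morphologika``
    Morphologika-style text: ``[individuals]``, ``[landmarks]``,
    ``[dimensions]`` and ``[names]`` header sections, then
    ``[rawpoints]`` with blank-line-separated per-specimen blocks.

Coordinates are stored double precision and written with shortest
round-trip ``repr`` formatting so write-then-read is bit exact.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError, DegenerateConfigurationError

GROUPS = ("control", "mild", "moderate", "severe")
SEXES = ("F", "M")
DIALECTS = ("tps", "morphologika", "csv_long")


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips to the same double."""
    return repr(float(x))


@dataclass(frozen=True)
class LandmarkSchema:
    """Named landmark set with free-text definitions and wireframe edges."""

    landmark_names: tuple[str, ...]
    definitions: dict[str, str] = field(default_factory=dict)
    wireframe_edges: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        names = tuple(self.landmark_names)
        object.__setattr__(self, "landmark_names", names)
        if len(set(names)) != len(names):
            raise SchemaError("landmark names must be unique")
        for a, b in self.wireframe_edges:
            if a == b:
                raise SchemaError(f"wireframe edge ({a!r}, {b!r}) joins a landmark to itself")
            if a not in names or b not in names:
                raise SchemaError(f"wireframe edge ({a!r}, {b!r}) references unknown landmarks")

    def __len__(self) -> int:
        return len(self.landmark_names)

    def index(self, name: str) -> int:
        return self.landmark_names.index(name)


def default_molar_schema() -> LandmarkSchema:
    """The 18-landmark schema for the lower left first permanent molar.

    Landmarks cover the proximal contact points, the five cusp tips, the
    four occlusal pits, the buccal gingival margin, and the occlusal
    limits of the three developmental grooves.
    """
    entries = [
        ("mesial_contact", "Mesial (MD) contact point"),
        ("distal_contact", "Distal (MD) contact point"),
        ("buccal_axis_endpoint", "Buccal endpoint of the bucco-lingual axis"),
        ("mesiolingual_cusp_tip", "Mesial lingual cusp tip"),
        ("distolingual_cusp_tip", "Distal lingual cusp tip"),
        ("mesiobuccal_cusp_tip", "Mesial buccal cusp tip"),
        ("distobuccal_cusp_tip", "Distal buccal cusp tip"),
        ("hypoconulid_tip", "Distobuccal (fifth) cusp tip"),
        ("outer_mesial_pit", "Outer mesial pit"),
        ("inner_mesial_pit", "Inner mesial pit"),
        ("central_pit", "Central pit"),
        ("distal_pit", "Distal pit"),
        ("mesial_papilla_end", "End of mesial papilla seen from the buccal side"),
        ("gingival_margin_midpoint",
         "Halfway between the papilla ends along the buccal gingival margin"),
        ("distal_papilla_end", "End of distal papilla seen from the buccal side"),
        ("buccal_groove_occlusal_limit", "Occlusal limit of the buccal groove"),
        ("distobuccal_groove_occlusal_limit", "Occlusal limit of the distobuccal groove"),
        ("lingual_groove_occlusal_limit", "Occlusal limit of the lingual groove"),
    ]
    names = tuple(n for n, _ in entries)
    edges = (
        # occlusal outline: cusp tips around the crown
        ("mesiobuccal_cusp_tip", "distobuccal_cusp_tip"),
        ("distobuccal_cusp_tip", "hypoconulid_tip"),
        ("hypoconulid_tip", "distolingual_cusp_tip"),
        ("distolingual_cusp_tip", "mesiolingual_cusp_tip"),
        ("mesiolingual_cusp_tip", "mesiobuccal_cusp_tip"),
        # pit chain along the central fossa
        ("outer_mesial_pit", "inner_mesial_pit"),
        ("inner_mesial_pit", "central_pit"),
        ("central_pit", "distal_pit"),
        # contacts to the pit chain
        ("mesial_contact", "outer_mesial_pit"),
        ("distal_contact", "distal_pit"),
        # buccal face: gingival margin and grooves
        ("mesial_papilla_end", "gingival_margin_midpoint"),
        ("gingival_margin_midpoint", "distal_papilla_end"),
        ("buccal_groove_occlusal_limit", "gingival_margin_midpoint"),
        ("buccal_groove_occlusal_limit", "central_pit"),
        ("distobuccal_groove_occlusal_limit", "distal_pit"),
        ("lingual_groove_occlusal_limit", "central_pit"),
        ("buccal_axis_endpoint", "buccal_groove_occlusal_limit"),
    )
    return LandmarkSchema(names, dict(entries), edges)


@dataclass
class LandmarkConfiguration:
    """One specimen's k x 3 landmark coordinate matrix (mm)."""

    specimen_id: str
    coords: np.ndarray
    schema: LandmarkSchema

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise SchemaError(
                f"{self.specimen_id}: coords must be k x 3, got {self.coords.shape}"
            )
        if self.coords.shape[0] != len(self.schema):
            raise SchemaError(
                f"{self.specimen_id}: {self.coords.shape[0]} landmarks, "
                f"schema defines {len(self.schema)}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise SchemaError(f"{self.specimen_id}: non-finite coordinates")
        centered = self.coords - self.coords.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
            raise DegenerateConfigurationError(
                f"{self.specimen_id}: fewer than 3 non-collinear landmarks"
            )


@dataclass
class SpecimenRecord:
    """Classifier entry: group and sex, plus optional replicate labels."""

    specimen_id: str
    group: str
    sex: str
    scan_session: int | None = None
    digitization: int | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValidationError(
                f"{self.specimen_id}: unknown group {self.group!r} (allowed: {GROUPS})"
            )
        if self.sex not in SEXES:
            raise ValidationError(
                f"{self.specimen_id}: unknown sex {self.sex!r} (allowed: {SEXES})"
            )


@dataclass
class StudyDataset:
    """Landmark configurations plus per-specimen classifier records."""

    configurations: list[LandmarkConfiguration]
    records: list[SpecimenRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.configurations:
            schema = self.configurations[0].schema
            for c in self.configurations:
                if c.schema.landmark_names != schema.landmark_names:
                    raise SchemaError(
                        f"{c.specimen_id}: schema disagrees with the dataset schema"
                    )
        if self.records:
            by_id = {r.specimen_id: r for r in self.records}
            if len(by_id) != len(self.records):
                raise ValidationError("duplicate specimen_id in classifier records")
            missing = [c.specimen_id for c in self.configurations if c.specimen_id not in by_id]
            if missing:
                raise ValidationError(f"no classifier record for specimens: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.configurations)

    @property
    def schema(self) -> LandmarkSchema:
        if not self.configurations:
            raise SchemaError("empty dataset has no schema")
        return self.configurations[0].schema

    @property
    def specimen_ids(self) -> list[str]:
        return [c.specimen_id for c in self.configurations]

    def coords_array(self) -> np.ndarray:
        """All configurations stacked as an n x k x 3 array."""
        return np.stack([c.coords for c in self.configurations])

    def record_for(self, specimen_id: str) -> SpecimenRecord:
        for r in self.records:
            if r.specimen_id == specimen_id:
                return r
        raise KeyError(specimen_id)

    def labels(self, fieldname: str) -> np.ndarray:
        """Per-configuration classifier column, in configuration order."""
        by_id = {r.specimen_id: r for r in self.records}
        return np.array([getattr(by_id[c.specimen_id], fieldname) for c in self.configurations])

    def attach_records(self, records: Sequence[SpecimenRecord]) -> "StudyDataset":
        return StudyDataset(self.configurations, list(records))


# ---------------------------------------------------------------------------
# readers / writers


def _schema_for(names: Sequence[str]) -> LandmarkSchema:
    default = default_molar_schema()
    if tuple(names) == default.landmark_names:
        return default
    return LandmarkSchema(tuple(names))


def _generic_names(k: int) -> list[str]:
    return [f"lm{i + 1}" for i in range(k)]


def _read_csv_long(path: Path) -> StudyDataset:
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header[:5]] != [
            "specimen_id", "landmark_name", "x", "y", "z",
        ]:
            raise ParseError(f"{path}: expected header specimen_id,landmark_name,x,y,z")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) < 5:
                raise ParseError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            try:
                rows.append((row[0], row[1], float(row[2]), float(row[3]), float(row[4])))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate ({exc})") from exc
    # group rows by specimen in order of first appearance
    order: list[str] = []
    per_spec: dict[str, list[tuple[str, float, float, float]]] = {}
    for sid, name, x, y, z in rows:
        if sid not in per_spec:
            per_spec[sid] = []
            order.append(sid)
        per_spec[sid].append((name, x, y, z))
    if not order:
        return StudyDataset([])
    first_names = [r[0] for r in per_spec[order[0]]]
    schema = _schema_for(first_names)
    configs = []
    for sid in order:
        block = per_spec[sid]
        names = [r[0] for r in block]
        if names != first_names:
            raise SchemaError(
                f"{path}: specimen {sid!r} landmark names/order disagree with first specimen"
            )
        coords = np.array([[x, y, z] for _, x, y, z in block])
        configs.append(LandmarkConfiguration(sid, coords, schema))
    return StudyDataset(configs)


def _write_csv_long(dataset: StudyDataset, path: Path) -> None:
    lines = ["specimen_id,landmark_name,x,y,z"]
    for c in dataset.configurations:
        for name, (x, y, z) in zip(c.schema.landmark_names, c.coords):
            lines.append(f"{c.specimen_id},{name},{_fmt(x)},{_fmt(y)},{_fmt(z)}")
    path.write_text("\n".join(lines) + "\n")


def _read_tps(path: Path) -> StudyDataset:
    configs_raw: list[tuple[str, np.ndarray]] = []
    k_declared = None
    coords_buf: list[list[float]] = []
    spec_id = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                if k_declared is not None:
                    raise ParseError(
                        f"{path}:{lineno}: new LM3 record before ID= of previous record"
                    )
                try:
                    k_declared = int(line.split("=", 1)[1])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad LM3 count") from exc
                coords_buf = []
            elif upper.startswith("ID="):
                if k_declared is None:
                    raise ParseError(f"{path}:{lineno}: ID= before any LM3= record")
                if len(coords_buf) != k_declared:
                    raise ParseError(
                        f"{path}:{lineno}: record declares LM3={k_declared} but has "
                        f"{len(coords_buf)} coordinate rows"
                    )
                spec_id = line.split("=", 1)[1]
                configs_raw.append((spec_id, np.array(coords_buf)))
                k_declared = None
            else:
                if k_declared is None:
                    raise ParseError(f"{path}:{lineno}: coordinates outside an LM3 record")
                parts = line.split()
                if len(parts) != 3:
                    raise ParseError(f"{path}:{lineno}: expected 3 coordinates, got {len(parts)}")
                try:
                    coords_buf.append([float(p) for p in parts])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad coordinate ({exc})") from exc
                if len(coords_buf) > k_declared:
                    raise ParseError(
                        f"{path}:{lineno}: more coordinate rows than declared LM3={k_declared}"
                    )
    if k_declared is not None:
        raise ParseError(f"{path}: final record has no ID= line")
    if not configs_raw:
        return StudyDataset([])
    k = configs_raw[0][1].shape[0]
    for sid, arr in configs_raw:
        if arr.shape[0] != k:
            raise SchemaError(f"{path}: specimen {sid!r} has {arr.shape[0]} landmarks, expected {k}")
    schema = _schema_for(_generic_names(k)) if k != 18 else default_molar_schema()
    return StudyDataset([LandmarkConfiguration(sid, arr, schema) for sid, arr in configs_raw])


def _write_tps(dataset: StudyDataset, path: Path) -> None:
    lines = []
    for c in dataset.configurations:
        lines.append(f"LM3={len(c.schema)}")
        for x, y, z in c.coords:
            lines.append(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}")
        lines.append(f"ID={c.specimen_id}")
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _read_morphologika(path: Path) -> StudyDataset:
    text = path.read_text()
    lines = text.splitlines()
    sections: dict[str, list[str]] = {}
    current = None
    for line in lines:
        stripped = line.strip()
        if stripped.lower().startswith("[") and stripped.endswith("]"):
            current = stripped.lower().strip("[]")
            sections[current] = []
        elif current is not None:
            sections[current].append(line)
    for required in ("individuals", "landmarks", "rawpoints"):
        if required not in sections:
            raise ParseError(f"{path}: missing [{required}] section")
    try:
        n = int(next(s for s in sections["individuals"] if s.strip()))
        k = int(next(s for s in sections["landmarks"] if s.strip()))
    except (StopIteration, ValueError) as exc:
        raise ParseError(f"{path}: bad [individuals]/[landmarks] counts") from exc
    if "dimensions" in sections:
        dim = int(next(s for s in sections["dimensions"] if s.strip()))
        if dim != 3:
            raise ParseError(f"{path}: only 3-dimensional data supported, got {dim}")
    names = [s.strip() for s in sections.get("names", []) if s.strip()]
    # rawpoints: blocks separated by blank lines; optional "' label" line per block
    blocks: list[tuple[str | None, list[list[float]]]] = []
    label: str | None = None
    buf: list[list[float]] = []
    for line in sections["rawpoints"] + [""]:
        stripped = line.strip()
        if not stripped:
            if buf:
                blocks.append((label, buf))
            label, buf = None, []
        elif stripped.startswith("'"):
            label = stripped.lstrip("'").strip()
        else:
            parts = stripped.split()
            if len(parts) != 3:
                raise ParseError(f"{path}: rawpoints row {stripped!r} is not 3 coordinates")
            try:
                buf.append([float(p) for p in parts])
            except ValueError as exc:
                raise ParseError(f"{path}: bad coordinate in {stripped!r}") from exc
    if len(blocks) != n:
        raise ParseError(f"{path}: [individuals] declares {n} but found {len(blocks)} blocks")
    schema = _schema_for(_generic_names(k)) if k != 18 else default_molar_schema()
    configs = []
    for i, (lbl, rows) in enumerate(blocks):
        if len(rows) != k:
            raise ParseError(
                f"{path}: block {i + 1} has {len(rows)} rows, [landmarks] declares {k}"
            )
        sid = lbl or (names[i] if i < len(names) else f"specimen{i + 1}")
        configs.append(LandmarkConfiguration(sid, np.array(rows), schema))
    return StudyDataset(configs)


def _write_morphologika(dataset: StudyDataset, path: Path) -> None:
    n = len(dataset)
    k = len(dataset.schema) if n else 0
    lines = ["[individuals]", str(n), "[landmarks]", str(k), "[dimensions]", "3", "[names]"]
    lines += dataset.specimen_ids
    lines.append("[rawpoints]")
    for c in dataset.configurations:
        lines.append(f"' {c.specimen_id}")
        for x, y, z in c.coords:
            lines.append(f"{_fmt(x)} {_fmt(y)} {_fmt(z)}")
        lines.append("")
    path.write_text("\n".join(lines) + "\n")


_READERS = {"csv_long": _read_csv_long, "tps": _read_tps, "morphologika": _read_morphologika}
_WRITERS = {"csv_long": _write_csv_long, "tps": _write_tps, "morphologika": _write_morphologika}


def read_landmarks(path: str | Path, dialect: str) -> StudyDataset:
    """Read a landmark coordinate file into a :class:`StudyDataset`.

    Classifier records are not part of landmark files; attach them with
    :meth:`StudyDataset.attach_records` after :func:`read_classifiers`.
    """
    if dialect not in _READERS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    return _READERS[dialect](Path(path))


def write_landmarks(dataset: StudyDataset, path: str | Path, dialect: str) -> None:
    """Write a dataset's configurations in the given text dialect."""
    if dialect not in _WRITERS:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {DIALECTS}")
    _WRITERS[dialect](dataset, Path(path))


def read_classifiers(path: str | Path) -> list[SpecimenRecord]:
    """Read a classifier CSV (id, group, sex[, scan_session, digitization])."""
    df = pd.read_csv(path, dtype=str)
    df.columns = [c.strip().lower() for c in df.columns]
    id_col = "specimen_id" if "specimen_id" in df.columns else "id"
    for col in (id_col, "group", "sex"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    bad = df[~df["group"].isin(GROUPS) | ~df["sex"].isin(SEXES)]
    if len(bad):
        raise ValidationError(
            f"{path}: invalid group/sex tokens in rows {list(bad.index + 2)}: "
            f"{bad[[id_col, 'group', 'sex']].to_dict('records')}"
        )
    records = []
    for _, row in df.iterrows():
        kw = {}
        for opt in ("scan_session", "digitization"):
            if opt in df.columns and pd.notna(row[opt]) and str(row[opt]).strip():
                kw[opt] = int(float(row[opt]))
        records.append(SpecimenRecord(str(row[id_col]), row["group"], row["sex"], **kw))
    has_reps = [r.scan_session is not None and r.digitization is not None for r in records]
    if any(has_reps) and not all(has_reps):
        raise ValidationError(f"{path}: replicate labels must be present for all specimens or none")
    return records


def write_classifiers(records: Iterable[SpecimenRecord], path: str | Path) -> None:
    records = list(records)
    has_reps = records and records[0].scan_session is not None
    cols = ["specimen_id", "group", "sex"] + (["scan_session", "digitization"] if has_reps else [])
    lines = [",".join(cols)]
    for r in records:
        vals = [r.specimen_id, r.group, r.sex]
        if has_reps:
            vals += [str(r.scan_session), str(r.digitization)]
        lines.append(",".join(vals))
    Path(path).write_text("\n".join(lines) + "\n")
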