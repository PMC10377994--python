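"""Reading, writing and validating landmark session files.

Three dialects are supported, all normalised to the LPS frame on read:

* Slicer markups FCSV -- comma separated, ``# CoordinateSystem`` header
  (commonly RAS), columns ``id,x,y,z,...,label,...``;
* Slicer markups JSON -- control points with ``label`` and ``position``;
* plain CSV with a required ``name,l,p,s`` header, always LPS.

RAS and LPS differ by a sign flip on the first two axes, so the conversion
is its own inverse.  Name matching against the registry is exact after
whitespace trimming and an explicit, user-supplied alias table; off-registry
names are kept in a side list and reported as warnings, never guessed at.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import DuplicateLandmarkError, ParseError
from .landmarks import LandmarkRegistry, LandmarkSet, build_registry

_FORMATS = ("fcsv", "markups_json", "csv")


def ras_to_lps(xyz: np.ndarray) -> np.ndarray:
    """Convert RAS coordinates to LPS (negate the first two axes); involutive."""
    out = np.asarray(xyz, dtype=float).copy()
    out[..., 0] *= -1.0
    out[..., 1] *= -1.0
    return out


lps_to_ras = ras_to_lps  # same sign flip


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix == ".fcsv":
        return "fcsv"
    if suffix == ".json":
        return "markups_json"
    if suffix == ".csv":
        return "csv"
    raise ParseError(f"cannot infer landmark format from suffix {suffix!r} ({path})")


def read_landmarks(path, format: str | None = None, *,
                   registry: LandmarkRegistry | None = None,
                   aliases: dict | None = None,
                   assume_coordinate_system: str | None = None,
                   subject_id: str = "", examiner_id: str = "",
                   session_id: str = "") -> LandmarkSet:
    """Read one labeling session and normalise it to LPS.

    Parameters
    ----------
    format
        One of ``fcsv``, ``markups_json``, ``csv``; inferred from the file
        suffix when omitted.
    aliases
        Explicit name map applied before registry matching, e.g.
        ``{"PNS": "alv(PNS)"}``.
    assume_coordinate_system
        Override for FCSV files lacking a ``# CoordinateSystem`` header;
        without it such files are rejected.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
    registry = registry or build_registry()
    aliases = aliases or {}

    if fmt == "fcsv":
        raw = _read_fcsv(path, assume_coordinate_system)
    elif fmt == "markups_json":
        raw = _read_markups_json(path)
    else:
        raw = _read_plain_csv(path)

    points, extras = {}, {}
    for name, xyz in raw:
        name = aliases.get(name.strip(), name.strip())
        target = points if name in registry else extras
        if name in points or name in extras:
            raise DuplicateLandmarkError(f"{path}: duplicate landmark {name!r}")
        target[name] = xyz
    if extras:
        warnings.warn(f"{path}: {len(extras)} off-registry landmark name(s): "
                      f"{sorted(extras)}", stacklevel=2)
    return LandmarkSet(points, subject_id=subject_id, examiner_id=examiner_id,
                       session_id=session_id, extras=extras)


def _read_fcsv(path: Path, assume_cs: str | None):
    coord_system = None
    rows = []
    with open(path, newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.lower().startswith("coordinatesystem"):
                    coord_system = body.split("=", 1)[1].strip()
                continue
            parts = line.split(",")
            if len(parts) < 12:
                raise ParseError(f"{path}:{lineno}: expected >=12 comma-separated "
                                 f"fields, got {len(parts)}")
            try:
                xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate ({exc})") from None
            rows.append((parts[11], xyz))
    cs = coord_system or assume_cs
    if cs is None:
        raise ParseError(f"{path}: no '# CoordinateSystem' header; pass "
                         "assume_coordinate_system='RAS' or 'LPS' to override")
    cs = cs.upper()
    if cs not in ("RAS", "LPS", "0", "1"):
        raise ParseError(f"{path}: unsupported coordinate system {cs!r}")
    if cs in ("RAS", "0"):  # Slicer encodes RAS as 0, LPS as 1 in some versions
        rows = [(name, ras_to_lps(xyz)) for name, xyz in rows]
    return rows


def _read_markups_json(path: Path):
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: invalid JSON at line {exc.lineno}") from None
    markups = doc.get("markups")
    if not markups:
        raise ParseError(f"{path}: no 'markups' entry")
    rows = []
    for markup in markups:
        cs = markup.get("coordinateSystem", "LPS").upper()
        if cs not in ("RAS", "LPS"):
            raise ParseError(f"{path}: unsupported coordinate system {cs!r}")
        for cp in markup.get("controlPoints", []):
            label = cp.get("label")
            pos = cp.get("position")
            if label is None or pos is None or len(pos) != 3:
                raise ParseError(f"{path}: control point missing label/position")
            xyz = np.asarray(pos, dtype=float)
            if cs == "RAS":
                xyz = ras_to_lps(xyz)
            rows.append((label, xyz))
    return rows


def _read_plain_csv(path: Path):
    rows = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file") from None
        if [h.strip().lower() for h in header[:4]] != ["name", "l", "p", "s"]:
            raise ParseError(f"{path}:1: expected header 'name,l,p,s', got {header!r}")
        for lineno, parts in enumerate(reader, start=2):
            if not parts or not "".join(parts).strip():
                continue
            if len(parts) < 4:
                raise ParseError(f"{path}:{lineno}: expected 4 fields, got {len(parts)}")
            try:
                xyz = np.array([float(parts[1]), float(parts[2]), float(parts[3])])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad coordinate ({exc})") from None
            rows.append((parts[0], xyz))
    return rows


def write_landmarks(lset: LandmarkSet, path, format: str = "csv") -> None:
    """Write a session; plain LPS CSV is the canonical output format."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["name", "l", "p", "s"])
            for name, xyz in list(lset.points.items()) + list(lset.extras.items()):
                writer.writerow([name] + [repr(float(v)) for v in xyz])
    elif format == "fcsv":
        with open(path, "w", newline="") as fh:
            fh.write("# Markups fiducial file version = 4.11\n")
            fh.write("# CoordinateSystem = LPS\n")
            fh.write("# columns = id,x,y,z,ow,ox,oy,oz,vis,sel,lock,label,desc,associatedNodeID\n")
            for i, (name, xyz) in enumerate(list(lset.points.items()) + list(lset.extras.items()), 1):
                coords = ",".join(repr(float(v)) for v in xyz)
                fh.write(f"F{i},{coords},0,0,0,1,1,1,0,{name},,\n")
    elif format == "markups_json":
        doc = {"markups": [{
            "type": "Fiducial",
            "coordinateSystem": "LPS",
            "controlPoints": [
                {"label": name, "position": [xyz[0], xyz[1], xyz[2]]}
                for name, xyz in list(lset.points.items()) + list(lset.extras.items())
            ],
        }]}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)
    else:
        raise ValueError(f"unknown format {format!r}")


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_set`; a report, never an exception."""

    missing: list = field(default_factory=list)
    off_registry: list = field(default_factory=list)
    outliers: list = field(default_factory=list)  # (name, distance_mm)

    @property
    def ok(self) -> bool:
        return not (self.missing or self.off_registry or self.outliers)


def validate_set(lset: LandmarkSet, required=None, *,
                 outlier_threshold_mm: float = 300.0) -> ValidationReport:
    """Check a session for missing names, off-registry names and gross outliers.

    A point farther than ``outlier_threshold_mm`` from the session centroid
    is flagged -- at head scale that can only be a unit or labeling blunder.
    """
    report = ValidationReport()
    if required is not None:
        report.missing = lset.missing(required)
    report.off_registry = sorted(lset.extras)
    if lset.points:
        coords = lset.coordinates()
        center = np.median(coords, axis=0)  # robust to the outliers it hunts
        dists = np.linalg.norm(coords - center, axis=1)
        for name, d in zip(lset.points, dists):
            if d > outlier_threshold_mm:
                report.outliers.append((name, float(d)))
    return report
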