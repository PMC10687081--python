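"""Readers and writers for 2D landmark shape files and specimen metadata.

Two on-disk dialects are supported, one file per specimen per
structure:

* the classic tps keyword format (``LM=``, ``CURVES=``, ``POINTS=``,
  ``IMAGE=``, ``ID=``, ``SCALE=``), possibly with several records per
  file;
* a tag-block text format as emitted by R digitisers: a named landmark
  block, named curve-point rows and an optional ruler block for
  scaling.

Coordinates are stored in physical units — the file's scale factor is
applied at read time.  Files without a scale are retained but flagged
``unscaled`` (superimposition removes size anyway; only centroid-size
reports need physical units).  File names carry a trailing ``_C`` /
``_P`` token naming the digitised structure.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CEPHALON",
    "PYGIDIUM",
    "LandmarkConfiguration",
    "SpecimenRecord",
    "ReferenceEntry",
    "TpsParseError",
    "ShapeParseError",
    "read_tps",
    "write_tps",
    "read_stereomorph",
    "write_stereomorph",
    "read_shape_file",
    "load_shape_dir",
    "resolve_structure_suffix",
    "read_metadata",
    "read_references",
]

CEPHALON = "cephalon"
PYGIDIUM = "pygidium"

_SUFFIX_TO_STRUCTURE = {"C": CEPHALON, "P": PYGIDIUM}


class TpsParseError(ValueError):
    """Malformed tps record; the message names the offending line."""


class ShapeParseError(ValueError):
    """Malformed tag-block shape file."""


@dataclass
class LandmarkConfiguration:
    """Digitised landmarks and semilandmark curves of one specimen/structure.

    ``landmarks`` is a ``(k, 2)`` float array in physical units; missing
    landmarks are NaN rows.  ``curves`` is an ordered list of ``(m, 2)``
    polylines.  ``scale`` is physical units per digitiser unit, already
    applied to the stored coordinates; ``None`` means the file carried
    no scale (see :attr:`unscaled`).
    """

    specimen_id: str
    structure: str | None
    landmarks: np.ndarray
    curves: list[np.ndarray] = field(default_factory=list)
    scale: float | None = None
    source_path: str | None = None
    dialect: str | None = None

    def __post_init__(self) -> None:
        self.landmarks = np.asarray(self.landmarks, dtype=float).reshape(-1, 2)
        self.curves = [np.asarray(c, dtype=float).reshape(-1, 2) for c in self.curves]
        bad = ~np.isfinite(self.landmarks) & ~np.isnan(self.landmarks)
        if bad.any():
            raise ValueError("landmarks must be finite or NaN (missing)")
        partial = np.isnan(self.landmarks).sum(axis=1) == 1
        if partial.any():
            raise ValueError("a landmark must be fully present or fully missing")
        for c in self.curves:
            if len(c) < 2:
                raise ValueError("every curve needs at least 2 points")
            if not np.isfinite(c).all():
                raise ValueError("curve points must be finite")
        if self.scale is not None and not self.scale > 0:
            raise ValueError("scale must be positive")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmarks)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean mask over landmarks, True where missing."""
        return np.isnan(self.landmarks).any(axis=1)

    @property
    def unscaled(self) -> bool:
        return self.scale is None


# -- specimen metadata -------------------------------------------------------


@dataclass
class Taxonomy:
    orig_genus: str | None = None
    genus: str | None = None
    gen_status: str | None = None
    gen_author: str | None = None
    subgen: str | None = None
    orig_sp: str | None = None
    sp: str | None = None
    sp_author: str | None = None
    subsp: str | None = None


@dataclass
class Morphology:
    cephalon: bool | None = None
    cranidium: bool | None = None
    pygidium: bool | None = None
    eyes: bool | None = None
    ontogeny: str | None = None


@dataclass
class Geography:
    locality: str | None = None
    country: str | None = None
    lat: float | None = None
    long: float | None = None
    state: str | None = None
    county: str | None = None


@dataclass
class Stratigraphy:
    formation: str | None = None
    min_age: str | None = None
    max_age: str | None = None
    ref_age: str | None = None
    basin: str | None = None


@dataclass
class SpecimenRecord:
    """Contextual information for one specimen, with validation findings.

    Mandatory-field violations are collected in :attr:`violations`
    rather than raised, so a whole metadata table can be screened in
    one pass.
    """

    id: str
    ref_pic: str | None = None
    enter_metadata: str | None = None
    enter_landmark: str | None = None
    comments: str | None = None
    taxonomy: Taxonomy = field(default_factory=Taxonomy)
    morphology: Morphology = field(default_factory=Morphology)
    geography: Geography = field(default_factory=Geography)
    stratigraphy: Stratigraphy = field(default_factory=Stratigraphy)
    violations: list[str] = field(default_factory=list)


_MANDATORY = (
    "ref_pic",
    "enter_metadata",
    "enter_landmark",
    "taxonomy.orig_genus",
    "taxonomy.genus",
    "taxonomy.sp",
    "morphology.cephalon",
    "morphology.cranidium",
    "morphology.pygidium",
    "morphology.eyes",
    "morphology.ontogeny",
    "geography.locality",
    "geography.lat",
    "geography.long",
    "stratigraphy.min_age",
    "stratigraphy.max_age",
)


@dataclass(frozen=True)
class ReferenceEntry:
    ref_id: str
    citation: str


# -- tps dialect -------------------------------------------------------------

_TPS_KEY = re.compile(r"^\s*([A-Za-z]+)\s*=\s*(.*?)\s*$")


def _parse_point(line: str, lineno: int) -> tuple[float, float]:
    parts = line.split()
    if len(parts) != 2:
        raise TpsParseError(f"line {lineno}: expected 'x y' coordinate pair, got {line!r}")
    try:
        return float(parts[0]), float(parts[1])
    except ValueError:
        raise TpsParseError(f"line {lineno}: non-numeric coordinate in {line!r}") from None


def read_tps(
    path,
    *,
    missing_as_negative: bool = True,
    structure: str | None = None,
) -> list[LandmarkConfiguration]:
    """Parse a tps file into one configuration per ``LM=`` record.

    Coordinates are multiplied by ``SCALE=`` when present.  When
    ``missing_as_negative``, a landmark whose two raw coordinates are
    both negative is flagged missing (the common digitiser encoding;
    toggleable because releases differ).
    """
    path = Path(path)
    if structure is None:
        try:
            _, structure = resolve_structure_suffix(path.name)
        except ValueError:
            structure = None
    lines = path.read_text().splitlines()
    configs: list[LandmarkConfiguration] = []
    i, n = 0, len(lines)

    while i < n:
        if not lines[i].strip():
            i += 1
            continue
        m = _TPS_KEY.match(lines[i])
        if not m or m.group(1).upper() != "LM":
            raise TpsParseError(f"line {i + 1}: expected 'LM=<n>', got {lines[i]!r}")
        try:
            n_lm = int(m.group(2))
        except ValueError:
            raise TpsParseError(f"line {i + 1}: bad landmark count {m.group(2)!r}") from None
        i += 1
        raw_lm = np.empty((n_lm, 2))
        for j in range(n_lm):
            if i >= n or _TPS_KEY.match(lines[i]):
                raise TpsParseError(
                    f"line {i + 1}: LM={n_lm} declared but only {j} coordinate lines found"
                )
            raw_lm[j] = _parse_point(lines[i], i + 1)
            i += 1

        raw_curves: list[np.ndarray] = []
        image = spec_id = None
        scale: float | None = None
        while i < n and lines[i].strip():
            m = _TPS_KEY.match(lines[i])
            if not m:
                raise TpsParseError(f"line {i + 1}: expected a keyword line, got {lines[i]!r}")
            key, value = m.group(1).upper(), m.group(2)
            if key == "LM":
                break  # next record
            i += 1
            if key == "CURVES":
                n_curves = int(value)
                for _ in range(n_curves):
                    if i >= n:
                        raise TpsParseError(f"line {i}: missing POINTS= for declared curve")
                    pm = _TPS_KEY.match(lines[i])
                    if not pm or pm.group(1).upper() != "POINTS":
                        raise TpsParseError(
                            f"line {i + 1}: expected 'POINTS=<k>', got {lines[i]!r}"
                        )
                    n_pts = int(pm.group(2))
                    i += 1
                    pts = np.empty((n_pts, 2))
                    for j in range(n_pts):
                        if i >= n or _TPS_KEY.match(lines[i]):
                            raise TpsParseError(
                                f"line {i + 1}: POINTS={n_pts} declared but only "
                                f"{j} coordinate lines found"
                            )
                        pts[j] = _parse_point(lines[i], i + 1)
                        i += 1
                    raw_curves.append(pts)
            elif key == "IMAGE":
                image = value
            elif key == "ID":
                spec_id = value
            elif key == "SCALE":
                try:
                    scale = float(value)
                except ValueError:
                    raise TpsParseError(f"line {i}: bad SCALE value {value!r}") from None
            elif key == "POINTS":
                raise TpsParseError(f"line {i}: POINTS= outside a CURVES= block")
            else:
                warnings.warn(f"{path.name}: ignoring unknown tps keyword {key}=")

        if missing_as_negative:
            miss = (raw_lm < 0).all(axis=1)
            raw_lm[miss] = np.nan
        if scale is not None:
            raw_lm = raw_lm * scale
            raw_curves = [c * scale for c in raw_curves]
        if spec_id is None:
            spec_id = image if image is not None else path.stem
        configs.append(
            LandmarkConfiguration(
                specimen_id=spec_id,
                structure=structure,
                landmarks=raw_lm,
                curves=raw_curves,
                scale=scale,
                source_path=str(path),
                dialect="tps",
            )
        )
    if not configs:
        raise TpsParseError(f"{path}: no LM= record found")
    return configs


def _fmt(x: float) -> str:
    # shortest round-trip representation; keeps write->read exact
    return repr(float(x))


def write_tps(configs, path, *, missing_as_negative: bool = True) -> None:
    """Write configurations as consecutive tps records (see :func:`read_tps`).

    Missing landmarks are emitted as ``-1 -1`` under the negative-pair
    convention; coordinates are divided by the scale so that re-reading
    restores physical units.
    """
    configs = list(configs)
    if not configs:
        raise ValueError("nothing to write")
    structures = {c.structure for c in configs}
    if len(structures) > 1:
        raise ValueError(f"mixed structures in one file: {sorted(map(str, structures))}")
    out = []
    for c in configs:
        s = c.scale if c.scale is not None else 1.0
        out.append(f"LM={c.n_landmarks}")
        for pt, miss in zip(c.landmarks, c.missing_mask):
            if miss:
                if not missing_as_negative:
                    raise ValueError(
                        f"{c.specimen_id}: cannot encode missing landmark "
                        "without the negative-pair convention"
                    )
                out.append("-1 -1")
            else:
                out.append(f"{_fmt(pt[0] / s)} {_fmt(pt[1] / s)}")
        if c.curves:
            out.append(f"CURVES={len(c.curves)}")
            for curve in c.curves:
                out.append(f"POINTS={len(curve)}")
                out.extend(f"{_fmt(p[0] / s)} {_fmt(p[1] / s)}" for p in curve)
        out.append(f"ID={c.specimen_id}")
        if c.scale is not None:
            out.append(f"SCALE={_fmt(c.scale)}")
    Path(path).write_text("\n".join(out) + "\n")


# -- tag-block (StereoMorph-style) dialect -----------------------------------

_TAG_OPEN = re.compile(r"^<([A-Za-z0-9_.]+)>(.*)$")


def _parse_blocks(text: str, source: str) -> dict[str, list[str]]:
    blocks: dict[str, list[str]] = {}
    current: str | None = None
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if current is not None:
            if stripped == f"</{current}>":
                current = None
            else:
                blocks[current].append(stripped)
            continue
        m = _TAG_OPEN.match(stripped)
        if not m:
            raise ShapeParseError(f"{source}, line {lineno}: expected a <block> tag, got {line!r}")
        name, rest = m.group(1), m.group(2)
        close = f"</{name}>"
        if rest.endswith(close):  # one-line block
            blocks[name] = [rest[: -len(close)].strip()]
        else:
            blocks[name] = []
            current = name
    if current is not None:
        raise ShapeParseError(f"{source}: unterminated block <{current}>")
    return blocks


_KNOWN_BLOCKS = {
    "landmarks.pixel",
    "curves.pixel",
    "ruler.pixel",
    "ruler.interval",
    "scaling",
    "image.name",
}


def read_stereomorph(path, template=None) -> LandmarkConfiguration:
    """Read one tag-block shape file into a configuration.

    Landmark rows are named; output order follows the template's
    landmark-name order and absent names are flagged missing.  Curves
    are keyed by template curve names.  A ruler block (``ruler.pixel``
    pixels spanning ``ruler.interval`` physical units) or a ``scaling``
    block supplies the scale.
    """
    from .template import builtin_template  # local: avoid import cycle

    path = Path(path)
    spec_id, structure = None, None
    try:
        spec_id, structure = resolve_structure_suffix(path.name)
    except ValueError:
        pass
    if template is None:
        if structure is None:
            raise ShapeParseError(
                f"{path}: cannot infer structure from filename; pass a template"
            )
        template = builtin_template(structure)
    if spec_id is None:
        spec_id = path.stem

    blocks = _parse_blocks(path.read_text(), path.name)
    for name in set(blocks) - _KNOWN_BLOCKS:
        warnings.warn(f"{path.name}: ignoring unknown block <{name}>")
        del blocks[name]
    if "landmarks.pixel" not in blocks:
        raise ShapeParseError(f"{path}: no landmark block found")

    named: dict[str, tuple[float, float]] = {}
    for row in blocks["landmarks.pixel"]:
        parts = row.split()
        if len(parts) != 3:
            raise ShapeParseError(f"{path.name}: bad landmark row {row!r}")
        named[parts[0]] = (float(parts[1]), float(parts[2]))
    unknown = set(named) - set(template.landmark_names)
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown landmark names {sorted(unknown)}")
    lm = np.full((template.n_landmarks, 2), np.nan)
    for i, name in enumerate(template.landmark_names):
        if name in named:
            lm[i] = named[name]

    curve_points: dict[str, list[tuple[int, float, float]]] = {}
    for row in blocks.get("curves.pixel", []):
        parts = row.split()
        if len(parts) != 3 or "." not in parts[0]:
            raise ShapeParseError(f"{path.name}: bad curve row {row!r}")
        cname, _, idx = parts[0].rpartition(".")
        curve_points.setdefault(cname, []).append((int(idx), float(parts[1]), float(parts[2])))
    unknown = set(curve_points) - set(template.curve_names)
    if unknown:
        warnings.warn(f"{path.name}: ignoring unknown curve names {sorted(unknown)}")
    curves = []
    for cname in template.curve_names:
        if cname in curve_points:
            rows = sorted(curve_points[cname])
            curves.append(np.array([[x, y] for _, x, y in rows]))

    scale: float | None = None
    if "scaling" in blocks:
        scale = float(blocks["scaling"][0])
    elif "ruler.pixel" in blocks and "ruler.interval" in blocks:
        px = float(blocks["ruler.pixel"][0])
        if px <= 0:
            raise ShapeParseError(f"{path.name}: non-positive ruler.pixel")
        scale = float(blocks["ruler.interval"][0]) / px
    if scale is not None:
        lm = lm * scale
        curves = [c * scale for c in curves]

    return LandmarkConfiguration(
        specimen_id=spec_id,
        structure=template.structure,
        landmarks=lm,
        curves=curves,
        scale=scale,
        source_path=str(path),
        dialect="stereomorph",
    )


def write_stereomorph(config: LandmarkConfiguration, path, template=None) -> None:
    """Write one configuration in the tag-block dialect (missing names omitted)."""
    from .template import builtin_template

    if template is None:
        template = builtin_template(config.structure)
    s = config.scale if config.scale is not None else 1.0
    out = ["<landmarks.pixel>"]
    for name, pt, miss in zip(template.landmark_names, config.landmarks, config.missing_mask):
        if not miss:
            out.append(f"{name}\t{_fmt(pt[0] / s)}\t{_fmt(pt[1] / s)}")
    out.append("</landmarks.pixel>")
    if config.curves:
        out.append("<curves.pixel>")
        for cname, curve in zip(template.curve_names, config.curves):
            for j, p in enumerate(curve, start=1):
                out.append(f"{cname}.{j:04d}\t{_fmt(p[0] / s)}\t{_fmt(p[1] / s)}")
        out.append("</curves.pixel>")
    if config.scale is not None:
        out.append(f"<scaling>{_fmt(config.scale)}</scaling>")
    Path(path).write_text("\n".join(out) + "\n")


def read_shape_file(path, *, missing_as_negative: bool = True) -> list[LandmarkConfiguration]:
    """Dispatch on extension: ``.tps`` → tps reader, ``.txt`` → tag-block reader."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".tps":
        return read_tps(path, missing_as_negative=missing_as_negative)
    if ext == ".txt":
        return [read_stereomorph(path)]
    raise ValueError(f"unrecognised shape file extension {ext!r} for {path}")


def load_shape_dir(
    directory,
    *,
    structure: str | None = None,
    missing_as_negative: bool = True,
) -> list[LandmarkConfiguration]:
    """Read every ``*.tps`` / ``*.txt`` under a directory (recursively).

    When ``structure`` is given, only files whose ``_C`` / ``_P`` suffix
    maps to it are read.
    """
    directory = Path(directory)
    configs: list[LandmarkConfiguration] = []
    for path in sorted(directory.rglob("*")):
        if path.suffix.lower() not in {".tps", ".txt"}:
            continue
        if structure is not None:
            try:
                _, s = resolve_structure_suffix(path.name)
            except ValueError:
                continue
            if s != structure:
                continue
        configs.extend(read_shape_file(path, missing_as_negative=missing_as_negative))
    return configs


def resolve_structure_suffix(filename: str) -> tuple[str, str]:
    """Split ``<ID>_C.<ext>`` / ``<ID>_P.<ext>`` into id and structure.

    The suffix is matched case-insensitively on the last underscore
    token only.
    """
    stem = Path(filename).stem
    if not stem:
        raise ValueError(f"empty filename {filename!r}")
    head, sep, tail = stem.rpartition("_")
    if sep and tail.upper() in _SUFFIX_TO_STRUCTURE and head:
        return head, _SUFFIX_TO_STRUCTURE[tail.upper()]
    raise ValueError(
        f"filename {filename!r} lacks a recognised '_C'/'_P' structure suffix"
    )


# -- metadata / references ---------------------------------------------------


def _get(entry: dict, group: str, key: str):
    sub = entry.get(group)
    if isinstance(sub, dict):
        if key in sub:
            return sub[key]
        if key.replace("_", " ") in sub:
            return sub[key.replace("_", " ")]
    for probe in (f"{group}.{key}", f"{group}.{key.replace('_', ' ')}"):
        if probe in entry:
            return entry[probe]
    return None


def _is_empty(value) -> bool:
    if value is None:
        return True
    if isinstance(value, str) and not value.strip():
        return True
    return False


def _coerce_float(value, field_name: str, violations: list[str]) -> float | None:
    if _is_empty(value):
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        violations.append(f"non-numeric {field_name}: {value!r}")
        return None


def read_metadata(path) -> list[SpecimenRecord]:
    """Parse the specimen metadata YAML into records.

    The document maps specimen ids to entries with ``taxonomy`` /
    ``morphology`` / ``geography`` / ``stratigraphy`` sub-mappings
    (dotted flat keys are accepted too).  Mandatory-field violations
    and range violations are collected on each record, never repaired.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: metadata document must map specimen ids to entries")
    records: list[SpecimenRecord] = []
    seen: set[str] = set()
    for spec_id, entry in doc.items():
        spec_id = str(spec_id)
        if spec_id in seen:
            raise ValueError(f"{path}: duplicate specimen id {spec_id!r}")
        seen.add(spec_id)
        if entry is None:
            entry = {}
        if not isinstance(entry, dict):
            raise ValueError(f"{path}: entry for {spec_id!r} is not a mapping")
        violations: list[str] = []

        def top(key: str):
            return entry.get(key, entry.get(key.replace("_", "."), entry.get(key.replace("_", " "))))

        rec = SpecimenRecord(
            id=spec_id,
            ref_pic=top("ref_pic") if not _is_empty(top("ref_pic")) else None,
            enter_metadata=top("enter_metadata") if not _is_empty(top("enter_metadata")) else None,
            enter_landmark=top("enter_landmark") if not _is_empty(top("enter_landmark")) else None,
            comments=top("comments"),
            taxonomy=Taxonomy(
                **{
                    f: _get(entry, "taxonomy", f)
                    for f in (
                        "orig_genus", "genus", "gen_status", "gen_author", "subgen",
                        "orig_sp", "sp", "sp_author", "subsp",
                    )
                }
            ),
            morphology=Morphology(
                **{
                    f: _get(entry, "morphology", f)
                    for f in ("cephalon", "cranidium", "pygidium", "eyes", "ontogeny")
                }
            ),
            geography=Geography(
                locality=_get(entry, "geography", "locality"),
                country=_get(entry, "geography", "country"),
                lat=None,
                long=None,
                state=_get(entry, "geography", "state"),
                county=_get(entry, "geography", "county"),
            ),
            stratigraphy=Stratigraphy(
                **{
                    f: _get(entry, "stratigraphy", f)
                    for f in ("formation", "min_age", "max_age", "ref_age", "basin")
                }
            ),
            violations=violations,
        )
        rec.geography.lat = _coerce_float(_get(entry, "geography", "lat"), "geography.lat", violations)
        rec.geography.long = _coerce_float(_get(entry, "geography", "long"), "geography.long", violations)

        for dotted in _MANDATORY:
            if "." in dotted:
                group, key = dotted.split(".")
                value = getattr(getattr(rec, group), key)
            else:
                value = getattr(rec, dotted)
            if _is_empty(value):
                label = dotted if "." in dotted else dotted.replace("_", ".")
                violations.append(f"missing mandatory field {label}")
        if rec.geography.lat is not None and not -90.0 <= rec.geography.lat <= 90.0:
            violations.append("lat out of range")
        if rec.geography.long is not None and not -180.0 <= rec.geography.long <= 180.0:
            violations.append("long out of range")
        flags = (rec.morphology.cephalon, rec.morphology.cranidium, rec.morphology.pygidium)
        if not any(bool(f) for f in flags if f is not None):
            violations.append("no digitised structure flagged true")
        records.append(rec)
    return records


def read_references(path) -> list[ReferenceEntry]:
    """Read the references CSV (``ref_id,citation``); ref_id must be unique."""
    df = pd.read_csv(path, dtype=str)
    missing = {"ref_id", "citation"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: references table lacks columns {sorted(missing)}")
    dupes = df["ref_id"][df["ref_id"].duplicated()].tolist()
    if dupes:
        raise ValueError(f"{path}: duplicate ref_id values {dupes}")
    return [ReferenceEntry(r.ref_id, r.citation) for r in df.itertuples(index=False)]
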