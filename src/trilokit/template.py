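"""The landmark standard for trilobite cephala and pygidia.

The cephalon is described by 16 fixed landmarks and 4 semilandmark
curves, the pygidium by 7 landmarks and 3 curves.  Each curve is bound
to a start and an end landmark; eye landmarks may legitimately be
absent (blind taxa).  :func:`validate` performs the homogeneity check
used before assembling specimens into a common array: landmark and
curve counts, curve lengths, presence of a scale and of missing
landmarks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .shapeio import CEPHALON, PYGIDIUM, LandmarkConfiguration

__all__ = [
    "LandmarkDef",
    "CurveDef",
    "StructureTemplate",
    "Finding",
    "ValidationReport",
    "builtin_template",
    "validate",
    "mirror",
]


@dataclass(frozen=True)
class LandmarkDef:
    """One fixed landmark: 1-based index, short name and definition."""

    index: int
    name: str
    definition: str


@dataclass(frozen=True)
class CurveDef:
    """One semilandmark curve bound to its start/end landmarks (1-based)."""

    name: str
    start_landmark: int
    end_landmark: int


@dataclass(frozen=True)
class StructureTemplate:
    """The landmark scheme for one anatomical structure."""

    structure: str
    landmark_defs: tuple[LandmarkDef, ...]
    curve_defs: tuple[CurveDef, ...]
    optionally_absent: frozenset[int] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        n = self.n_landmarks
        for cd in self.curve_defs:
            if not (1 <= cd.start_landmark <= n and 1 <= cd.end_landmark <= n):
                raise ValueError(f"curve {cd.name!r} references an unknown landmark")
        if not self.optionally_absent <= {d.index for d in self.landmark_defs}:
            raise ValueError("optionally_absent references unknown landmark indices")

    @property
    def n_landmarks(self) -> int:
        return len(self.landmark_defs)

    @property
    def n_curves(self) -> int:
        return len(self.curve_defs)

    @property
    def landmark_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.landmark_defs)

    @property
    def curve_names(self) -> tuple[str, ...]:
        return tuple(d.name for d in self.curve_defs)

    def to_json(self) -> str:
        """Serialise the template (names, bindings, definitions) to JSON."""
        doc = {
            "structure": self.structure,
            "landmarks": [
                {"index": d.index, "name": d.name, "definition": d.definition}
                for d in self.landmark_defs
            ],
            "curves": [
                {"name": c.name, "start": c.start_landmark, "end": c.end_landmark}
                for c in self.curve_defs
            ],
            "optionally_absent": sorted(self.optionally_absent),
        }
        return json.dumps(doc, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "StructureTemplate":
        doc = json.loads(text)
        return cls(
            structure=doc["structure"],
            landmark_defs=tuple(
                LandmarkDef(d["index"], d["name"], d["definition"])
                for d in doc["landmarks"]
            ),
            curve_defs=tuple(
                CurveDef(c["name"], c["start"], c["end"]) for c in doc["curves"]
            ),
            optionally_absent=frozenset(doc.get("optionally_absent", ())),
        )


_CEPHALON_LANDMARKS = (
    "Anteriormost point of the sagittal cephalic length without spine",
    "Anteriormost point of the sagittal glabellar length",
    "Intersection between the sagittal axis and the occipital furrow",
    "Posteriormost point of the sagittal cephalic length",
    "Maximum transversal glabellar width",
    "Intersection between the occipital and axial furrows",
    "Intersection between the posterior margin and the axial furrow",
    "Anteriormost end of the eye",
    "Posteriormost end of the eye",
    "Anterior facial suture at the sagittal line",
    "Intersection between the posterior branch of facial suture and the posterior or lateral border furrow",
    "Intersection between the posterior branch of facial suture and the posterior or lateral margin",
    "Anteriormost point of the sagittal (or ex-sagittal) cephalic length (if spiny, LM13 at the tip of the spine)",
    "Lateralmost external point of the eye",
    "Cephalic width at the level of the posterior margin of the occipital ring (LM4). If that point cannot be located, it is defined as the extreme of the genal angle.",
    "Tip of the genal angle or spine",
)

_CEPHALON_CURVES = (
    CurveDef("glabella", 2, 7),
    CurveDef("facial_suture", 10, 12),
    CurveDef("anterior_margin", 13, 15),
    CurveDef("posterior_margin", 4, 15),
)

# Eye landmarks may be absent in blind taxa.
_CEPHALON_OPTIONAL = frozenset({8, 9, 14})

_PYGIDIUM_LANDMARKS = (
    "Anteriormost point of the pygidial axis",
    "Posteriormost point of the pygidial axis",
    "Border furrow at the sagittal point",
    "Posteriormost point of pygidium at the sagittal line (if spiny LM 4 at the tip of the spine).",
    "Intersection between the axial furrow and the anterior pygidial margin",
    "Intersection between the anterior pygidial margin and the border furrow",
    "Intersection between the anterior and the lateral pygidial margin",
)

_PYGIDIUM_CURVES = (
    CurveDef("axis", 1, 2),
    CurveDef("border_furrow", 3, 6),
    CurveDef("margin", 4, 5),
)


def _make(structure: str, defs: tuple[str, ...], curves, optional) -> StructureTemplate:
    return StructureTemplate(
        structure=structure,
        landmark_defs=tuple(
            LandmarkDef(i + 1, f"LM{i + 1}", text) for i, text in enumerate(defs)
        ),
        curve_defs=curves,
        optionally_absent=optional,
    )


_TEMPLATES = {
    CEPHALON: _make(CEPHALON, _CEPHALON_LANDMARKS, _CEPHALON_CURVES, _CEPHALON_OPTIONAL),
    PYGIDIUM: _make(PYGIDIUM, _PYGIDIUM_LANDMARKS, _PYGIDIUM_CURVES, frozenset()),
}


def builtin_template(structure: str) -> StructureTemplate:
    """Return the bundled landmark template for ``cephalon`` or ``pygidium``."""
    try:
        return _TEMPLATES[structure]
    except KeyError:
        raise ValueError(
            f"unknown structure {structure!r}; expected {CEPHALON!r} or {PYGIDIUM!r}"
        ) from None


@dataclass(frozen=True)
class Finding:
    """A coded validation finding, e.g. ``missing_landmark`` / ``LM7``."""

    code: str
    detail: str = ""

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.code}({self.detail})" if self.detail else self.code


@dataclass
class ValidationReport:
    specimen_id: str
    conforms: bool
    issues: list[Finding]
    notes: list[Finding] = field(default_factory=list)


# LM10 sits on LM1 for marginal sutures; flag coincidence as informational.
_COINCIDENCE_TOL = 1e-6
MIN_CURVE_POINTS = 3


def validate(
    config: LandmarkConfiguration,
    template: StructureTemplate | None = None,
    *,
    require_scale: bool = True,
    allow_absent: bool = True,
) -> ValidationReport:
    """Homogeneity check of one configuration against the template.

    Counts landmarks and curves, checks curve lengths, the presence of
    a scale and of missing landmarks.  With ``allow_absent`` the
    template's optionally-absent landmarks (eyes) may be missing
    without breaking conformity; they are recorded as notes.
    """
    if template is None:
        template = builtin_template(config.structure)
    if config.structure != template.structure:
        raise ValueError(
            f"structure mismatch: configuration is {config.structure!r}, "
            f"template is {template.structure!r}"
        )
    issues: list[Finding] = []
    notes: list[Finding] = []

    if config.n_landmarks != template.n_landmarks:
        issues.append(
            Finding("wrong_landmark_count", f"{config.n_landmarks}!={template.n_landmarks}")
        )
    else:
        for i in np.flatnonzero(config.missing_mask):
            idx = int(i) + 1
            if allow_absent and idx in template.optionally_absent:
                notes.append(Finding("absent_landmark", f"LM{idx}"))
            else:
                issues.append(Finding("missing_landmark", f"LM{idx}"))
        lm = config.landmarks
        if (
            config.structure == CEPHALON
            and not config.missing_mask[0]
            and not config.missing_mask[9]
            and float(np.hypot(*(lm[9] - lm[0]))) < _COINCIDENCE_TOL
        ):
            notes.append(Finding("lm10_at_lm1"))

    if len(config.curves) != template.n_curves:
        issues.append(
            Finding("wrong_curve_count", f"{len(config.curves)}!={template.n_curves}")
        )
    names = template.curve_names
    for j, curve in enumerate(config.curves):
        name = names[j] if j < len(names) else f"curve{j + 1}"
        if len(curve) < MIN_CURVE_POINTS:
            issues.append(Finding("short_curve", name))

    if require_scale and config.scale is None:
        issues.append(Finding("missing_scale"))

    return ValidationReport(
        specimen_id=config.specimen_id,
        conforms=not issues,
        issues=issues,
        notes=notes,
    )


def mirror(config: LandmarkConfiguration) -> LandmarkConfiguration:
    """Reflect a configuration about the vertical (sagittal) axis.

    Negates x coordinates of landmarks and curve points, preserving
    point order and missing flags; an involution.
    """
    lm = config.landmarks.copy()
    lm[:, 0] = -lm[:, 0]
    curves = []
    for c in config.curves:
        c = c.copy()
        c[:, 0] = -c[:, 0]
        curves.append(c)
    return LandmarkConfiguration(
        specimen_id=config.specimen_id,
        structure=config.structure,
        landmarks=lm,
        curves=curves,
        scale=config.scale,
        source_path=config.source_path,
        dialect=config.dialect,
    )
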