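"""Arc-length curve resampling and assembly into the standard shape array.

Each semilandmark curve is resampled to a user-chosen number of
equally spaced points on its piecewise-linear interpolant.  Conforming
specimens are then stacked into a ``(points, 2, specimens)`` array.
Because every curve of the standard is bound to fixed start/end
landmarks, the two endpoint semilandmarks duplicate those landmarks
and are dropped at assembly time, so a curve resampled to ``k`` points
contributes ``k - 2`` semilandmarks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .shapeio import LandmarkConfiguration
from .template import StructureTemplate, validate

__all__ = ["PointRole", "ShapeArray", "Exclusion", "resample_curve", "fix_shapes"]


@dataclass(frozen=True)
class PointRole:
    """Provenance of one array point: a fixed landmark or a semilandmark.

    ``kind`` is ``"fixed"`` (then ``index`` is the 1-based landmark
    number) or ``"semilandmark"`` (then ``curve`` names the curve and
    ``index`` is the position within the resampled curve, counting the
    dropped start endpoint as 0).
    """

    kind: str
    index: int
    curve: str | None = None


@dataclass
class ShapeArray:
    """Stacked configurations: ``coords[p, 2, n]`` plus point provenance."""

    coords: np.ndarray
    specimen_ids: list[str]
    point_roles: list[PointRole]
    resample_spec: list[int]

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1] != 2:
            raise ValueError("coords must have shape (points, 2, specimens)")
        if self.coords.shape[2] != len(self.specimen_ids):
            raise ValueError("specimen_ids length must match coords")
        if self.coords.shape[0] != len(self.point_roles):
            raise ValueError("point_roles length must match coords")
        if not np.isfinite(self.coords).all():
            raise ValueError("shape array must be fully finite")

    @property
    def n_points(self) -> int:
        return self.coords.shape[0]

    @property
    def n_specimens(self) -> int:
        return self.coords.shape[2]

    def specimen(self, i: int) -> np.ndarray:
        return self.coords[:, :, i]


@dataclass(frozen=True)
class Exclusion:
    specimen_id: str
    reason: str


def resample_curve(polyline: np.ndarray, k: int) -> np.ndarray:
    """Resample a polyline to ``k`` points equally spaced in arc length.

    Points sit on the piecewise-linear interpolant at arc-length
    positions ``j * L / (k - 1)``; the first and last outputs equal the
    input endpoints exactly.
    """
    poly = np.asarray(polyline, dtype=float)
    if poly.ndim != 2 or poly.shape[1] != 2 or len(poly) < 2:
        raise ValueError("polyline must be an (m >= 2, 2) array")
    if not np.isfinite(poly).all():
        raise ValueError("polyline must be finite")
    if k < 3:
        raise ValueError("k must be >= 3")
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    total = s[-1]
    if total <= 0.0:
        raise ValueError("degenerate curve: all points identical")
    t = np.linspace(0.0, total, k)
    out = np.column_stack([np.interp(t, s, poly[:, 0]), np.interp(t, s, poly[:, 1])])
    out[0] = poly[0]
    out[-1] = poly[-1]
    return out


def _arclength_fractions(polyline: np.ndarray) -> np.ndarray:
    """Cumulative arc-length fraction of each vertex, in [0, 1]."""
    seg = np.linalg.norm(np.diff(polyline, axis=0), axis=1)
    s = np.concatenate(([0.0], np.cumsum(seg)))
    if s[-1] <= 0:
        raise ValueError("degenerate curve: all points identical")
    return s / s[-1]


def fix_shapes(
    configs: Iterable[LandmarkConfiguration],
    template: StructureTemplate,
    k_per_curve: Sequence[int],
    *,
    policy: Literal["drop_specimen", "drop_trait"] = "drop_specimen",
    require_scale: bool = False,
    include_curves: bool = True,
) -> tuple[ShapeArray, list[Exclusion]]:
    """Validate, resample and stack configurations into a :class:`ShapeArray`.

    Under ``drop_specimen`` (the default) any specimen failing the
    homogeneity check — wrong counts, any missing landmark, short or
    degenerate curves — is excluded and reported.  Under ``drop_trait``
    landmarks missing in *any* specimen are removed from *all*
    specimens, together with every curve bound to a removed landmark,
    before assembly.

    ``include_curves=False`` assembles fixed landmarks only (used for
    the landmark-only error comparison).
    """
    configs = list(configs)
    k_per_curve = [int(k) for k in k_per_curve]
    if len(k_per_curve) != template.n_curves:
        raise ValueError(
            f"k_per_curve has {len(k_per_curve)} entries, template defines "
            f"{template.n_curves} curves"
        )
    if any(k < 3 for k in k_per_curve):
        raise ValueError("every semilandmark count must be >= 3")
    if not configs:
        raise ValueError("no configurations supplied")
    structures = {c.structure for c in configs}
    if structures != {template.structure}:
        raise ValueError(
            f"inconsistent structures {sorted(map(str, structures))}; "
            f"template is {template.structure!r}"
        )
    if policy not in ("drop_specimen", "drop_trait"):
        raise ValueError(f"unknown policy {policy!r}")

    exclusions: list[Exclusion] = []
    reports = {
        c.specimen_id: validate(c, template, require_scale=require_scale, allow_absent=False)
        for c in configs
    }

    dropped_landmarks: set[int] = set()  # 1-based
    if policy == "drop_trait":
        for rep in reports.values():
            for f in rep.issues:
                if f.code == "missing_landmark":
                    dropped_landmarks.add(int(f.detail[2:]))
    dropped_curves = {
        cd.name
        for cd in template.curve_defs
        if cd.start_landmark in dropped_landmarks or cd.end_landmark in dropped_landmarks
    }

    kept: list[LandmarkConfiguration] = []
    for c in configs:
        rep = reports[c.specimen_id]
        blocking = [
            f
            for f in rep.issues
            if not (
                policy == "drop_trait"
                and f.code == "missing_landmark"
                and int(f.detail[2:]) in dropped_landmarks
            )
        ]
        if blocking:
            exclusions.append(
                Exclusion(c.specimen_id, "; ".join(str(f) for f in blocking))
            )
        else:
            kept.append(c)
    if not kept:
        raise ValueError("no specimens survive the homogeneity check")

    kept_lm = [d.index for d in template.landmark_defs if d.index not in dropped_landmarks]
    kept_curves = [
        (j, cd, k_per_curve[j])
        for j, cd in enumerate(template.curve_defs)
        if cd.name not in dropped_curves
    ]

    roles: list[PointRole] = [PointRole("fixed", i) for i in kept_lm]
    if include_curves:
        for _, cd, k in kept_curves:
            roles.extend(PointRole("semilandmark", j, cd.name) for j in range(1, k - 1))

    stacked = np.empty((len(roles), 2, len(kept)))
    for s, c in enumerate(kept):
        rows = [c.landmarks[i - 1] for i in kept_lm]
        if include_curves:
            for j, cd, k in kept_curves:
                rows.extend(resample_curve(c.curves[j], k)[1:-1])
        stacked[:, :, s] = np.asarray(rows)

    array = ShapeArray(
        coords=stacked,
        specimen_ids=[c.specimen_id for c in kept],
        point_roles=roles,
        resample_spec=[k for _, _, k in kept_curves] if include_curves else [],
    )
    return array, exclusions
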