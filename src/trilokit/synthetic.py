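"""Synthetic template-conforming datasets with known latent structure.

Generates groups of specimens around idealised right-half base shapes:
genus means are Gaussian displacements of the base configuration,
specimens add within-genus digitising noise, and nuisance similarity
transforms (rotation, translation, scale) plus optional defects
(missing landmarks, missing scales, blind genera) are injected on top.
Curve points follow the deformed landmarks by interpolating the
endpoint displacements along arc length, so curve/landmark bindings
stay exact.  Everything is reproducible from the seed and every latent
value is recorded in a truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .disparity import DEVONIAN_STAGES
from .shapeio import (
    CEPHALON,
    PYGIDIUM,
    LandmarkConfiguration,
    write_stereomorph,
    write_tps,
)
from .resample import _arclength_fractions
from .template import StructureTemplate, builtin_template

__all__ = ["SimulationSpec", "base_shape", "simulate_dataset", "simulate_error_experiment"]


_CEPHALON_LM = np.array(
    [
        [0.00, 0.98],   # LM1  anterior sagittal margin
        [0.00, 0.80],   # LM2  anterior glabella
        [0.00, 0.05],   # LM3  occipital furrow at axis
        [0.00, -0.10],  # LM4  posterior sagittal margin
        [0.35, 0.30],   # LM5  max glabellar width
        [0.30, 0.02],   # LM6  occipital x axial furrow
        [0.32, -0.10],  # LM7  posterior margin x axial furrow
        [0.55, 0.55],   # LM8  eye, anterior
        [0.62, 0.25],   # LM9  eye, posterior
        [0.00, 0.92],   # LM10 anterior facial suture at axis
        [0.80, -0.02],  # LM11 suture x border furrow
        [0.85, -0.08],  # LM12 suture x margin
        [0.00, 1.00],   # LM13 anteriormost margin (spine tip)
        [0.66, 0.40],   # LM14 eye, lateral
        [1.00, -0.05],  # LM15 width at occipital level
        [1.05, -0.35],  # LM16 genal angle/spine
    ]
)

_CEPHALON_CURVES = [
    # glabella: LM2 -> LM7
    np.array([[0.00, 0.80], [0.18, 0.72], [0.30, 0.55], [0.35, 0.30],
              [0.33, 0.12], [0.30, 0.02], [0.32, -0.10]]),
    # facial suture: LM10 -> LM12
    np.array([[0.00, 0.92], [0.25, 0.88], [0.45, 0.72], [0.55, 0.55],
              [0.63, 0.35], [0.72, 0.12], [0.85, -0.08]]),
    # anterior margin: LM13 -> LM15
    np.array([[0.00, 1.00], [0.35, 0.96], [0.65, 0.80], [0.88, 0.50],
              [1.00, 0.18], [1.00, -0.05]]),
    # posterior margin: LM4 -> LM15
    np.array([[0.00, -0.10], [0.30, -0.13], [0.60, -0.13], [0.85, -0.10],
              [1.00, -0.05]]),
]

_PYGIDIUM_LM = np.array(
    [
        [0.00, 0.50],   # LM1 anterior axis
        [0.00, -0.10],  # LM2 posterior axis
        [0.00, -0.25],  # LM3 border furrow at axis
        [0.00, -0.40],  # LM4 posterior margin (spine tip)
        [0.25, 0.50],   # LM5 axial furrow x anterior margin
        [0.85, 0.42],   # LM6 anterior margin x border furrow
        [1.00, 0.50],   # LM7 anterior x lateral margin
    ]
)

_PYGIDIUM_CURVES = [
    # axis: LM1 -> LM2
    np.array([[0.00, 0.50], [0.17, 0.35], [0.16, 0.15], [0.10, 0.00], [0.00, -0.10]]),
    # border furrow: LM3 -> LM6
    np.array([[0.00, -0.25], [0.35, -0.20], [0.65, -0.02], [0.80, 0.22], [0.85, 0.42]]),
    # margin: LM4 -> LM5 (around the lateral and anterior margins)
    np.array([[0.00, -0.40], [0.45, -0.34], [0.85, -0.12], [1.03, 0.15],
              [1.00, 0.50], [0.60, 0.52], [0.25, 0.50]]),
]


def base_shape(structure: str) -> LandmarkConfiguration:
    """Idealised template-conforming configuration for one structure.

    Curve endpoints coincide exactly with their bound landmarks and the
    configuration passes validation with no issues.
    """
    if structure == CEPHALON:
        lm, curves = _CEPHALON_LM, _CEPHALON_CURVES
    elif structure == PYGIDIUM:
        lm, curves = _PYGIDIUM_LM, _PYGIDIUM_CURVES
    else:
        raise ValueError(f"unknown structure {structure!r}")
    return LandmarkConfiguration(
        specimen_id=f"BASE_{structure[0].upper()}",
        structure=structure,
        landmarks=lm.copy(),
        curves=[c.copy() for c in curves],
        scale=1.0,
        dialect=None,
    )


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one synthetic dataset (all randomness from ``seed``)."""

    structure: str = CEPHALON
    n_genera: int = 5
    n_per_genus: int = 3
    sigma_between: float = 0.08
    sigma_within: float = 0.01
    nuisance: tuple[float, float, float] = (180.0, 2.0, 0.5)
    defects: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0
    stages: tuple[str, ...] = tuple(DEVONIAN_STAGES.names)

    def __post_init__(self) -> None:
        p_lm, p_scale, blind = self.defects
        for p in (p_lm, p_scale, blind):
            if not 0.0 <= p <= 1.0:
                raise ValueError("defect probabilities must be in [0, 1]")
        if self.sigma_between < 0 or self.sigma_within < 0:
            raise ValueError("sigmas must be non-negative")
        if self.n_genera < 1 or self.n_per_genus < 1:
            raise ValueError("need at least one genus and one specimen per genus")


def deform(
    config: LandmarkConfiguration,
    rng: np.random.Generator,
    sigma: float,
    template: StructureTemplate | None = None,
    *,
    landmark_offsets: dict[int, tuple[float, float]] | None = None,
) -> LandmarkConfiguration:
    """Displace landmarks by isotropic Gaussian noise, dragging curves along.

    Curve points receive the arc-length interpolation of their two
    endpoint-landmark displacements plus interior jitter that vanishes
    at the endpoints, so endpoint bindings remain exact.
    ``landmark_offsets`` (0-based index -> vector) displaces specific
    landmarks *after* curve propagation — the misplaced-landmark
    scenario, where the curve stays on the true outline.
    """
    if template is None:
        template = builtin_template(config.structure)
    lm = config.landmarks.copy()
    d = rng.normal(0.0, sigma, size=lm.shape)
    present = ~config.missing_mask
    lm[present] += d[present]
    curves = []
    for curve, cd in zip(config.curves, template.curve_defs):
        t = _arclength_fractions(curve)
        d_start = d[cd.start_landmark - 1]
        d_end = d[cd.end_landmark - 1]
        disp = np.outer(1.0 - t, d_start) + np.outer(t, d_end)
        jitter = rng.normal(0.0, 0.5 * sigma, size=curve.shape)
        disp += jitter * np.sin(np.pi * t)[:, None]
        curves.append(curve + disp)
    if landmark_offsets:
        for idx, vec in landmark_offsets.items():
            lm[idx] += np.asarray(vec, dtype=float)
    return replace(config, landmarks=lm, curves=curves)


def apply_similarity(
    config: LandmarkConfiguration,
    *,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    scale_factor: float = 1.0,
) -> LandmarkConfiguration:
    """Rotate, scale and translate a configuration (missing flags kept)."""
    if scale_factor <= 0:
        raise ValueError("scale_factor must be positive")
    theta = np.deg2rad(rotation_deg)
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    t = np.asarray(translation, dtype=float)

    def tf(X: np.ndarray) -> np.ndarray:
        return scale_factor * (X @ R.T) + t

    return replace(
        config,
        landmarks=tf(config.landmarks),
        curves=[tf(c) for c in config.curves],
    )


def _shift_positive(config: LandmarkConfiguration, margin: float = 0.5) -> LandmarkConfiguration:
    """Translate into the positive quadrant (digitiser coordinates are
    pixel-like, never negative — and negative pairs encode missing)."""
    pools = [config.landmarks[~config.missing_mask]] + list(config.curves)
    lo = np.min([p.min(axis=0) for p in pools if len(p)], axis=0)
    shift = np.maximum(0.0, margin - lo)
    return replace(
        config,
        landmarks=config.landmarks + shift,
        curves=[c + shift for c in config.curves],
    )


def _random_nuisance(rng: np.random.Generator, nuisance) -> dict:
    rot_range, trans_range, scale_range = nuisance
    return {
        "rotation_deg": float(rng.uniform(-rot_range, rot_range)),
        "translation": tuple(rng.uniform(-trans_range, trans_range, size=2)),
        "scale_factor": float(np.exp(rng.uniform(-scale_range, scale_range))),
    }


def simulate_dataset(spec: SimulationSpec, out_dir) -> tuple[list[LandmarkConfiguration], pd.DataFrame]:
    """Generate a multi-genus dataset on disk plus its truth table.

    Genus mean shapes are isotropic Gaussian displacements of the base
    shape (sd ``sigma_between``); specimens add displacements of sd
    ``sigma_within``, then a random similarity nuisance.  Half the
    files are written in tps, half in the tag-block dialect, alongside
    a metadata YAML and ``truth.csv``.  Byte-identical for a fixed
    seed.
    """
    out_dir = Path(out_dir)
    rng = np.random.default_rng(spec.seed)
    template = builtin_template(spec.structure)
    base = base_shape(spec.structure)
    suffix = "C" if spec.structure == CEPHALON else "P"
    p_missing_lm, p_missing_scale, blind_fraction = spec.defects
    eye_idx = sorted(i - 1 for i in template.optionally_absent)

    lm_dir = out_dir / "landmarks" / spec.structure
    lm_dir.mkdir(parents=True, exist_ok=True)

    configs: list[LandmarkConfiguration] = []
    truth_rows: list[dict] = []
    metadata: dict[str, dict] = {}
    counter = 0
    for g in range(spec.n_genera):
        genus = f"Genus{g + 1:02d}"
        genus_mean = deform(base, rng, spec.sigma_between, template)
        blind = bool(eye_idx) and rng.random() < blind_fraction
        stage = str(rng.choice(list(spec.stages)))
        for i in range(spec.n_per_genus):
            counter += 1
            spec_id = f"SYN-{g + 1:02d}-{i + 1:02d}"
            cfg = deform(genus_mean, rng, spec.sigma_within, template)
            lm = cfg.landmarks.copy()
            if blind:
                lm[eye_idx] = np.nan
            missing_lm: int | None = None
            if p_missing_lm > 0 and rng.random() < p_missing_lm:
                candidates = [
                    j
                    for j in range(template.n_landmarks)
                    if not np.isnan(lm[j]).any() and (j + 1) not in template.optionally_absent
                ]
                missing_lm = int(rng.choice(candidates))
                lm[missing_lm] = np.nan
            cfg = replace(cfg, landmarks=lm, specimen_id=spec_id)
            nui = _random_nuisance(rng, spec.nuisance)
            cfg = _shift_positive(apply_similarity(cfg, **nui))
            missing_scale = p_missing_scale > 0 and rng.random() < p_missing_scale
            cfg = replace(cfg, scale=None if missing_scale else 1.0)

            dialect = "tps" if counter % 2 == 1 else "stereomorph"
            fname = f"{spec_id}_{suffix}." + ("tps" if dialect == "tps" else "txt")
            path = lm_dir / fname
            if dialect == "tps":
                write_tps([cfg], path)
            else:
                write_stereomorph(cfg, path, template)
            cfg = replace(cfg, source_path=str(path), dialect=dialect)
            configs.append(cfg)

            metadata[spec_id] = {
                "ref.pic": "synthetic",
                "enter.metadata": "SIM",
                "enter.landmark": "SIM",
                "taxonomy": {"orig_genus": genus, "genus": genus, "sp": f"{genus} synthetica"},
                "morphology": {
                    "cephalon": spec.structure == CEPHALON,
                    "cranidium": False,
                    "pygidium": spec.structure == PYGIDIUM,
                    "eyes": not blind,
                    "ontogeny": "Holaspis",
                },
                "geography": {"locality": "synthetic locality", "lat": 0.0, "long": 0.0},
                "stratigraphy": {"min_age": stage, "max_age": stage},
            }
            truth_rows.append(
                {
                    "specimen_id": spec_id,
                    "genus": genus,
                    "structure": spec.structure,
                    "dialect": dialect,
                    "stage": stage,
                    "blind": blind,
                    "missing_landmark": "" if missing_lm is None else f"LM{missing_lm + 1}",
                    "missing_scale": missing_scale,
                    "rotation_deg": nui["rotation_deg"],
                    "translation_x": nui["translation"][0],
                    "translation_y": nui["translation"][1],
                    "scale_factor": nui["scale_factor"],
                    "file": fname,
                }
            )

    with open(out_dir / "metadata.yaml", "w") as fh:
        yaml.safe_dump(metadata, fh, sort_keys=False)
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out_dir / "truth.csv", index=False)
    return configs, truth


def simulate_error_experiment(
    seed: int,
    *,
    sigma_within: float = 0.005,
    sigma_among: float = 0.01,
    n_replicates: int = 10,
    n_observers: int = 8,
    n_genera: int = 20,
    sigma_genus: float = 0.1,
    lm15_offset: float | None = None,
    structure: str = CEPHALON,
    nuisance: tuple[float, float, float] = (30.0, 0.5, 0.1),
) -> tuple[dict[str, list[LandmarkConfiguration]], dict]:
    """Replicate-digitisation experiment with known error structure.

    Produces two within-observer groups (repeated digitisations of one
    specimen, noise sd ``sigma_within``), an among-observer group
    (observer-specific displacement fields of sd ``sigma_among`` plus
    digitising noise) and an among-genus reference group (spread
    ``sigma_genus``).  With ``lm15_offset`` the last observer misplaces
    LM15 by that amount while the curves stay on the true outline.
    """
    if n_replicates < 2 or n_observers < 2:
        raise ValueError("need at least 2 replicates and 2 observers")
    rng = np.random.default_rng(seed)
    template = builtin_template(structure)
    base = base_shape(structure)

    def finish(cfg: LandmarkConfiguration, group: str, i: int) -> LandmarkConfiguration:
        cfg = _shift_positive(apply_similarity(cfg, **_random_nuisance(rng, nuisance)))
        return replace(cfg, specimen_id=f"{group}-{i + 1:02d}")

    groups: dict[str, list[LandmarkConfiguration]] = {}
    for w in (1, 2):
        groups[f"within_obs_{w}"] = [
            finish(deform(base, rng, sigma_within, template), f"WITHIN{w}", i)
            for i in range(n_replicates)
        ]
    among = []
    for o in range(n_observers):
        cfg = deform(base, rng, sigma_among, template)  # observer bias field
        offsets = None
        if lm15_offset is not None and o == n_observers - 1:
            offsets = {14: (lm15_offset, 0.0)}  # LM15, landmark only
        cfg = deform(cfg, rng, sigma_within, template, landmark_offsets=offsets)
        among.append(finish(cfg, "AMONG", o))
    groups["among_obs"] = among
    groups["among_genus"] = [
        finish(deform(base, rng, sigma_genus, template), "GENUS", g)
        for g in range(n_genera)
    ]
    truth = {
        "seed": seed,
        "sigma_within": sigma_within,
        "sigma_among": sigma_among,
        "sigma_genus": sigma_genus,
        "n_replicates": n_replicates,
        "n_observers": n_observers,
        "n_genera": n_genera,
        "lm15_offset": lm15_offset,
    }
    return groups, truth
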