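"""Disparity metrics, stage binning and diversity standardisation.

Metrics on morphospace scores: sum of per-axis sample variances (SoV),
sum of per-axis ranges (SoR) and mean nearest-neighbour distance
(NND).  Specimens are assigned to chronostratigraphic bins from their
min/max stage ages, disparity is bootstrapped per bin, and taxonomic
richness can be range-through standardised from an occurrence table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .morphospace import Morphospace

__all__ = [
    "Stage",
    "StageTable",
    "DEVONIAN_STAGES",
    "sov",
    "sor",
    "nnd",
    "assign_bins",
    "disparity_through_time",
    "richness_range_through",
]


@dataclass(frozen=True)
class Stage:
    name: str
    base_age: float  # Ma, older bound
    top_age: float  # Ma, younger bound

    def __post_init__(self) -> None:
        if not self.base_age > self.top_age:
            raise ValueError(f"stage {self.name!r}: base_age must exceed top_age")


class StageTable:
    """Contiguous, ordered (old to young) chronostratigraphic stages."""

    def __init__(self, stages: Iterable[Stage | tuple]) -> None:
        parsed = [s if isinstance(s, Stage) else Stage(*s) for s in stages]
        if not parsed:
            raise ValueError("empty stage table")
        for older, younger in zip(parsed, parsed[1:]):
            if abs(older.top_age - younger.base_age) > 1e-9:
                raise ValueError(
                    f"stages {older.name!r} and {younger.name!r} are not contiguous"
                )
        self.stages = parsed
        self._index = {s.name: i for i, s in enumerate(parsed)}
        if len(self._index) != len(parsed):
            raise ValueError("duplicate stage names")

    def __len__(self) -> int:
        return len(self.stages)

    def __iter__(self):
        return iter(self.stages)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.stages]

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise KeyError(f"unresolvable stage name {name!r}") from None

    def between(self, first: str, second: str) -> list[str]:
        """Stage names covered between two stages, inclusive, in either order."""
        i, j = self.index(first), self.index(second)
        if i > j:
            i, j = j, i
        return [s.name for s in self.stages[i : j + 1]]

    @classmethod
    def from_csv(cls, path) -> "StageTable":
        df = pd.read_csv(path)
        missing = {"stage", "base_age", "top_age"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: stage table lacks columns {sorted(missing)}")
        return cls(
            Stage(str(r.stage), float(r.base_age), float(r.top_age))
            for r in df.itertuples(index=False)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(s.name, s.base_age, s.top_age) for s in self.stages],
            columns=["stage", "base_age", "top_age"],
        )


#: Devonian stages with ICS boundary ages (Ma).
DEVONIAN_STAGES = StageTable(
    [
        Stage("Lochkovian", 419.2, 410.8),
        Stage("Pragian", 410.8, 407.6),
        Stage("Emsian", 407.6, 393.3),
        Stage("Eifelian", 393.3, 387.7),
        Stage("Givetian", 387.7, 382.7),
        Stage("Frasnian", 382.7, 372.2),
        Stage("Famennian", 372.2, 358.9),
    ]
)


def _scores_matrix(scores) -> np.ndarray:
    X = np.asarray(scores, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.ndim != 2:
        raise ValueError("scores must be a 2D (n x m) matrix")
    if len(X) < 2:
        raise ValueError("need at least 2 points")
    return X


def sov(scores) -> float:
    """Sum over axes of the sample variance (denominator n - 1)."""
    X = _scores_matrix(scores)
    return float(X.var(axis=0, ddof=1).sum())


def sor(scores) -> float:
    """Sum over axes of the range (max - min)."""
    X = _scores_matrix(scores)
    return float((X.max(axis=0) - X.min(axis=0)).sum())


def nnd(scores) -> float:
    """Mean Euclidean distance from each point to its nearest neighbour."""
    X = _scores_matrix(scores)
    D = squareform(pdist(X))
    np.fill_diagonal(D, np.inf)
    return float(D.min(axis=1).mean())


def assign_bins(
    records,
    stages: StageTable,
    mode: str = "overlap",
) -> dict[str, list[str]]:
    """Map specimens (or taxa) to stage bins.

    ``records`` is either a list of specimen records (with
    ``stratigraphy.min_age`` / ``max_age`` and, for ``range_through``,
    ``taxonomy.genus``) or a mapping of id to ``(max_age_stage,
    min_age_stage)``.

    ``overlap`` assigns each specimen to every stage intersecting its
    age interval.  ``range_through`` pools records by taxon and marks
    the taxon present in every stage between its first and last
    occupied stage inclusive.
    """
    if mode not in ("overlap", "range_through"):
        raise ValueError(f"unknown mode {mode!r}")

    if isinstance(records, Mapping):
        spans = {str(k): (v[0], v[1]) for k, v in records.items()}
        taxa = {k: k for k in spans}
    else:
        spans, taxa = {}, {}
        for rec in records:
            spans[rec.id] = (rec.stratigraphy.max_age, rec.stratigraphy.min_age)
            taxa[rec.id] = rec.taxonomy.genus or rec.id

    if mode == "overlap":
        return {rid: stages.between(a, b) for rid, (a, b) in spans.items()}

    occupied: dict[str, set[int]] = {}
    for rid, (a, b) in spans.items():
        idx = {stages.index(s) for s in stages.between(a, b)}
        occupied.setdefault(taxa[rid], set()).update(idx)
    return {
        taxon: [stages.stages[i].name for i in range(min(idx), max(idx) + 1)]
        for taxon, idx in occupied.items()
    }


def disparity_through_time(
    space: Morphospace,
    bin_map: Mapping[str, Iterable[str] | str],
    *,
    n_boot: int = 1000,
    coverage: float = 0.95,
    seed: int,
    n_axes: int | None = None,
    bin_order: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-bin disparity with bootstrap percentile intervals.

    ``bin_map`` maps specimen id to its bin(s) (as from
    :func:`assign_bins` in overlap mode).  Metrics are computed on the
    first ``n_axes`` score columns (default: all retained components);
    uncertainty comes from resampling specimens within each bin with
    replacement.  Bins with fewer than two specimens are reported with
    absent (NaN) metrics.
    """
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    rng = np.random.default_rng(seed)
    row_of = {sid: i for i, sid in enumerate(space.specimen_ids)}
    unknown = set(bin_map) - set(row_of)
    if unknown:
        raise KeyError(f"unknown specimens in bin map: {sorted(unknown)}")

    members: dict[str, list[int]] = {}
    order: list[str] = []
    for sid, bins in bin_map.items():
        if isinstance(bins, str):
            bins = [bins]
        for b in bins:
            if b not in members:
                members[b] = []
                order.append(b)
            members[b].append(row_of[sid])
    if bin_order is not None:
        extra = [b for b in order if b not in bin_order]
        order = [b for b in bin_order if b in members] + extra
    if not members:
        raise ValueError("bin map assigns no specimens")

    m = space.n_components if n_axes is None else min(int(n_axes), space.n_components)
    lo_q = 100 * (1 - coverage) / 2
    hi_q = 100 - lo_q
    metrics = {"SoV": sov, "SoR": sor, "NND": nnd}

    rows = []
    for b in order:
        idx = np.array(sorted(members[b]))
        X = space.scores[idx][:, :m]
        row: dict[str, object] = {"bin": b, "n": len(idx)}
        if len(idx) < 2:
            for name in metrics:
                row[name] = np.nan
                row[f"{name}_lower"] = np.nan
                row[f"{name}_upper"] = np.nan
        else:
            boot = {name: np.empty(n_boot) for name in metrics}
            for name, fn in metrics.items():
                row[name] = fn(X)
            for r in range(n_boot):
                pick = rng.integers(0, len(idx), size=len(idx))
                Xb = X[pick]
                for name, fn in metrics.items():
                    boot[name][r] = fn(Xb)
            for name in metrics:
                row[f"{name}_lower"] = float(np.percentile(boot[name], lo_q))
                row[f"{name}_upper"] = float(np.percentile(boot[name], hi_q))
        rows.append(row)
    return pd.DataFrame(rows)


def richness_range_through(occurrences: pd.DataFrame, stages: StageTable) -> pd.Series:
    """Range-through richness: per stage, taxa whose first-last span covers it.

    ``occurrences`` needs columns ``taxon``, ``stage_first``,
    ``stage_last`` (in either age order).
    """
    missing = {"taxon", "stage_first", "stage_last"} - set(occurrences.columns)
    if missing:
        raise ValueError(f"occurrence table lacks columns {sorted(missing)}")
    spans: dict[str, set[int]] = {}
    for r in occurrences.itertuples(index=False):
        i, j = stages.index(str(r.stage_first)), stages.index(str(r.stage_last))
        if i > j:
            i, j = j, i
        prev = spans.setdefault(str(r.taxon), set())
        prev.update(range(i, j + 1))
    counts = np.zeros(len(stages), dtype=int)
    for idx in spans.values():
        lo, hi = min(idx), max(idx)
        counts[lo : hi + 1] += 1
    return pd.Series(counts, index=pd.Index(stages.names, name="stage"), name="richness")
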