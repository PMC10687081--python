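"""Measurement-error validation statistics.

Compares digitisation variability (replicates by one observer, one
specimen digitised by several observers) against natural among-genus
shape variation after a joint superimposition: per-group pairwise
tangent distances, a Kruskal-Wallis rank test on those distances, a
homogeneity-of-multivariate-dispersion test (group mean distance to
group centroid, F statistic, parametric and permutation p values) and
Tukey honest-significant-difference comparisons of the dispersions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist

from .procrustes import GPAResult, gpa, pairwise_distances
from .resample import fix_shapes
from .template import StructureTemplate

__all__ = [
    "DispersionTestResult",
    "ErrorReport",
    "groupwise_pairwise_distances",
    "kruskal_wallis",
    "dispersion_test",
    "error_report",
]


def _coords_matrix(data) -> np.ndarray:
    if isinstance(data, GPAResult):
        return data.flattened()
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected an (n x m) coordinate/score matrix")
    return X


def _group_indices(labels: Sequence[str]) -> dict[str, np.ndarray]:
    labels = [str(l) for l in labels]
    out: dict[str, list[int]] = {}
    for i, l in enumerate(labels):
        out.setdefault(l, []).append(i)
    return {g: np.array(idx) for g, idx in out.items()}


def groupwise_pairwise_distances(
    data,
    labels: Sequence[str],
) -> dict[str, np.ndarray]:
    """All within-group pairwise Euclidean distances, per group.

    ``data`` is a GPA result or an (n x m) matrix; ``labels`` assigns a
    group to each row.  Every group must have at least two members.
    """
    X = _coords_matrix(data)
    if len(labels) != len(X):
        raise ValueError("labels length must match the number of rows")
    groups = _group_indices(labels)
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has a single member")
    return {g: pdist(X[idx]) for g, idx in groups.items()}


def kruskal_wallis(samples: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Kruskal-Wallis rank test with tie correction.

    Returns ``(H, df, p)`` with the p value from the chi-squared upper
    tail on ``groups - 1`` degrees of freedom.  All-equal observations
    give H = 0, p = 1.
    """
    samples = [np.asarray(s, dtype=float).ravel() for s in samples]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for i, s in enumerate(samples):
        if s.size == 0:
            raise ValueError(f"group {i} is empty")
    pooled = np.concatenate(samples)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 observations in total")
    ranks = stats.rankdata(pooled)
    H = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + s.size]
        H += r.sum() ** 2 / s.size
        start += s.size
    H = 12.0 / (N * (N + 1)) * H - 3.0 * (N + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()))
    denom = 1.0 - tie_term / (N**3 - N)
    if denom <= 0.0:  # every observation identical
        return 0.0, len(samples) - 1, 1.0
    H /= denom
    df = len(samples) - 1
    return float(H), df, float(stats.chi2.sf(H, df))


@dataclass
class DispersionTestResult:
    """Homogeneity-of-dispersion test output (PERMDISP-style)."""

    group_dispersions: dict[str, float]
    F: float
    df_between: int
    df_within: int
    p_parametric: float
    p_permutation: float
    n_perm: int
    tukey: pd.DataFrame
    distances: pd.Series = field(repr=False, default=None)


def _anova_f(d: np.ndarray, codes: np.ndarray, k: int) -> float:
    N = d.size
    grand = d.mean()
    ssb = 0.0
    ssw = 0.0
    for g in range(k):
        dg = d[codes == g]
        mg = dg.mean()
        ssb += dg.size * (mg - grand) ** 2
        ssw += ((dg - mg) ** 2).sum()
    if ssw <= 0.0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (N - k))


def dispersion_test(
    data,
    labels: Sequence[str],
    *,
    n_perm: int = 9999,
    seed: int,
) -> DispersionTestResult:
    """Test homogeneity of multivariate dispersion across groups.

    Each observation's Euclidean distance to its own group centroid is
    computed in the full coordinate/score space; a one-way ANOVA F on
    these distances gives the statistic.  The permutation p value
    shuffles group labels ``n_perm`` times (seeded) and counts permuted
    F >= observed with add-one correction.  A Tukey HSD table on the
    same distances identifies which group pairs differ (family-wise
    95% intervals).
    """
    X = _coords_matrix(data)
    if len(labels) != len(X):
        raise ValueError("labels length must match the number of rows")
    groups = _group_indices(labels)
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for g, idx in groups.items():
        if len(idx) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 members")

    codes = np.empty(len(X), dtype=int)
    for gi, g in enumerate(names):
        codes[groups[g]] = gi
    d = np.empty(len(X))
    for gi, g in enumerate(names):
        idx = groups[g]
        centroid = X[idx].mean(axis=0)
        d[idx] = np.linalg.norm(X[idx] - centroid, axis=1)

    k = len(names)
    N = len(X)
    F_obs = _anova_f(d, codes, k)
    p_param = float(stats.f.sf(F_obs, k - 1, N - k)) if np.isfinite(F_obs) else 0.0

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(codes)
        if _anova_f(d, perm, k) >= F_obs:
            hits += 1
    p_perm = (hits + 1) / (n_perm + 1)

    res = stats.tukey_hsd(*[d[groups[g]] for g in names])
    ci = res.confidence_interval(confidence_level=0.95)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_1": names[j],
                    "group_2": names[i],
                    "difference": float(res.statistic[j, i]),
                    "lower": float(ci.low[j, i]),
                    "upper": float(ci.high[j, i]),
                    "p_adjusted": float(res.pvalue[j, i]),
                }
            )
    tukey = pd.DataFrame(rows, columns=["group_1", "group_2", "difference", "lower", "upper", "p_adjusted"])

    return DispersionTestResult(
        group_dispersions={g: float(d[groups[g]].mean()) for g in names},
        F=float(F_obs),
        df_between=k - 1,
        df_within=N - k,
        p_parametric=p_param,
        p_permutation=float(p_perm),
        n_perm=n_perm,
        tukey=tukey,
        distances=pd.Series(d, index=[str(l) for l in labels]),
    )


@dataclass
class ErrorReport:
    """Comparative digitisation-error report across groups."""

    group_mean_distances: dict[str, float]
    reference_group: str
    ratios_to_reference: dict[str, float]
    kruskal_H: float
    kruskal_df: int
    kruskal_p: float
    dispersion: DispersionTestResult
    landmark_only_means: dict[str, float] | None = None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "group": g,
                "mean_pairwise_distance": m,
                "ratio_reference_over_group": self.ratios_to_reference[g],
            }
            for g, m in self.group_mean_distances.items()
        ]
        return pd.DataFrame(rows)


def error_report(
    groups: Mapping[str, Sequence],
    reference: str,
    template: StructureTemplate,
    k_per_curve: Sequence[int],
    *,
    n_perm: int = 999,
    seed: int = 0,
    landmark_only: bool = False,
) -> ErrorReport:
    """Full measurement-error comparison over labelled configuration groups.

    All configurations are resampled and superimposed jointly; pairwise
    tangent distances are summarised per group, with ratios of the
    reference (among-genus) group's mean to each error group's mean,
    a Kruskal-Wallis test across the per-group distance distributions
    and a dispersion homogeneity test with permutation inference.

    With ``landmark_only`` the among-observer-style comparison is also
    run on the fixed landmarks alone (no semilandmarks), reporting each
    group's mean pairwise distance under both configurations.
    """
    if reference not in groups:
        raise KeyError(f"reference group {reference!r} not among groups")
    configs: list = []
    labels: list[str] = []
    for g, cfgs in groups.items():
        for c in cfgs:
            configs.append(c)
            labels.append(g)

    def run(include_curves: bool):
        ids = [f"{lab}//{i}" for i, lab in enumerate(labels)]
        renamed = []
        for c, new_id in zip(configs, ids):
            from dataclasses import replace

            renamed.append(replace(c, specimen_id=new_id))
        arr, excl = fix_shapes(
            renamed, template, k_per_curve, policy="drop_specimen",
            include_curves=include_curves,
        )
        if excl:
            raise ValueError(
                "configurations failed the homogeneity check: "
                + "; ".join(f"{e.specimen_id}: {e.reason}" for e in excl)
            )
        result = gpa(arr)
        kept_labels = [sid.split("//")[0] for sid in result.specimen_ids]
        return result, kept_labels

    result, kept_labels = run(include_curves=True)
    dists = groupwise_pairwise_distances(result, kept_labels)
    means = {g: float(v.mean()) for g, v in dists.items()}
    ref_mean = means[reference]
    ratios = {g: (ref_mean / m if m > 0 else np.inf) for g, m in means.items()}
    H, df, p = kruskal_wallis([dists[g] for g in dists])
    disp = dispersion_test(result, kept_labels, n_perm=n_perm, seed=seed)

    lm_only_means = None
    if landmark_only:
        lm_result, lm_labels = run(include_curves=False)
        lm_dists = groupwise_pairwise_distances(lm_result, lm_labels)
        lm_only_means = {g: float(v.mean()) for g, v in lm_dists.items()}

    return ErrorReport(
        group_mean_distances=means,
        reference_group=reference,
        ratios_to_reference=ratios,
        kruskal_H=H,
        kruskal_df=df,
        kruskal_p=p,
        dispersion=disp,
        landmark_only_means=lm_only_means,
    )
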