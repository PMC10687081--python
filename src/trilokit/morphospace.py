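"""Covariance-based PCA of aligned shapes and virtual-shape reconstruction."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .procrustes import GPAResult

__all__ = ["Morphospace", "pca", "reconstruct_shape", "occupancy_grid", "plot_morphospace"]

_RANK_TOL = 1e-12  # relative eigenvalue cutoff for noise axes


@dataclass
class Morphospace:
    """PC scores, axes and eigenvalues of the aligned-shape covariance.

    ``scores`` is (n specimens x m components), ``eigenvectors`` is
    (2p x m) with unit columns, ``mean_flat`` the flattened consensus
    of the sample.  Supports reconstruction of a shape at an arbitrary
    score vector.
    """

    scores: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mean_flat: np.ndarray
    variance_explained: np.ndarray
    specimen_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @property
    def n_points(self) -> int:
        return len(self.mean_flat) // 2

    def scores_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores,
            index=pd.Index(self.specimen_ids, name="specimen_id"),
            columns=[f"PC{i + 1}" for i in range(self.n_components)],
        )


def pca(result: GPAResult) -> Morphospace:
    """Principal component analysis of the covariance of aligned coordinates.

    Components with eigenvalue below ``1e-12`` times the largest are
    dropped.  Eigenvector signs are fixed by making each column's
    largest-magnitude entry positive, so scores are deterministic
    across runs and platforms.
    """
    X = result.flattened()
    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 specimens for a morphospace")
    mean_flat = X.mean(axis=0)
    Xc = X - mean_flat
    # SVD of the centred data matrix <=> eigendecomposition of the covariance
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    eigenvalues = s**2 / (n - 1)
    if eigenvalues.size and eigenvalues[0] > 0:
        keep = eigenvalues > _RANK_TOL * eigenvalues[0]
    else:
        keep = np.zeros_like(eigenvalues, dtype=bool)
    eigenvalues = eigenvalues[keep]
    vectors = Vt[keep].T
    scores = Xc @ vectors
    for j in range(vectors.shape[1]):
        if vectors[np.argmax(np.abs(vectors[:, j])), j] < 0:
            vectors[:, j] = -vectors[:, j]
            scores[:, j] = -scores[:, j]
    total_var = float(Xc.var(axis=0, ddof=1).sum()) if n > 1 else 0.0
    explained = eigenvalues / total_var if total_var > 0 else np.zeros_like(eigenvalues)
    return Morphospace(
        scores=scores,
        eigenvectors=vectors,
        eigenvalues=eigenvalues,
        mean_flat=mean_flat,
        variance_explained=explained,
        specimen_ids=list(result.specimen_ids),
    )


def reconstruct_shape(space: Morphospace, score_vector) -> np.ndarray:
    """Virtual shape at a score vector: mean + sum of scaled eigenvectors.

    The vector may be shorter than the number of components; trailing
    scores are taken as zero.  Returns a (p, 2) configuration.
    """
    s = np.asarray(score_vector, dtype=float).ravel()
    if s.size > space.n_components:
        raise ValueError(
            f"score vector has {s.size} entries but the space has "
            f"{space.n_components} components"
        )
    flat = space.mean_flat + space.eigenvectors[:, : s.size] @ s
    return flat.reshape(-1, 2)


def occupancy_grid(
    space: Morphospace,
    groups: Mapping[str, Iterable[str] | str],
) -> pd.DataFrame:
    """Presence/absence of every specimen in every interval.

    ``groups`` maps specimen id to the interval(s) it occupies.  The
    result has one row per (interval, specimen) over the union of both,
    supporting present/absent morphospace plots per time bin.
    """
    known = set(space.specimen_ids)
    unknown = set(groups) - known
    if unknown:
        raise KeyError(f"unknown specimens in interval map: {sorted(unknown)}")
    membership: dict[str, set[str]] = {}
    intervals: list[str] = []
    for spec_id, bins in groups.items():
        if isinstance(bins, str):
            bins = [bins]
        for b in bins:
            if b not in membership:
                membership[b] = set()
                intervals.append(b)
            membership[b].add(spec_id)
    rows = [
        {"interval": b, "specimen_id": sid, "present": sid in membership[b]}
        for b in intervals
        for sid in space.specimen_ids
    ]
    return pd.DataFrame(rows, columns=["interval", "specimen_id", "present"])


def plot_morphospace(space: Morphospace, path, *, groups: Mapping[str, str] | None = None):
    """Scatter of PC1 x PC2 saved to ``path`` (SVG/PNG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    xs, ys = space.scores[:, 0], space.scores[:, 1] if space.n_components > 1 else np.zeros(len(space.scores))
    if groups:
        labels = [groups.get(sid, "?") for sid in space.specimen_ids]
        for g in sorted(set(labels)):
            sel = [i for i, l in enumerate(labels) if l == g]
            ax.scatter(xs[sel], ys[sel], label=g, s=18)
        ax.legend(fontsize=8)
    else:
        ax.scatter(xs, ys, s=18, color="tab:blue")
    ve = space.variance_explained
    ax.set_xlabel(f"PC1 ({100 * ve[0]:.1f}%)")
    if space.n_components > 1:
        ax.set_ylabel(f"PC2 ({100 * ve[1]:.1f}%)")
    ax.axhline(0, lw=0.5, color="grey")
    ax.axvline(0, lw=0.5, color="grey")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
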