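"""Ordinary and generalised Procrustes superimposition in two dimensions.

Configurations are centred and (by default) scaled to unit centroid
size; rotations are restricted to proper rotations because specimens
are digitised on a consistent (right) side.  Generalised alignment
iterates rotation onto a running consensus until the consensus is
stable.  Downstream statistics use Euclidean distances between aligned
pre-shapes (the tangent-space approximation); exact two-shape
distances are available through :func:`opa`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .resample import ShapeArray

__all__ = [
    "GPAResult",
    "centroid_size",
    "opa",
    "gpa",
    "procrustes_distance",
    "pairwise_distances",
]

logger = logging.getLogger(__name__)


def centroid_size(config: np.ndarray) -> float:
    """Square root of summed squared deviations of points from their centroid."""
    X = np.asarray(config, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2 or len(X) < 2:
        raise ValueError("configuration must be a (p >= 2, 2) array")
    if not np.isfinite(X).all():
        raise ValueError("configuration must be finite")
    size = float(np.linalg.norm(X - X.mean(axis=0)))
    if size <= 0.0:
        raise ValueError("zero-size configuration: all points identical")
    return size


def _preshape(X: np.ndarray, scale: bool = True) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    return Xc / centroid_size(X) if scale else Xc


def _optimal_rotation(source: np.ndarray, target: np.ndarray, allow_reflection: bool) -> np.ndarray:
    """Rotation R minimising ||source @ R - target||_F (both centred)."""
    M = source.T @ target
    U, _, Vt = np.linalg.svd(M)
    R = U @ Vt
    if not allow_reflection and np.linalg.det(R) < 0:
        R = U @ np.diag([1.0, -1.0]) @ Vt
    return R


def opa(
    A: np.ndarray,
    B: np.ndarray,
    allow_reflection: bool = False,
) -> tuple[np.ndarray, float]:
    """Ordinary Procrustes superimposition of two configurations.

    Both inputs are centred and scaled to unit centroid size; the
    returned rotation ``R`` minimises ``||A_hat - B_hat @ R||`` over
    proper rotations (reflections admitted only on request), and the
    returned distance is that minimised Frobenius norm.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch: {A.shape} vs {B.shape}")
    if A.ndim != 2 or A.shape[1] != 2 or len(A) < 3:
        raise ValueError("configurations must be (p >= 3, 2) arrays")
    Ah = _preshape(A)
    Bh = _preshape(B)
    R = _optimal_rotation(Bh, Ah, allow_reflection)
    # direct norm, not sqrt(2 - 2 tr): well conditioned near zero distance
    return R, float(np.linalg.norm(Ah - Bh @ R))


def procrustes_distance(A: np.ndarray, B: np.ndarray, allow_reflection: bool = False) -> float:
    """Two-shape Procrustes distance (see :func:`opa`); symmetric."""
    return opa(A, B, allow_reflection=allow_reflection)[1]


@dataclass
class GPAResult:
    """Aligned pre-shapes, consensus, original sizes and convergence info."""

    aligned: np.ndarray  # (p, 2, n)
    consensus: np.ndarray  # (p, 2)
    centroid_sizes: np.ndarray  # (n,)
    iterations: int
    final_delta: float
    converged: bool
    specimen_ids: list[str]
    scaled: bool = True

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[2]

    @property
    def n_points(self) -> int:
        return self.aligned.shape[0]

    def flattened(self) -> np.ndarray:
        """Aligned coordinates as an (n, 2p) matrix, rows x1 y1 x2 y2 ..."""
        p, _, n = self.aligned.shape
        return self.aligned.transpose(2, 0, 1).reshape(n, 2 * p)


def gpa(
    shapes: ShapeArray | np.ndarray,
    *,
    scale: bool = True,
    tol: float = 1e-8,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> GPAResult:
    """Generalised Procrustes superimposition of ``n >= 2`` configurations.

    The consensus is initialised from the pre-shape of the
    lexicographically first specimen id (removing input-order
    nondeterminism), every pre-shape is rotated onto it, and the
    consensus is recomputed as the renormalised coordinate-wise mean
    until its change drops below ``tol``.
    """
    if isinstance(shapes, ShapeArray):
        coords = shapes.coords
        ids = list(shapes.specimen_ids)
    else:
        coords = np.asarray(shapes, dtype=float)
        if coords.ndim != 3 or coords.shape[1] != 2:
            raise ValueError("expected a (points, 2, specimens) array")
        ids = [str(i) for i in range(coords.shape[2])]
    n = coords.shape[2]
    if n < 2:
        raise ValueError("generalised alignment needs at least 2 specimens")
    if not np.isfinite(coords).all():
        raise ValueError("aligned input must not contain missing points")

    sizes = np.array([centroid_size(coords[:, :, i]) for i in range(n)])
    pre = np.stack([_preshape(coords[:, :, i], scale=scale) for i in range(n)], axis=2)

    first = ids.index(min(ids))
    consensus = pre[:, :, first].copy()
    if scale:
        consensus /= np.linalg.norm(consensus)

    aligned = np.empty_like(pre)
    iterations = 0
    delta = np.inf
    for iterations in range(1, max_iter + 1):
        for i in range(n):
            R = _optimal_rotation(pre[:, :, i], consensus, allow_reflection)
            aligned[:, :, i] = pre[:, :, i] @ R
        new_consensus = aligned.mean(axis=2)
        new_consensus -= new_consensus.mean(axis=0)
        if scale:
            new_consensus /= np.linalg.norm(new_consensus)
        delta = float(np.linalg.norm(new_consensus - consensus))
        consensus = new_consensus
        if delta < tol:
            break
    converged = delta < tol
    if not converged:
        logger.warning(
            "generalised alignment did not converge after %d iterations (delta=%.3g)",
            max_iter,
            delta,
        )
    return GPAResult(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        iterations=iterations,
        final_delta=delta,
        converged=converged,
        specimen_ids=ids,
        scaled=scale,
    )


def pairwise_distances(result: GPAResult) -> np.ndarray:
    """Symmetric matrix of Euclidean (tangent-space) distances between
    aligned pre-shapes; zero diagonal."""
    return squareform(pdist(result.flattened()))
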