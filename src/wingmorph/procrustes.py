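"""Generalized least-squares Procrustes superimposition.

Configurations are centred, scaled to unit centroid size (partial
Procrustes) and rotated to a consensus that is re-estimated each
iteration. Rotations come from the closed-form orthogonal solution via
SVD of the cross-covariance matrix, with the determinant sign-corrected
so reflections are blocked unless explicitly allowed. The residual
coordinates after superimposition are pure shape; flattened, they are the
feature space for the downstream ordination and PERMANOVA stages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import LandmarkConfiguration


@dataclass
class AlignedShapeSet:
    """Result of a generalized Procrustes fit.

    Attributes
    ----------
    coords : ndarray (n, k, 2)
        Aligned, dimensionless Procrustes coordinates; each configuration
        is centred at the origin with unit centroid size.
    consensus : ndarray (k, 2)
        Mean shape (unit centroid size).
    centroid_sizes : ndarray (n,)
        Original centroid sizes in mm, the scale removed by the fit.
    specimen_ids : list of str
    iterations_run : int
    converged : bool
    """

    coords: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list
    iterations_run: int
    converged: bool

    @property
    def n(self) -> int:
        return self.coords.shape[0]

    @property
    def k(self) -> int:
        return self.coords.shape[1]


def centroid_size(coords: np.ndarray) -> float:
    """√(Σ squared distances of landmarks to their centroid)."""
    coords = np.asarray(coords, dtype=float)
    centered = coords - coords.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def normalize(config) -> tuple[np.ndarray, float]:
    """Centre a configuration and scale it to unit centroid size.

    Accepts a :class:`~wingmorph.data_model.LandmarkConfiguration` or a
    bare ``(k, 2)`` array. Returns ``(unit_coords, centroid_size_mm)``.
    """
    coords = config.coords if isinstance(config, LandmarkConfiguration) else config
    coords = np.asarray(coords, dtype=float)
    if coords.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    centered = coords - coords.mean(axis=0)
    size = float(np.sqrt(np.sum(centered**2)))
    if size == 0.0:
        raise ValueError("degenerate configuration: all landmarks coincide")
    return centered / size, size


def reflect(coords: np.ndarray) -> np.ndarray:
    """Mirror a configuration about the y axis (negate x). Involutive."""
    coords = np.asarray(coords, dtype=float)
    out = coords.copy()
    out[:, 0] = -out[:, 0]
    return out


def optimal_rotation(
    source: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> np.ndarray:
    """Least-squares orthogonal matrix R minimising ‖source·R − target‖.

    Determinant is forced to +1 (pure rotation) unless ``allow_reflection``.
    """
    u, _, vt = np.linalg.svd(source.T @ target)
    r = u @ vt
    if not allow_reflection and np.linalg.det(r) < 0:
        u[:, -1] *= -1
        r = u @ vt
    return r


def align_pair(
    source: np.ndarray, target: np.ndarray, allow_reflection: bool = False
) -> tuple[np.ndarray, float]:
    """Rotate ``source`` onto ``target``; both must be normalized.

    Returns the rotated source and the Procrustes distance
    √(Σ squared landmark differences) after the fit.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError(
            f"landmark count mismatch: {source.shape} vs {target.shape}"
        )
    r = optimal_rotation(source, target, allow_reflection=allow_reflection)
    rotated = source @ r
    distance = float(np.sqrt(np.sum((rotated - target) ** 2)))
    return rotated, distance


def gpa(
    configs: Sequence,
    tol: float = 1e-10,
    max_iter: int = 100,
    reflect_left: bool = True,
) -> AlignedShapeSet:
    """Generalized least-squares Procrustes superimposition.

    All configurations are normalized (centred, unit centroid size), left
    wings are mirrored into right-wing orientation when ``reflect_left``,
    and each is rotated to the running consensus, which is recomputed and
    re-normalized until its root-mean-square change drops below ``tol``
    or ``max_iter`` is reached (then ``converged=False``; no exception).
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    ids = []
    raw = []
    for i, cfg in enumerate(configs):
        if isinstance(cfg, LandmarkConfiguration):
            coords = cfg.coords
            if reflect_left and cfg.side == "left":
                coords = reflect(coords)
            ids.append(cfg.specimen_id)
        else:
            coords = np.asarray(cfg, dtype=float)
            ids.append(str(i))
        raw.append(coords)
    ks = {c.shape[0] for c in raw}
    if len(ks) != 1:
        raise ValueError(f"configurations disagree on landmark count: {sorted(ks)}")

    normalized = []
    sizes = np.empty(len(raw))
    for i, coords in enumerate(raw):
        unit, size = normalize(coords)
        normalized.append(unit)
        sizes[i] = size
    aligned = np.stack(normalized)

    consensus = aligned[0].copy()
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        for i in range(aligned.shape[0]):
            aligned[i], _ = align_pair(aligned[i], consensus)
        new_consensus = aligned.mean(axis=0)
        new_consensus, _ = normalize(new_consensus)
        change = float(np.sqrt(np.mean((new_consensus - consensus) ** 2)))
        consensus = new_consensus
        if change < tol:
            converged = True
            break
    # final pass so every configuration is aligned to the final consensus
    for i in range(aligned.shape[0]):
        aligned[i], _ = align_pair(aligned[i], consensus)

    return AlignedShapeSet(
        coords=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=ids,
        iterations_run=iterations,
        converged=converged,
    )


def procrustes_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Partial Procrustes distance between two raw configurations."""
    ua, _ = normalize(a)
    ub, _ = normalize(b)
    _, d = align_pair(ua, ub)
    return d


def align_to_consensus(
    config, consensus: np.ndarray, reflect_left: bool = True
) -> np.ndarray:
    """Ordinary superimposition of one configuration onto a frozen consensus.

    Used when diagnosing queries against a reference library: the library
    consensus never moves, so library features are unchanged by queries.
    """
    if isinstance(config, LandmarkConfiguration):
        coords = config.coords
        if reflect_left and config.side == "left":
            coords = reflect(coords)
    else:
        coords = np.asarray(config, dtype=float)
    if coords.shape[0] != consensus.shape[0]:
        raise ValueError(
            f"landmark count mismatch: query has k={coords.shape[0]}, "
            f"consensus has k={consensus.shape[0]}"
        )
    unit, _ = normalize(coords)
    rotated, _ = align_pair(unit, consensus)
    return rotated


def tangent_project(aligned: AlignedShapeSet, project: bool = False) -> np.ndarray:
    """Flatten aligned coordinates into an (n, 2k) feature matrix.

    By default rows are the untransformed Procrustes coordinates, so
    pairwise Euclidean distances between rows equal Procrustes residual
    distances. With ``project=True`` rows are orthogonally projected onto
    the tangent space at the consensus (component along the consensus
    direction removed from each residual).
    """
    flat = aligned.coords.reshape(aligned.n, -1)
    if not project:
        return flat.copy()
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    residuals = flat - aligned.consensus.reshape(-1)
    return residuals - np.outer(residuals @ c, c)
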