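"""Procrustes superimposition of landmark configurations.

Implements the standard geometric-morphometric toolchain: centroid size,
ordinary (pairwise) Procrustes analysis by SVD, iterative generalized
Procrustes analysis (GPA) with a full-Procrustes fit (scaling inside the
fit, reflections disallowed), orthogonal projection to the tangent space at
the consensus, and full/partial Procrustes distances.

Conventions follow the defaults of the mainstream morphometrics programs:
configurations are centered and scaled to unit centroid size before
fitting, the consensus is rescaled to unit centroid size each iteration,
and the final consensus is aligned to its principal axes so the output
orientation is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landmark_io import LandmarkDataset


class DegenerateShapeError(ValueError):
    """All landmarks coincident or cross-product rank 0."""


def centroid_size(config: np.ndarray) -> float:
    """Square root of the summed squared distances of landmarks from their
    centroid — the standard size measure in geometric morphometrics.

    Translation- and rotation-invariant; scales linearly under isotropic
    scaling.
    """
    config = np.asarray(config, dtype=float)
    if config.shape[0] < 3:
        raise ValueError("need at least 3 landmarks")
    centered = config - config.mean(axis=0)
    cs = float(np.sqrt((centered**2).sum()))
    if cs <= 0.0:
        raise DegenerateShapeError("all landmarks coincident: centroid size 0")
    return cs


def _center(config: np.ndarray) -> np.ndarray:
    return config - config.mean(axis=0)


def _preshape(config: np.ndarray) -> np.ndarray:
    """Center and scale to unit centroid size."""
    c = _center(np.asarray(config, dtype=float))
    return c / centroid_size(config)


def opa_align(
    target: np.ndarray,
    reference: np.ndarray,
    *,
    allow_reflection: bool = False,
    scale: bool = True,
) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Ordinary Procrustes superimposition of ``target`` onto ``reference``.

    Both configurations are centered internally.  The least-squares optimal
    rotation comes from the SVD of the cross-product matrix; when
    reflections are disallowed the smallest singular value's sign is flipped
    if the rotation would otherwise have determinant −1.

    Returns ``(aligned_target, rotation, beta, d_full)`` where ``aligned =
    beta * centered_target @ rotation`` and ``d_full`` is the full
    Procrustes distance between the two shapes (computed on unit-size
    preshapes, independent of the input sizes).
    """
    x = _preshape(reference)
    y = _preshape(target)
    a = x.T @ y  # 2x2 cross-product
    u, s, vt = np.linalg.svd(a)
    if np.allclose(s, 0.0):
        raise DegenerateShapeError("rank-0 cross-product: alignment undefined")
    sign = np.ones(2)
    if not allow_reflection and np.linalg.det(u @ vt) < 0:
        sign[-1] = -1.0
    rotation = (vt.T * sign) @ u.T  # maps y onto x
    gamma = float((s * sign).sum())  # = trace of rotated cross-product
    # full Procrustes distance between the two *shapes*
    d_full = float(np.sqrt(max(0.0, 1.0 - min(gamma, 1.0) ** 2)))
    y_cent = _center(np.asarray(target, dtype=float))
    beta = gamma * centroid_size(reference) / centroid_size(target) if scale else 1.0
    aligned = beta * y_cent @ rotation
    return aligned, rotation, beta, d_full


def procrustes_distance(
    shape_a: np.ndarray, shape_b: np.ndarray, *, kind: str = "full"
) -> float:
    """Procrustes distance between two configurations.

    ``kind='full'`` gives the full Procrustes distance
    sin(ρ) = sqrt(1 − cos²ρ); ``kind='partial'`` gives the partial distance
    sqrt(2 − 2 cos ρ), where cos ρ is the sum of the (reflection-corrected)
    singular values of the preshape cross-product.  Both are symmetric and
    zero iff the shapes are similarity-equivalent.
    """
    x = _preshape(shape_a)
    y = _preshape(shape_b)
    s = np.linalg.svd(x.T @ y, compute_uv=False)
    det = np.linalg.det(x.T @ y)
    cos_rho = s[0] + (s[1] if det >= 0 else -s[1])
    cos_rho = min(cos_rho, 1.0)
    if kind == "full":
        return float(np.sqrt(max(0.0, 1.0 - cos_rho**2)))
    if kind == "partial":
        return float(np.sqrt(max(0.0, 2.0 - 2.0 * cos_rho)))
    raise ValueError(f"unknown distance kind {kind!r}")


@dataclass
class AlignedDataset:
    """Result of generalized Procrustes superimposition.

    ``aligned`` is (n, k, 2); ``consensus`` has unit centroid size; labels
    and exclusion flags are carried over from the input dataset.
    """

    aligned: np.ndarray
    consensus: np.ndarray
    centroid_sizes: np.ndarray
    specimen_ids: list[str]
    n_iterations: int
    converged: bool
    group_of: dict[str, str] = field(default_factory=dict)
    species_of: dict[str, str] = field(default_factory=dict)
    excluded_from_stats: set[str] = field(default_factory=set)
    fit_history: list[float] = field(default_factory=list)  # residual SS per iteration

    @property
    def n_specimens(self) -> int:
        return self.aligned.shape[0]

    @property
    def n_landmarks(self) -> int:
        return self.aligned.shape[1]

    def shape_variables(self, *, tangent: bool = True) -> np.ndarray:
        """Flattened (n, 2k) shape variables, tangent-projected by default."""
        flat = self.aligned.reshape(self.n_specimens, -1)
        if not tangent:
            return flat
        return tangent_project(self)

    def populations(self) -> np.ndarray:
        return np.array([self.group_of[i] for i in self.specimen_ids])

    def species(self) -> np.ndarray:
        return np.array([self.species_of[i] for i in self.specimen_ids])

    def included_mask(self) -> np.ndarray:
        return np.array([i not in self.excluded_from_stats for i in self.specimen_ids])


def _principal_axis_rotation(consensus: np.ndarray) -> np.ndarray:
    """Proper rotation aligning the consensus to its principal axes with a
    deterministic sign convention (largest-spread axis → x, landmark of
    largest |x| has x > 0)."""
    c = _center(consensus)
    cov = c.T @ c
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    r = evecs[:, order]
    if np.linalg.det(r) < 0:
        r[:, 1] *= -1.0
    rotated = c @ r
    anchor = np.argmax(np.abs(rotated[:, 0]))
    if rotated[anchor, 0] < 0:
        r = r @ np.diag([-1.0, -1.0])  # rotate by pi, stays proper
    return r


def gpa(
    dataset: LandmarkDataset,
    *,
    tol: float = 1e-10,
    max_iter: int = 100,
    allow_reflection: bool = False,
) -> AlignedDataset:
    """Generalized Procrustes analysis.

    Iteratively aligns every configuration to a provisional consensus
    (full-Procrustes fit: translation, rotation and scale), recomputes the
    consensus as the arithmetic mean rescaled to unit centroid size, and
    stops when the root-mean-square change of the consensus falls below
    ``tol``.  The consensus is initialized from the first specimen, and the
    final fit is rotated so the consensus sits on its principal axes, making
    the output orientation deterministic.

    Non-convergence within ``max_iter`` sets ``converged=False`` (a warning
    flag, not an exception).
    """
    raw = dataset.coords_array()
    n = raw.shape[0]
    sizes = np.array([centroid_size(c) for c in raw])
    aligned = np.stack([_preshape(c) for c in raw])

    consensus = aligned[0].copy()
    n_iter = 0
    converged = n == 1
    fit_history: list[float] = []
    for n_iter in range(1, max_iter + 1):
        for i in range(n):
            aligned[i] = opa_align(aligned[i], consensus, allow_reflection=allow_reflection)[0]
        new_consensus = aligned.mean(axis=0)
        new_consensus = _preshape(new_consensus)
        drift = np.sqrt(((new_consensus - consensus) ** 2).mean())
        consensus = new_consensus
        fit_history.append(float(((aligned - consensus) ** 2).sum()))
        if drift < tol:
            converged = True
            break

    rot = _principal_axis_rotation(consensus)
    consensus = _center(consensus) @ rot
    aligned = aligned @ rot

    return AlignedDataset(
        aligned=aligned,
        consensus=consensus,
        centroid_sizes=sizes,
        specimen_ids=dataset.specimen_ids,
        n_iterations=n_iter,
        converged=converged,
        group_of=dict(dataset.group_of),
        species_of=dict(dataset.species_of),
        excluded_from_stats=set(dataset.excluded_from_stats),
        fit_history=fit_history,
    )


def tangent_project(aligned: AlignedDataset) -> np.ndarray:
    """Orthogonally project aligned coordinates onto the tangent space at
    the consensus.

    With the flattened consensus ``c`` scaled to unit norm, each flattened
    specimen ``x`` maps to ``x + (1 − x·c) c``, the orthogonal projection
    onto the hyperplane tangent to the unit preshape sphere at ``c``.  The
    consensus is a fixed point; for small shape variation the projection is
    a first-order identity.  Output is (n, 2k) with 4 constrained degrees
    of freedom (2 translation, 1 scale, 1 rotation).
    """
    c = aligned.consensus.reshape(-1)
    c = c / np.linalg.norm(c)
    x = aligned.aligned.reshape(aligned.n_specimens, -1)
    proj = x + np.outer(1.0 - x @ c, c)
    return proj
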