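"""Thin-plate-spline deformation grids for visualizing shape change.

The classic transformation-grid display: a thin-plate spline (kernel
U(r) = r² log r²) is fitted so that it maps the consensus landmarks exactly
onto a target shape — typically the consensus displaced along a canonical
axis by a scale factor — and a regular grid over the consensus is pushed
through the warp.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cva import CVAResult


class SingularWarpError(ValueError):
    """Source landmarks collinear: TPS system singular."""


def _tps_kernel(r2: np.ndarray) -> np.ndarray:
    # U(r) = r^2 log r^2, with U(0) = 0
    out = np.zeros_like(r2)
    nz = r2 > 0
    out[nz] = r2[nz] * np.log(r2[nz])
    return out


@dataclass
class TPSWarp:
    """Fitted thin-plate-spline interpolant from source to target landmarks."""

    source_landmarks: np.ndarray  # (k, 2)
    affine_part: np.ndarray  # (3, 2): rows constant, x, y
    nonaffine_weights: np.ndarray  # (k, 2)
    bending_energy: float

    def __call__(self, points: np.ndarray) -> np.ndarray:
        """Map (m, 2) points through the warp."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((pts[:, None, :] - self.source_landmarks[None, :, :]) ** 2).sum(axis=2)
        u = _tps_kernel(d2)
        affine = self.affine_part[0] + pts @ self.affine_part[1:]
        return affine + u @ self.nonaffine_weights


def fit_tps_warp(source: np.ndarray, target: np.ndarray) -> TPSWarp:
    """Fit the standard thin-plate spline interpolating ``source`` →
    ``target`` by solving the bordered linear system

        [K  P] [w]   [v]
        [Pᵀ 0] [a] = [0]

    with K the kernel matrix and P = [1 | source].  Interpolation at the
    landmarks is exact; the bending energy is wᵀ K w summed over the two
    coordinates, zero iff the map is affine.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ValueError("source and target must both be k x 2")
    k = src.shape[0]
    if k < 3:
        raise ValueError("need at least 3 landmarks")
    svals = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if svals[1] <= 1e-10 * svals[0]:
        raise SingularWarpError("collinear source landmarks: TPS system singular")
    d2 = ((src[:, None, :] - src[None, :, :]) ** 2).sum(axis=2)
    kmat = _tps_kernel(d2)
    p = np.hstack([np.ones((k, 1)), src])
    lmat = np.zeros((k + 3, k + 3))
    lmat[:k, :k] = kmat
    lmat[:k, k:] = p
    lmat[k:, :k] = p.T
    rhs = np.zeros((k + 3, 2))
    rhs[:k] = tgt
    try:
        sol = np.linalg.solve(lmat, rhs)
    except np.linalg.LinAlgError as exc:
        raise SingularWarpError("TPS system singular (collinear source landmarks?)") from exc
    w = sol[:k]
    a = sol[k:]
    bending = float(np.einsum("ic,ij,jc->", w, kmat, w))
    return TPSWarp(
        source_landmarks=src,
        affine_part=a,
        nonaffine_weights=w,
        bending_energy=max(bending, 0.0),
    )


def axis_target_shape(
    cva_result: CVAResult, consensus: np.ndarray, axis: int, scale_factor: float
) -> np.ndarray:
    """Consensus displaced along a canonical axis.

    The axis loading is taken in shape-variable space (the canonical basis
    mapped back through the within-group metric), normalized to unit length
    and applied multiplicatively: target = consensus + scale_factor x unit
    loading reshaped to k x 2.  A zero axis returns the consensus
    unchanged.
    """
    if not 0 <= axis < cva_result.n_axes:
        raise ValueError(f"axis {axis} out of range (m = {cva_result.n_axes})")
    loading = cva_result.cv_axes[:, axis]
    norm = np.linalg.norm(loading)
    cons = np.asarray(consensus, dtype=float)
    if norm == 0:
        return cons.copy()
    return cons + scale_factor * (loading / norm).reshape(cons.shape)


def deformation_grid(
    cva_result: CVAResult,
    consensus: np.ndarray,
    *,
    axis: int = 0,
    scale_factor: float = 15.0,
    grid_density: int = 20,
    padding: float = 0.1,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Warped transformation-grid polylines for shape change along a
    canonical axis.

    A ``grid_density`` x ``grid_density`` regular grid over the consensus
    bounding box (padded 10% by default) is pushed through the TPS warp
    from the consensus to the axis target.  Returns (polylines, warped
    landmarks); with ``scale_factor=0`` the grid is undeformed.
    """
    cons = np.asarray(consensus, dtype=float)
    target = axis_target_shape(cva_result, cons, axis, scale_factor)
    if np.allclose(target, cons):
        warp = lambda pts: np.atleast_2d(pts)  # identity grid for a degenerate axis
        warped_lms = cons.copy()
    else:
        tps = fit_tps_warp(cons, target)
        warp = tps
        warped_lms = tps(cons)

    lo = cons.min(axis=0)
    hi = cons.max(axis=0)
    span = hi - lo
    lo = lo - padding * span
    hi = hi + padding * span
    xs = np.linspace(lo[0], hi[0], grid_density)
    ys = np.linspace(lo[1], hi[1], grid_density)
    polylines: list[np.ndarray] = []
    for x in xs:
        line = np.column_stack([np.full(grid_density * 4, x), np.linspace(lo[1], hi[1], grid_density * 4)])
        polylines.append(warp(line))
    for y in ys:
        line = np.column_stack([np.linspace(lo[0], hi[0], grid_density * 4), np.full(grid_density * 4, y)])
        polylines.append(warp(line))
    return polylines, warped_lms


def plot_deformation_grid(
    cva_result: CVAResult,
    consensus: np.ndarray,
    path: str,
    *,
    axis: int = 0,
    scale_factor: float = 15.0,
    grid_density: int = 20,
) -> None:
    """Render the transformation grid with landmarks to SVG or PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    polylines, warped = deformation_grid(
        cva_result, consensus, axis=axis, scale_factor=scale_factor, grid_density=grid_density
    )
    fig, ax = plt.subplots(figsize=(5, 5))
    for line in polylines:
        ax.plot(line[:, 0], line[:, 1], lw=0.5, color="0.6")
    cons = np.asarray(consensus)
    ax.scatter(cons[:, 0], cons[:, 1], s=18, color="0.3", label="consensus")
    ax.scatter(warped[:, 0], warped[:, 1], s=22, color="crimson", label="warped")
    ax.set_aspect("equal")
    ax.legend(loc="best", fontsize=8)
    ax.set_title(f"CV{axis + 1} deformation, scale factor {scale_factor:g}")
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def plot_cva_scatter(
    cva_result: CVAResult,
    path: str,
    *,
    passive_scores: np.ndarray | None = None,
    passive_labels: list[str] | None = None,
    title: str = "Canonical variates analysis",
) -> None:
    """CV1 x CV2 scatter with group colour coding and optional passively
    projected singleton specimens."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    scores = cva_result.scores
    groups = cva_result.groups
    fig, ax = plt.subplots(figsize=(6, 5))
    y = scores[:, 1] if scores.shape[1] > 1 else np.zeros(scores.shape[0])
    for g in cva_result.group_labels:
        sel = np.asarray(groups).astype(str) == g
        ax.scatter(scores[sel, 0], y[sel], s=25, label=g)
    if passive_scores is not None and len(passive_scores):
        ps = np.atleast_2d(passive_scores)
        py = ps[:, 1] if ps.shape[1] > 1 else np.zeros(ps.shape[0])
        ax.scatter(ps[:, 0], py, marker="x", color="k", s=40, label="singletons")
        if passive_labels:
            for (x0, y0), lab in zip(zip(ps[:, 0], py), passive_labels):
                ax.annotate(lab, (x0, y0), fontsize=7)
    ax.set_xlabel("CV1")
    ax.set_ylabel("CV2")
    ax.legend(fontsize=7)
    ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
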