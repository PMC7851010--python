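"""Canonical variates analysis, Mahalanobis/Procrustes distances with
permutation tests, and leave-one-out classification.

The CVA solves the between-group versus pooled-within-group generalized
eigenproblem after projecting onto the non-null eigenspace of the within
covariance (rank reduction before inversion), which is the behaviour of the
mainstream morphometrics packages and keeps small-sample synthetic cases
well defined.  Mahalanobis distances are Euclidean distances of group means
in the whitened within-group metric; pairwise significance comes from
permuting only the two groups under comparison.  Classification accuracy is
strict leave-one-out: group means *and* the pooled covariance are refit
without the held-out specimen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .superimposition import procrustes_distance

_RANK_TOL = 1e-9


class CVAUndefinedError(ValueError):
    """Within-group covariance has rank 0 or too few specimens."""


def _group_index(groups: np.ndarray) -> tuple[np.ndarray, list[str]]:
    labels = sorted(set(map(str, groups)))
    lut = {g: i for i, g in enumerate(labels)}
    return np.array([lut[str(g)] for g in groups]), labels


def pooled_within_covariance(
    shape_vars: np.ndarray, groups: np.ndarray, *, rank_tol: float = _RANK_TOL
) -> tuple[np.ndarray, int]:
    """Pooled within-group covariance: within-group centered cross-products
    summed over groups, divided by (n − g).  Returns the matrix and its
    effective rank from an eigenvalue census at ``rank_tol`` relative to the
    largest eigenvalue."""
    x = np.asarray(shape_vars, dtype=float)
    idx, labels = _group_index(np.asarray(groups))
    n, g = x.shape[0], len(labels)
    if n - g < 1:
        raise CVAUndefinedError(f"n - g = {n - g} < 1: within covariance underdetermined")
    cross = np.zeros((x.shape[1], x.shape[1]))
    for gi in range(g):
        xg = x[idx == gi]
        cg = xg - xg.mean(axis=0)
        cross += cg.T @ cg
    w = cross / (n - g)
    evals = np.linalg.eigvalsh(w)
    top = evals.max(initial=0.0)
    rank = int((evals > rank_tol * top).sum()) if top > 0 else 0
    return w, rank


def _whitener(w: np.ndarray, *, rank_tol: float = _RANK_TOL) -> np.ndarray:
    """(p, r) matrix T with T' W T = I_r, restricted to the non-null
    eigenspace of W."""
    evals, evecs = np.linalg.eigh(w)
    top = evals.max(initial=0.0)
    if top <= 0.0:
        raise CVAUndefinedError("rank-0 within-group covariance")
    keep = evals > rank_tol * top
    return evecs[:, keep] / np.sqrt(evals[keep])


def mahalanobis_matrix(
    shape_vars: np.ndarray, groups: np.ndarray, *, rank_tol: float = _RANK_TOL
) -> np.ndarray:
    """g x g Mahalanobis distances between group means in the pooled
    within-group metric (rank-reduced)."""
    x = np.asarray(shape_vars, dtype=float)
    idx, labels = _group_index(np.asarray(groups))
    w, _ = pooled_within_covariance(x, groups, rank_tol=rank_tol)
    t = _whitener(w, rank_tol=rank_tol)
    means = np.stack([x[idx == gi].mean(axis=0) for gi in range(len(labels))])
    zm = means @ t
    diff = zm[:, None, :] - zm[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


@dataclass
class CVAResult:
    """Fitted canonical variates analysis over a-priori groups."""

    cv_axes: np.ndarray  # (p, m) loadings in shape-variable space
    eigenvalues: np.ndarray  # (m,)
    scores: np.ndarray  # (n, m)
    group_labels: list[str]
    group_means: np.ndarray  # (g, p)
    grand_mean: np.ndarray  # (p,) weighted by specimens
    mahalanobis: np.ndarray  # (g, g)
    procrustes_dist: np.ndarray | None  # (g, g) between mean shapes
    perm_p_mahalanobis: np.ndarray | None
    perm_p_procrustes: np.ndarray | None
    n_permutations: int
    groups: np.ndarray = field(repr=False, default=None)

    @property
    def n_axes(self) -> int:
        return self.cv_axes.shape[1]


def _pair_permutation_p(
    xa: np.ndarray,
    xb: np.ndarray,
    n_perm: int,
    rng: np.random.Generator,
    *,
    procrustes_kind: str | None,
) -> tuple[float, float | None]:
    """Permutation p-values for the Mahalanobis (and optionally Procrustes)
    distance between two groups, permuting specimens across the pair only.

    The statistic uses the pair's own pooled within-covariance; data are
    first rotated onto the span of the pair-centered observations so the
    pseudo-inverse works in at most n_pair − 1 dimensions.
    """
    pooled = np.vstack([xa, xb])
    na = xa.shape[0]
    n = pooled.shape[0]
    centered = pooled - pooled.mean(axis=0)
    # orthonormal basis of the observed span; Mahalanobis is invariant
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    keep = s > _RANK_TOL * s.max(initial=0.0)
    z = centered @ vt[keep].T

    def mahal(ia: np.ndarray, ib: np.ndarray) -> float:
        za, zb = z[ia], z[ib]
        ca, cb = za - za.mean(axis=0), zb - zb.mean(axis=0)
        w = (ca.T @ ca + cb.T @ cb) / (n - 2)
        evals, evecs = np.linalg.eigh(w)
        top = evals.max(initial=0.0)
        if top <= 0.0:
            return 0.0
        kp = evals > _RANK_TOL * top
        t = evecs[:, kp] / np.sqrt(evals[kp])
        d = (za.mean(axis=0) - zb.mean(axis=0)) @ t
        return float(np.sqrt((d**2).sum()))

    def proc(ia: np.ndarray, ib: np.ndarray) -> float:
        k = pooled.shape[1] // 2
        ma = pooled[ia].mean(axis=0).reshape(k, 2)
        mb = pooled[ib].mean(axis=0).reshape(k, 2)
        return procrustes_distance(ma, mb, kind=procrustes_kind)

    all_idx = np.arange(n)
    obs_m = mahal(all_idx[:na], all_idx[na:])
    obs_p = proc(all_idx[:na], all_idx[na:]) if procrustes_kind else None
    count_m = 0
    count_p = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        ia, ib = perm[:na], perm[na:]
        if mahal(ia, ib) >= obs_m:
            count_m += 1
        if procrustes_kind and proc(ia, ib) >= obs_p:
            count_p += 1
    p_m = (count_m + 1) / (n_perm + 1)
    p_p = (count_p + 1) / (n_perm + 1) if procrustes_kind else None
    return p_m, p_p


def cva(
    shape_vars: np.ndarray,
    groups: np.ndarray,
    *,
    n_perm: int = 10_000,
    seed: int | np.random.Generator | None = None,
    procrustes: bool = True,
    procrustes_kind: str = "full",
    rank_tol: float = _RANK_TOL,
) -> CVAResult:
    """Canonical variates analysis over a-priori groups.

    Axes are eigenvectors of the between-group covariance in the whitened
    within-group metric; scores are scaled so the pooled within-group
    variance is 1 on each axis, and each axis is oriented so the first
    group's mean score is non-positive (canonical axes are otherwise
    sign-indeterminate).  ``n_perm > 0`` adds pairwise permutation p-values
    for the Mahalanobis and (when the variables are flattened k x 2 shapes)
    Procrustes distances, permuting only the pair under comparison.
    """
    x = np.asarray(shape_vars, dtype=float)
    idx, labels = _group_index(np.asarray(groups))
    g = len(labels)
    if g < 2:
        raise CVAUndefinedError("need at least 2 groups")
    counts = np.bincount(idx, minlength=g)
    if counts.min() < 2:
        raise CVAUndefinedError("every group needs n >= 2")
    n = x.shape[0]

    w, _ = pooled_within_covariance(x, groups, rank_tol=rank_tol)
    t = _whitener(w, rank_tol=rank_tol)

    means = np.stack([x[idx == gi].mean(axis=0) for gi in range(g)])
    grand = x.mean(axis=0)
    zm = (means - grand) @ t  # whitened group means
    b = (zm * counts[:, None]).T @ zm / (g - 1)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    m = min(g - 1, t.shape[1])
    evals = np.maximum(evals[order[:m]], 0.0)
    axes_w = evecs[:, order[:m]]  # orthonormal in whitened space
    axes = t @ axes_w  # back to shape-variable space

    scores = (x - grand) @ axes
    mean_scores = (means - grand) @ axes
    flip = np.where(mean_scores[0] > 0, -1.0, 1.0)
    axes *= flip
    scores *= flip
    mean_scores *= flip

    diff = zm[:, None, :] - zm[None, :, :]
    mahal = np.sqrt((diff**2).sum(axis=2))

    k2 = x.shape[1]
    do_proc = procrustes and k2 % 2 == 0 and k2 >= 6
    proc_mat = None
    if do_proc:
        k = k2 // 2
        proc_mat = np.zeros((g, g))
        for i in range(g):
            for j in range(i + 1, g):
                d = procrustes_distance(
                    means[i].reshape(k, 2), means[j].reshape(k, 2), kind=procrustes_kind
                )
                proc_mat[i, j] = proc_mat[j, i] = d

    p_m = p_p = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        p_m = np.zeros((g, g))
        p_p = np.zeros((g, g)) if do_proc else None
        for i in range(g):
            for j in range(i + 1, g):
                pm, pp = _pair_permutation_p(
                    x[idx == i],
                    x[idx == j],
                    n_perm,
                    rng,
                    procrustes_kind=procrustes_kind if do_proc else None,
                )
                p_m[i, j] = p_m[j, i] = pm
                if do_proc:
                    p_p[i, j] = p_p[j, i] = pp

    return CVAResult(
        cv_axes=axes,
        eigenvalues=evals,
        scores=scores,
        group_labels=labels,
        group_means=means,
        grand_mean=grand,
        mahalanobis=mahal,
        procrustes_dist=proc_mat,
        perm_p_mahalanobis=p_m,
        perm_p_procrustes=p_p,
        n_permutations=n_perm,
        groups=np.asarray(groups),
    )


def project_passive(cva_result: CVAResult, extra_specimens: np.ndarray) -> np.ndarray:
    """Scores for specimens that did not take part in fitting (e.g.
    singleton populations shown in plots but excluded from statistics).
    Projection through the fitted axes; has no effect on axes, distances or
    tests."""
    x = np.atleast_2d(np.asarray(extra_specimens, dtype=float))
    if x.shape[1] != cva_result.cv_axes.shape[0]:
        raise ValueError(
            f"dimension mismatch: specimens have {x.shape[1]} variables, "
            f"CVA was fitted on {cva_result.cv_axes.shape[0]}"
        )
    return (x - cva_result.grand_mean) @ cva_result.cv_axes


def mean_offdiagonal(distances: np.ndarray) -> float:
    """Mean of the upper-triangle entries of a symmetric distance matrix."""
    d = np.asarray(distances, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1] or d.shape[0] < 2:
        raise ValueError("need a square matrix with g >= 2")
    iu = np.triu_indices(d.shape[0], k=1)
    return float(d[iu].mean())


def upper_triangle(distances: np.ndarray) -> np.ndarray:
    """Upper-triangle entries of a symmetric matrix as a flat vector."""
    d = np.asarray(distances, dtype=float)
    return d[np.triu_indices(d.shape[0], k=1)]


def compare_distance_means(
    dists_a: np.ndarray, dists_b: np.ndarray, *, equal_var: bool = True
) -> tuple[float, float]:
    """Two-sample t-test on two sets of pairwise distances (pooled-variance
    by default, Welch with ``equal_var=False``).  Returns (t, p)."""
    a = np.asarray(dists_a, dtype=float)
    b = np.asarray(dists_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each set needs at least 2 values")
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        if np.isclose(a[0], b[0]):
            return 0.0, 1.0
        raise ValueError("zero variance in both sets")
    t, p = stats.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


@dataclass
class ClassificationResult:
    """Leave-one-out confusion matrix and percent-correct summaries."""

    group_labels: list[str]
    confusion: np.ndarray  # (g, g) true x assigned counts
    pct_correct_per_group: np.ndarray
    pct_correct_overall: float

    def as_dict(self) -> dict[str, float]:
        d = {g: float(p) for g, p in zip(self.group_labels, self.pct_correct_per_group)}
        d["overall"] = float(self.pct_correct_overall)
        return d


def loo_classify(
    shape_vars: np.ndarray,
    groups: np.ndarray,
    *,
    refit_covariance: bool = True,
    rank_tol: float = _RANK_TOL,
) -> ClassificationResult:
    """Leave-one-out cross-validated classification to the nearest group
    mean in the Mahalanobis metric.

    For each held-out specimen the group means and (by default) the pooled
    within-group covariance are refit without it; the specimen is assigned
    to the group whose mean is closest in the rank-reduced whitened space.
    Deterministic.  ``refit_covariance=False`` keeps the full-data
    covariance (sensitivity option).
    """
    x = np.asarray(shape_vars, dtype=float)
    idx, labels = _group_index(np.asarray(groups))
    g = len(labels)
    if g < 2:
        raise CVAUndefinedError("need at least 2 groups")
    counts = np.bincount(idx, minlength=g)
    if counts.min() < 2:
        raise CVAUndefinedError("every group needs n >= 2 for leave-one-out")
    n = x.shape[0]
    if not refit_covariance:
        w_full, _ = pooled_within_covariance(x, groups, rank_tol=rank_tol)
        t_full = _whitener(w_full, rank_tol=rank_tol)

    confusion = np.zeros((g, g), dtype=int)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        xi, gi = x[mask], idx[mask]
        means = np.stack([xi[gi == a].mean(axis=0) for a in range(g)])
        if refit_covariance:
            w, _ = pooled_within_covariance(xi, gi, rank_tol=rank_tol)
            t = _whitener(w, rank_tol=rank_tol)
        else:
            t = t_full
        d = ((x[i] - means) @ t) ** 2
        assigned = int(np.argmin(d.sum(axis=1)))
        confusion[idx[i], assigned] += 1

    pct_group = 100.0 * np.diag(confusion) / counts
    pct_overall = 100.0 * np.diag(confusion).sum() / n
    return ClassificationResult(
        group_labels=labels,
        confusion=confusion,
        pct_correct_per_group=pct_group,
        pct_correct_overall=float(pct_overall),
    )


def cv_size_correlation(scores_axis: np.ndarray, sizes: np.ndarray) -> float:
    """Pearson correlation between scores on one canonical axis and
    centroid size.  Canonical axes are sign-indeterminate, so |r| is the
    reportable invariant; the fitted axis orientation fixes the sign."""
    s = np.asarray(scores_axis, dtype=float)
    z = np.asarray(sizes, dtype=float)
    if s.size < 3:
        raise ValueError("need at least 3 specimens")
    if np.std(s) == 0 or np.std(z) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(stats.pearsonr(s, z)[0])
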