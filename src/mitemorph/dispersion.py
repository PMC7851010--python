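"""Multivariate dispersion tests, Mantel tests and geographic distances.

The dispersion test is the distance-based homogeneity-of-dispersion
procedure popularized by the vegan package (``betadisper`` +
``permutest``): specimens are embedded by principal coordinates of their
pairwise Euclidean distances, each group's spatial (geometric) median is
found by Weiszfeld iteration, and a one-way ANOVA F on the specimens'
distances to their group median is referred to a permutation distribution
obtained by relabeling specimens.  Axes with negative PCoA eigenvalues
contribute negatively to squared distances (the standard sign-split rule);
for Euclidean inputs, as produced by shape variables, no such axes occur.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

EARTH_RADIUS_KM = 6371.0


@dataclass
class DispersionResult:
    """Distance-to-median dispersion test."""

    group_labels: list[str]
    dist_to_median: np.ndarray  # n distances, specimen order
    group_mean_dispersion: np.ndarray  # g means
    f_stat: float
    perm_p: float
    n_perm: int


@dataclass
class MantelResult:
    """Matrix correlation with row/column permutation null."""

    r: float
    perm_p: float
    n_perm: int


def _pcoa_embed(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinate embedding of a distance matrix.

    Returns (real_axes, imaginary_axes): coordinates on positive- and
    negative-eigenvalue axes; squared inter-point distances are recovered
    as ||Δreal||² − ||Δimag||².
    """
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    evals, evecs = np.linalg.eigh(g)
    tol = 1e-9 * max(abs(evals).max(), 1.0)
    pos = evals > tol
    neg = evals < -tol
    real = evecs[:, pos] * np.sqrt(evals[pos])
    imag = evecs[:, neg] * np.sqrt(-evals[neg])
    return real, imag


def _spatial_median(points: np.ndarray, *, tol: float = 1e-8, max_iter: int = 200) -> np.ndarray:
    """Geometric median by Weiszfeld iteration (with the standard guard for
    iterates landing on a data point)."""
    med = points.mean(axis=0)
    for _ in range(max_iter):
        dist = np.linalg.norm(points - med, axis=1)
        near = dist < 1e-12
        if near.any():
            dist[near] = 1e-12
        w = 1.0 / dist
        new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(new - med) < tol:
            return new
        med = new
    return med


def _distances_to_group_medians(
    real: np.ndarray, imag: np.ndarray, idx: np.ndarray, g: int
) -> np.ndarray:
    """Each specimen's distance to its group's spatial median, with the
    negative-axis sign-split rule (squared imaginary distance subtracts)."""
    out = np.empty(idx.shape[0])
    for a in range(g):
        sel = idx == a
        mr = _spatial_median(real[sel])
        d2 = ((real[sel] - mr) ** 2).sum(axis=1)
        if imag.shape[1]:
            mi = _spatial_median(imag[sel])
            d2 = d2 - ((imag[sel] - mi) ** 2).sum(axis=1)
        out[sel] = np.sqrt(np.clip(d2, 0.0, None))
    return out


def _anova_f(values: np.ndarray, idx: np.ndarray, g: int) -> float:
    n = values.shape[0]
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for a in range(g):
        v = values[idx == a]
        ss_between += v.shape[0] * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    if ss_within <= 0.0:
        return np.inf if ss_between > 0 else 0.0
    return float((ss_between / (g - 1)) / (ss_within / (n - g)))


def dispersion_test(
    shape_vars: np.ndarray,
    groups: np.ndarray,
    *,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> DispersionResult:
    """Permutation test for homogeneity of multivariate dispersions.

    The dispersion of a group is the average distance of its members to the
    group's spatial median in principal-coordinate space; the one-way ANOVA
    F on the member distances is compared with ``n_perm`` random
    relabelings (p with the +1 correction).  Groups of size 1 are dropped
    with a warning entry in the labels.
    """
    x = np.asarray(shape_vars, dtype=float)
    garr = np.asarray(groups).astype(str)
    labels, counts = np.unique(garr, return_counts=True)
    keep_labels = labels[counts >= 2]
    if keep_labels.size < 2:
        raise ValueError("need at least 2 groups with n >= 2")
    mask = np.isin(garr, keep_labels)
    x, garr = x[mask], garr[mask]
    lut = {g: i for i, g in enumerate(keep_labels)}
    idx = np.array([lut[g] for g in garr])
    g = keep_labels.size

    d = squareform(pdist(x))
    real, imag = _pcoa_embed(d)
    dist_med = _distances_to_group_medians(real, imag, idx, g)
    f_obs = _anova_f(dist_med, idx, g)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(idx)
        dist_p = _distances_to_group_medians(real, imag, perm, g)
        if _anova_f(dist_p, perm, g) >= f_obs:
            count += 1
    perm_p = (count + 1) / (n_perm + 1)

    group_disp = np.array([dist_med[idx == a].mean() for a in range(g)])
    return DispersionResult(
        group_labels=list(keep_labels),
        dist_to_median=dist_med,
        group_mean_dispersion=group_disp,
        f_stat=f_obs,
        perm_p=perm_p,
        n_perm=n_perm,
    )


def pairwise_dispersion(
    shape_vars: np.ndarray,
    groups: np.ndarray,
    *,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[list[str], np.ndarray]:
    """Dispersion test for every pair of groups.

    Returns (labels, p-matrix): symmetric, with 1.0 on the diagonal and no
    multiplicity correction (raw pairwise outcomes).
    """
    garr = np.asarray(groups).astype(str)
    labels = [g for g in sorted(set(garr)) if (garr == g).sum() >= 2]
    g = len(labels)
    rng = np.random.default_rng(seed)
    pmat = np.ones((g, g))
    x = np.asarray(shape_vars, dtype=float)
    for i in range(g):
        for j in range(i + 1, g):
            sel = np.isin(garr, [labels[i], labels[j]])
            res = dispersion_test(x[sel], garr[sel], n_perm=n_perm, seed=rng)
            pmat[i, j] = pmat[j, i] = res.perm_p
    return labels, pmat


def great_circle_matrix(latlon: np.ndarray) -> np.ndarray:
    """Haversine great-circle distances (km, Earth radius 6371 km) between
    points given as (lat, lon) decimal-degree pairs."""
    ll = np.asarray(latlon, dtype=float)
    if ll.ndim != 2 or ll.shape[1] != 2:
        raise ValueError("latlon must be g x 2 (lat, lon)")
    if (np.abs(ll[:, 0]) > 90).any() or (np.abs(ll[:, 1]) > 180).any():
        raise ValueError("coordinates out of range")
    lat = np.radians(ll[:, 0])
    lon = np.radians(ll[:, 1])
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = np.sin(dlat / 2) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def mantel_test(
    a: np.ndarray,
    b: np.ndarray,
    *,
    n_perm: int = 9999,
    seed: int | np.random.Generator | None = None,
    alternative: str = "greater",
) -> MantelResult:
    """Mantel test of correlation between two distance matrices.

    Pearson r over the upper triangles; the null permutes the rows and
    columns of ``b`` simultaneously.  ``alternative`` is 'greater'
    (positive association, the default), 'less' or 'two-sided'.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("matrices must be square and of equal size")
    g = a.shape[0]
    if g < 4:
        raise ValueError("need at least 4 objects for a meaningful Mantel test")
    iu = np.triu_indices(g, k=1)
    va = a[iu]
    if np.std(va) == 0 or np.std(b[iu]) == 0:
        raise ValueError("constant distance matrix: correlation undefined")

    def corr(mat: np.ndarray) -> float:
        return float(stats.pearsonr(va, mat[iu])[0])

    r_obs = corr(b)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(g)
        r_p = corr(b[np.ix_(perm, perm)])
        if alternative == "greater":
            hit = r_p >= r_obs
        elif alternative == "less":
            hit = r_p <= r_obs
        else:
            hit = abs(r_p) >= abs(r_obs)
        count += hit
    return MantelResult(r=r_obs, perm_p=(count + 1) / (n_perm + 1), n_perm=n_perm)


def mantel_exhaustive_p(a: np.ndarray, b: np.ndarray, *, alternative: str = "greater") -> float:
    """Exact Mantel p-value by enumerating all g! simultaneous row/column
    permutations (practical only for small g; used as an oracle)."""
    from itertools import permutations

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    g = a.shape[0]
    iu = np.triu_indices(g, k=1)
    va = a[iu]
    r_obs = float(stats.pearsonr(va, b[iu])[0])
    count = 0
    total = 0
    for perm in permutations(range(g)):
        p = np.array(perm)
        r_p = float(stats.pearsonr(va, b[np.ix_(p, p)][iu])[0])
        if alternative == "greater":
            hit = r_p >= r_obs - 1e-12
        elif alternative == "less":
            hit = r_p <= r_obs + 1e-12
        else:
            hit = abs(r_p) >= abs(r_obs) - 1e-12
        count += hit
        total += 1
    return count / total
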