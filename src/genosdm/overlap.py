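"""Niche comparison statistics.

Covers Schoener's D between suitability surfaces, the randomization-based
niche-similarity test (are two ranges' niches more alike than models built
from random points in the same ranges?), PCA convex-hull niche breadth,
pairwise Welch's t-tests of environmental means, and the Mantel test
relating niche overlap to genetic differentiation.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.stats import ttest_ind
from sklearn.decomposition import PCA

from .enm import SuitabilityMap, fit_niche_model, sample_background
from .grids import EnvGrid
from .occurrences import OccurrenceSet

__all__ = [
    "OverlapResult",
    "NicheBreadth",
    "schoener_d",
    "similarity_test",
    "niche_breadth_pca",
    "welch_pairwise",
    "mantel_test",
]


def schoener_d(mx: SuitabilityMap, my: SuitabilityMap) -> float:
    """Schoener's D between two suitability maps on identical geometry.

    Each map is first scaled to sum to 1 over valid cells (a probability
    surface), then ``D = 1 - 0.5 * sum_i |P_X,i - P_Y,i|``; 0 means disjoint
    support, 1 identical surfaces.
    """
    if not mx.same_geometry(my):
        raise ValueError("suitability maps have different geometry or mask")
    x = mx.valid_values().astype(float)
    y = my.valid_values().astype(float)
    sx, sy = x.sum(), y.sum()
    if sx <= 0 or sy <= 0:
        raise ValueError("each map must have positive total suitability")
    d = 1.0 - 0.5 * np.abs(x / sx - y / sy).sum()
    return float(min(max(d, 0.0), 1.0))


@dataclass
class OverlapResult:
    """Observed Schoener's D with its randomization null distribution."""

    D: float
    null_values: list[float] = field(default_factory=list)
    percentile_low: float = float("nan")
    percentile_high: float = float("nan")
    significant: bool | None = None
    n_failed: int = 0


def _uniform_records(grid: EnvGrid, n: int, rng: np.random.Generator,
                     range_label: str) -> OccurrenceSet:
    centers = grid.valid_cell_centers()
    idx = rng.choice(len(centers), size=n, replace=n > len(centers))
    return OccurrenceSet.from_arrays(centers[idx, 0], centers[idx, 1],
                                     range_label=range_label)


def similarity_test(records_A: OccurrenceSet, records_B: OccurrenceSet,
                    grid_A: EnvGrid, grid_B: EnvGrid, target: EnvGrid,
                    n_reps: int = 100, seed: int | None = None,
                    betamultiplier: float = 1.0, n_background: int = 1000,
                    buffer_radius: float = 0.0) -> OverlapResult:
    """Randomization test of niche similarity between two ranges.

    The observed D compares models fitted on the true records of ranges A
    and B, both projected to ``target``. The null distribution holds one
    model fixed and refits the other on points drawn uniformly from the
    valid cells of its range: ``n_reps`` values of D(M_A, M_Brandom) plus
    ``n_reps`` values of D(M_Arandom, M_B). The observed D is significant if
    it sits at or below the 2.5th or at or above the 97.5th percentile of
    the null — D values inside the band cannot be distinguished from
    differences in habitat availability alone.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)

    def fit_project(records, grid, sub_seed):
        bg = sample_background(grid, records, n_background,
                               buffer_radius=buffer_radius, seed=sub_seed)
        model = fit_niche_model(records, bg, grid,
                                betamultiplier=betamultiplier)
        return model.predict_grid(target)

    proj_A = fit_project(records_A, grid_A, int(rng.integers(2**31 - 1)))
    proj_B = fit_project(records_B, grid_B, int(rng.integers(2**31 - 1)))
    observed = schoener_d(proj_A, proj_B)

    null: list[float] = []
    n_failed = 0
    for fixed_proj, other_records, other_grid in (
            (proj_A, records_B, grid_B), (proj_B, records_A, grid_A)):
        for _ in range(n_reps):
            rand = _uniform_records(other_grid, len(other_records), rng,
                                    range_label="random")
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    rand_proj = fit_project(rand, other_grid,
                                            int(rng.integers(2**31 - 1)))
            except Exception:  # degenerate replicate: skip, keep count
                n_failed += 1
                continue
            null.append(schoener_d(fixed_proj, rand_proj))
    if n_failed:
        warnings.warn(f"{n_failed} null replicate(s) failed and were skipped")
    if not null:
        return OverlapResult(observed, [], n_failed=n_failed)
    lo = float(np.quantile(null, 0.025))
    hi = float(np.quantile(null, 0.975))
    significant = observed <= lo or observed >= hi
    return OverlapResult(observed, null, lo, hi, significant, n_failed)


@dataclass
class NicheBreadth:
    """PC1–PC2 scores and convex-hull areas used as niche-breadth proxies."""

    pc_scores: pd.DataFrame  # columns: PC1, PC2, range
    hull_area_by_range: dict
    pct_of_global: dict
    explained_variance_ratio: np.ndarray | None = None


def _hull_area(points: np.ndarray) -> float:
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        warnings.warn("fewer than 3 distinct points; hull area is 0")
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D: volume is the area
    except QhullError:
        warnings.warn("degenerate (collinear) point set; hull area is 0")
        return 0.0


def niche_breadth_pca(records_by_range: dict, grids: dict) -> NicheBreadth:
    """Convex-hull niche breadth on the first two principal components.

    Environmental values are extracted at every record, pooled across
    ranges, z-standardized per variable (correlation-matrix PCA, appropriate
    for mixed-unit predictors) and projected onto PC1–PC2. The area of each
    range's convex hull, as a percentage of the pooled ('global') hull, is
    the niche-breadth proxy.
    """
    frames = []
    for rng_label, records in records_by_range.items():
        grid = grids[rng_label]
        env = records.env_at(grid)
        env = env.dropna()
        env["range"] = rng_label
        frames.append(env)
    pooled = pd.concat(frames, ignore_index=True)
    X = pooled.drop(columns="range").to_numpy(dtype=float)
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd < 1e-12] = 1.0
    Z = (X - mu) / sd
    pca = PCA(n_components=2)
    scores = pca.fit_transform(Z)
    df = pd.DataFrame({"PC1": scores[:, 0], "PC2": scores[:, 1],
                       "range": pooled["range"]})
    areas = {"global": _hull_area(scores)}
    for rng_label in records_by_range:
        areas[rng_label] = _hull_area(
            scores[(pooled["range"] == rng_label).to_numpy()])
    g = areas["global"]
    pct = {k: (100.0 * a / g if g > 0 else float("nan"))
           for k, a in areas.items()}
    return NicheBreadth(df, areas, pct, pca.explained_variance_ratio_)


def welch_pairwise(values_by_group: dict) -> pd.DataFrame:
    """Pairwise Welch's t-tests of group means (unequal variances).

    Returns a tidy table with columns group1, group2, t, df, p. Pairs where
    both groups have zero variance yield NaN with a warning.
    """
    rows = []
    names = list(values_by_group)
    for g1, g2 in itertools.combinations(names, 2):
        a = np.asarray(values_by_group[g1], dtype=float)
        b = np.asarray(values_by_group[g2], dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError("each group needs at least 2 values")
        if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
            warnings.warn(f"zero variance in both {g1!r} and {g2!r}; "
                          "Welch's t undefined")
            rows.append((g1, g2, np.nan, np.nan, np.nan))
            continue
        res = ttest_ind(a, b, equal_var=False)
        rows.append((g1, g2, float(res.statistic), float(res.df),
                     float(res.pvalue)))
    return pd.DataFrame(rows, columns=["group1", "group2", "t", "df", "p"])


def mantel_test(m1: np.ndarray, m2: np.ndarray, n_perm: int = 999,
                seed: int | None = None) -> tuple[float, float]:
    """Mantel test of association between two distance matrices.

    ``r`` is the Pearson correlation of the strict upper triangles; ``p`` is
    the two-sided permutation p-value under simultaneous row/column
    permutations of ``m2``. When ``n_perm >= n!`` the permutation
    distribution is enumerated exactly (p = count / n!); otherwise the null
    consists of the identity plus ``n_perm - 1`` random permutations.
    """
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    n = m1.shape[0]
    if m1.shape != (n, n) or m2.shape != (n, n) or n < 3:
        raise ValueError("matrices must be square, same size, n >= 3")
    for m in (m1, m2):
        if not np.allclose(m, m.T) or not np.allclose(np.diag(m), 0):
            raise ValueError("matrices must be symmetric with zero diagonal")
    iu = np.triu_indices(n, k=1)
    v1 = m1[iu]

    def corr(mat):
        v2 = mat[iu]
        if v1.std() == 0 or v2.std() == 0:
            raise ValueError("zero variance in a distance-matrix triangle")
        return float(np.corrcoef(v1, v2)[0, 1])

    r_obs = corr(m2)
    if n_perm >= math.factorial(n):
        perms = itertools.permutations(range(n))
        total = math.factorial(n)
        count = sum(1 for p in perms
                    if abs(corr(m2[np.ix_(p, p)])) >= abs(r_obs) - 1e-12)
        return r_obs, count / total
    rng = np.random.default_rng(seed)
    count = 1  # identity permutation
    for _ in range(n_perm - 1):
        p = rng.permutation(n)
        if abs(corr(m2[np.ix_(p, p)])) >= abs(r_obs) - 1e-12:
            count += 1
    return r_obs, count / n_perm
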