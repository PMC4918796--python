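"""Alpha/beta diversity and permutation inference for community tables.

Alpha diversity: bias-corrected Chao1 richness and Pielou's evenness
(J = H'/ln S, natural-log Shannon).  Beta diversity: Bray-Curtis
dissimilarities, non-metric multidimensional scaling (NMDS) with Kruskal
stress-1, and a permutation-inference suite — envfit-style vector fitting,
one-way PERMANOVA, the Procrustes randomisation test (PROTEST) and
multivariate beta dispersion — all with explicit seeds and the permutation
p-value convention p = (1 + #{perm >= obs}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import smacof

from .otu_io import OTUTable

__all__ = [
    "Ordination",
    "PermutationTestResult",
    "chao1",
    "pielou_evenness",
    "bray_curtis",
    "kruskal_stress",
    "nmds",
    "envfit_vector",
    "permanova",
    "procrustes_test",
    "beta_dispersion",
]


# -- alpha diversity --------------------------------------------------------


def _validated_counts(counts) -> np.ndarray:
    arr = np.asarray(counts, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"expected a 1-d count vector, got shape {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty count vector")
    if not np.all(np.isfinite(arr)) or np.any(arr < 0) or np.any(np.modf(arr)[0] != 0):
        raise ValueError("counts must be finite non-negative integers")
    if arr.sum() == 0:
        raise ValueError("all-zero count vector")
    return arr


def chao1(counts) -> float:
    """Bias-corrected Chao1 richness estimate.

    S_chao1 = S_obs + F1 (F1 - 1) / (2 (F2 + 1)), with F1/F2 the numbers of
    singleton and doubleton taxa.  Always >= observed richness, with equality
    iff F1 <= 1.
    """
    arr = _validated_counts(counts)
    s_obs = int(np.count_nonzero(arr))
    f1 = int(np.count_nonzero(arr == 1))
    f2 = int(np.count_nonzero(arr == 2))
    return s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))


def pielou_evenness(counts) -> float:
    """Pielou's J = H'/ln S over taxa with positive counts (natural log).

    Undefined for a single-taxon sample (ln 1 = 0); raises rather than
    returning 0.
    """
    arr = _validated_counts(counts)
    pos = arr[arr > 0]
    if pos.size < 2:
        raise ValueError("Pielou's evenness requires >= 2 taxa with positive counts")
    p = pos / pos.sum()
    h = float(-(p * np.log(p)).sum())
    return h / np.log(pos.size)


# -- Bray-Curtis ------------------------------------------------------------


def bray_curtis(table: OTUTable | pd.DataFrame) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarities d(x,y) = sum|x-y| / sum(x+y).

    Bounded in [0, 1]; double-zero taxa contribute nothing.  Every sample
    must have a positive total (an all-zero pair has no defined
    dissimilarity).
    """
    df = table.counts if isinstance(table, OTUTable) else table
    if df.shape[0] < 2:
        raise ValueError("Bray-Curtis requires >= 2 samples")
    totals = df.sum(axis=1)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"samples with zero total reads: {empty}")
    d = pdist(df.to_numpy(dtype=float), metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=[str(i) for i in df.index])


# -- NMDS -------------------------------------------------------------------


@dataclass(frozen=True)
class Ordination:
    """A low-dimensional sample configuration with its Kruskal stress-1."""

    ids: tuple[str, ...]
    scores: np.ndarray  # n x k
    stress: float
    k: int

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.scores, index=list(self.ids), columns=[f"NMDS{i+1}" for i in range(self.k)]
        )


def kruskal_stress(scores: np.ndarray, dm: DistanceMatrix) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix.

    Monotone (isotonic) regression of configuration distances on the
    dissimilarities with primary (weak) tie treatment: within a tie group of
    equal dissimilarities the fitted values are free to follow the observed
    distances.  stress-1 = sqrt(sum (d - dhat)^2 / sum d^2).
    """
    scores = np.asarray(scores, dtype=float)
    delta = dm.condensed_form()
    d = pdist(scores)
    order = np.lexsort((d, delta))  # primary tie treatment
    iso = IsotonicRegression()
    dhat_sorted = iso.fit_transform(np.arange(d.size), d[order])
    dhat = np.empty_like(d)
    dhat[order] = dhat_sorted
    denom = float((d**2).sum())
    if denom == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return float(np.sqrt(((d - dhat) ** 2).sum() / denom))


def _classical_mds(dm: DistanceMatrix, k: int) -> np.ndarray:
    """Principal-coordinates (Torgerson) configuration used as the metric start."""
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    idx = np.argsort(vals)[::-1][:k]
    vals = np.clip(vals[idx], 0.0, None)
    return vecs[:, idx] * np.sqrt(vals)


def nmds(
    dm: DistanceMatrix,
    k: int = 2,
    n_restarts: int = 20,
    max_iter: int = 300,
    tol: float = 1e-7,
    seed: int | None = None,
) -> Ordination:
    """Non-metric multidimensional scaling minimising Kruskal stress-1.

    Runs monotone-regression (isotonic SMACOF) majorisation from
    ``n_restarts`` random starts plus one metric-scaling (principal
    coordinates) start and returns the configuration with the lowest
    stress-1.  Deterministic given ``seed``.
    """
    data = np.asarray(dm.data, dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("distance matrix contains non-finite values")
    n = data.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n_samples; got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    inits = [_classical_mds(dm, k)]
    inits += [rng.uniform(-1, 1, size=(n, k)) for _ in range(n_restarts)]
    best_scores, best_stress = None, np.inf
    for init in inits:
        config, _ = smacof(
            data,
            metric=False,
            n_components=k,
            init=init,
            n_init=1,
            max_iter=max_iter,
            eps=tol,
            normalized_stress=True,
            random_state=0,
        )
        s = kruskal_stress(config, dm)
        if s < best_stress:
            best_scores, best_stress = config, s
    return Ordination(ids=tuple(dm.ids), scores=best_scores, stress=best_stress, k=k)


# -- permutation inference --------------------------------------------------


@dataclass(frozen=True)
class PermutationTestResult:
    statistic: float
    statistic_name: str
    p_value: float
    n_permutations: int
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p-value out of (0, 1]: {self.p_value}")


def _perm_pvalue(obs: float, perm_stats: np.ndarray) -> float:
    return float((1 + np.count_nonzero(perm_stats >= obs)) / (1 + perm_stats.size))


def _align_grouping(ids: Sequence[str], grouping) -> np.ndarray:
    if isinstance(grouping, pd.Series):
        missing = [i for i in ids if i not in grouping.index]
        if missing:
            raise KeyError(f"grouping has no entry for samples: {missing}")
        return grouping.loc[list(ids)].to_numpy()
    arr = np.asarray(grouping)
    if arr.shape[0] != len(ids):
        raise ValueError(f"grouping length {arr.shape[0]} != number of samples {len(ids)}")
    return arr


def _label_permutations(labels: np.ndarray, n_perm: int, rng) -> np.ndarray:
    return rng.permuted(np.tile(labels, (n_perm, 1)), axis=1)


def envfit_vector(
    ordination: Ordination,
    env_values,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Fit an environmental vector to an ordination (envfit-style).

    R^2 is the squared multiple correlation from ordinary least squares of
    the centred variable on the ordination scores; significance by permuting
    the variable over samples.  Samples with a missing value are dropped
    pairwise and reported in ``extras['n_used']``; the fitted direction is
    returned as a unit vector of regression coefficients.
    """
    ids = list(ordination.ids)
    if isinstance(env_values, pd.Series):
        env = env_values.reindex(ids).to_numpy(dtype=float)
    else:
        env = np.asarray(env_values, dtype=float)
        if env.shape[0] != len(ids):
            raise ValueError("env_values not aligned with ordination samples")
    keep = np.isfinite(env)
    env = env[keep]
    x = np.asarray(ordination.scores, dtype=float)[keep]
    n = env.size
    if n < x.shape[1] + 2:
        raise ValueError(f"too few non-missing samples ({n}) for envfit")
    xc = x - x.mean(axis=0)
    ec = env - env.mean()
    sst = float(ec @ ec)
    if sst == 0:
        raise ValueError("env variable is constant")
    coef, *_ = np.linalg.lstsq(xc, ec, rcond=None)
    hat = xc @ np.linalg.pinv(xc)  # projection onto the score space
    r2_obs = float(ec @ hat @ ec) / sst

    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.tile(ec, (n_perm, 1)), axis=1)
    r2_perm = np.einsum("pi,ij,pj->p", perms, hat, perms) / sst
    norm = float(np.linalg.norm(coef))
    direction = coef / norm if norm > 0 else coef
    return PermutationTestResult(
        statistic=r2_obs,
        statistic_name="envfit_r2",
        p_value=_perm_pvalue(r2_obs, r2_perm),
        n_permutations=n_perm,
        extras={"direction": direction, "n_used": n},
    )


def _permanova_f(d2: np.ndarray, label_mat: np.ndarray, groups, counts) -> np.ndarray:
    """Pseudo-F for each row of ``label_mat`` (vectorised over permutations)."""
    n = d2.shape[0]
    ss_total = d2.sum() / (2.0 * n)
    ss_within = np.zeros(label_mat.shape[0])
    for g, n_g in zip(groups, counts):
        ind = (label_mat == g).astype(float)
        ss_within += np.einsum("pi,ij,pj->p", ind, d2, ind) / (2.0 * n_g)
    g_count = len(groups)
    ss_between = ss_total - ss_within
    return (ss_between / (g_count - 1)) / (ss_within / (n - g_count))


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """One-way PERMANOVA on a distance matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within from within-group pairs with
    group-size denominators; pseudo-F = (SS_b/(g-1)) / (SS_w/(n-g)); p by
    permuting group labels.  Requires >= 2 groups, each with >= 2 samples.
    """
    labels = _align_grouping(dm.ids, grouping)
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    if counts.min() < 2:
        small = groups[counts < 2].tolist()
        raise ValueError(f"groups with fewer than 2 samples: {small}")
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    f_obs = float(_permanova_f(d2, labels[None, :], groups, counts)[0])
    ss_total = d2.sum() / (2.0 * n)
    g = groups.size
    # recover R^2 from F: SS_b/SS_t with SS_b = F*(g-1)*SS_w/(n-g)
    ss_within = ss_total / (1.0 + f_obs * (g - 1) / (n - g))
    r2 = 1.0 - ss_within / ss_total

    rng = np.random.default_rng(seed)
    perm_labels = _label_permutations(labels, n_perm, rng)
    f_perm = _permanova_f(d2, perm_labels, groups, counts)
    return PermutationTestResult(
        statistic=f_obs,
        statistic_name="pseudo_F",
        p_value=_perm_pvalue(f_obs, f_perm),
        n_permutations=n_perm,
        extras={"r2": r2, "n": n, "n_groups": int(g)},
    )


def _standardize_config(x: np.ndarray) -> np.ndarray:
    xc = x - x.mean(axis=0)
    norm = np.linalg.norm(xc)
    if norm == 0:
        raise ValueError("degenerate configuration: all points coincide")
    return xc / norm


def _procrustes_m2(x0: np.ndarray, y_rows: np.ndarray) -> np.ndarray:
    """Symmetric-Procrustes m^2 of x0 against each (possibly batched) row-set."""
    if y_rows.ndim == 2:
        y_rows = y_rows[None, ...]
    m = np.einsum("ni,pnj->pij", x0, y_rows)
    sv = np.linalg.svd(m, compute_uv=False)
    return 1.0 - sv.sum(axis=1) ** 2


def procrustes_test(
    config_x,
    config_y,
    n_perm: int = 999,
    seed: int | None = None,
) -> PermutationTestResult:
    """Procrustes randomisation test (PROTEST) of two sample configurations.

    Both configurations (matched by sample id when DataFrames/Ordinations
    are given) are centred and scaled to unit norm; m^2 is the residual
    after the optimal rotation and r = sqrt(1 - m^2) the concordance.
    Significance by permuting the row order of the second configuration.
    """
    x, y = _as_scores(config_x), _as_scores(config_y)
    if list(x.index) != list(y.index):
        missing = set(x.index) ^ set(y.index)
        if missing:
            raise ValueError(f"configurations cover different samples: {sorted(missing)}")
        y = y.loc[x.index]
    if x.shape != y.shape:
        raise ValueError(f"configuration shapes differ: {x.shape} vs {y.shape}")
    x0 = _standardize_config(x.to_numpy(dtype=float))
    y0 = _standardize_config(y.to_numpy(dtype=float))
    m2_obs = float(_procrustes_m2(x0, y0)[0])
    r_obs = float(np.sqrt(max(0.0, 1.0 - m2_obs)))

    rng = np.random.default_rng(seed)
    n = x0.shape[0]
    perm_idx = rng.permuted(np.tile(np.arange(n), (n_perm, 1)), axis=1)
    r_perm = np.sqrt(np.clip(1.0 - _procrustes_m2(x0, y0[perm_idx]), 0.0, None))
    return PermutationTestResult(
        statistic=r_obs,
        statistic_name="procrustes_r",
        p_value=_perm_pvalue(r_obs, r_perm),
        n_permutations=n_perm,
        extras={"m2": m2_obs, "n": n},
    )


def _as_scores(config) -> pd.DataFrame:
    if isinstance(config, Ordination):
        return config.as_frame()
    if isinstance(config, pd.DataFrame):
        return config
    arr = np.asarray(config, dtype=float)
    return pd.DataFrame(arr, index=[str(i) for i in range(arr.shape[0])])


def _dispersion_distances(dm: DistanceMatrix, labels: np.ndarray) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Negative eigenvalue axes are embedded separately and their squared
    contribution subtracted (floored at zero), the standard correction for
    semi-metric dissimilarities such as Bray-Curtis.
    """
    d2 = np.asarray(dm.data, dtype=float) ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    vals, vecs = np.linalg.eigh(b)
    tol = 1e-10 * np.abs(vals).max()
    pos, neg = vals > tol, vals < -tol
    yp = vecs[:, pos] * np.sqrt(vals[pos])
    yn = vecs[:, neg] * np.sqrt(-vals[neg])
    d2c = np.zeros(n)
    for g in np.unique(labels):
        m = labels == g
        d2c[m] = ((yp[m] - yp[m].mean(axis=0)) ** 2).sum(axis=1)
        if yn.shape[1]:
            d2c[m] -= ((yn[m] - yn[m].mean(axis=0)) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2c, 0.0, None))


def _anova_f(values: np.ndarray, label_mat: np.ndarray, groups, counts) -> np.ndarray:
    """One-way ANOVA F of ``values`` for each labelling row (vectorised)."""
    n = values.size
    grand = values.mean()
    sst = float(((values - grand) ** 2).sum())
    ssb = np.zeros(label_mat.shape[0])
    for g, n_g in zip(groups, counts):
        means = (label_mat == g) @ values / n_g
        ssb += n_g * (means - grand) ** 2
    k = len(groups)
    ssw = sst - ssb
    return (ssb / (k - 1)) / (ssw / (n - k))


def beta_dispersion(
    dm: DistanceMatrix,
    grouping,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[PermutationTestResult, pd.Series]:
    """Homogeneity of multivariate dispersion between groups.

    Each sample's distance to its group centroid is computed in the
    principal-coordinates embedding (with the negative-eigenvalue
    correction); the between-group difference in mean distances is tested by
    permuting group labels over those distances.  Returns the test result and
    the per-sample distances.  ``extras`` reports group means plus both the
    difference and the ratio of means (two-group case).
    """
    labels = _align_grouping(dm.ids, grouping)
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("beta dispersion requires >= 2 groups")
    if counts.min() < 2:
        raise ValueError(f"groups with fewer than 2 samples: {groups[counts < 2].tolist()}")
    dists = _dispersion_distances(dm, labels)
    f_obs = float(_anova_f(dists, labels[None, :], groups, counts)[0])
    rng = np.random.default_rng(seed)
    perm_labels = _label_permutations(labels, n_perm, rng)
    f_perm = _anova_f(dists, perm_labels, groups, counts)

    means = {str(g): float(dists[labels == g].mean()) for g in groups}
    extras: dict = {"group_mean_distances": means}
    if groups.size == 2:
        a, b = (means[str(g)] for g in groups)
        extras["mean_difference"] = abs(a - b)
        extras["mean_ratio"] = max(a, b) / min(a, b) if min(a, b) > 0 else np.inf
    result = PermutationTestResult(
        statistic=f_obs,
        statistic_name="dispersion_F",
        p_value=_perm_pvalue(f_obs, f_perm),
        n_permutations=n_perm,
        extras=extras,
    )
    return result, pd.Series(dists, index=list(dm.ids), name="distance_to_centroid")
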