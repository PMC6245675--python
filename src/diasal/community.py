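"""Community-structure statistics on dissimilarity matrices.

Seasonal differences in assemblage composition are tested on a Bray-Curtis
dissimilarity matrix computed from square-root-transformed percentages:

* :func:`permanova` asks whether group centroids differ (one-way design,
  free permutation of group labels),
* :func:`dispersion_test` asks whether within-group spread (beta diversity)
  differs, via distances to group centroids in principal-coordinate space,
* :func:`simper` decomposes the average between-group dissimilarity into
  per-taxon contributions,
* :func:`nmds` provides the low-dimensional ordination view (Kruskal
  stress-1, SMACOF with isotonic regression), and
* :func:`env_screen` runs the univariate environment checks (one-way ANOVA
  across groups, Pearson correlation against the calibration target).

Permutation p-values include the observed statistic in both numerator and
denominator, so p >= 1/(n_permutations + 1) and is never zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy import stats
from sklearn.isotonic import IsotonicRegression

from .datasets import CommunityTable

__all__ = [
    "DistanceMatrix",
    "PermanovaResult",
    "DispersionResult",
    "NMDSResult",
    "bray_curtis",
    "permanova",
    "dispersion_test",
    "simper",
    "nmds",
    "kruskal_stress",
    "env_screen",
]


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with a zero diagonal."""

    site_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("distance matrix must be square")
        if len(self.site_ids) != v.shape[0]:
            raise ValueError("site_ids length does not match matrix size")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


def bray_curtis(ct: CommunityTable, *, allow_any_unit: bool = False) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between sites.

    d_ij = sum_k |y_ik - y_jk| / sum_k (y_ik + y_jk).  By convention the
    input is the square-root-transformed percentage matrix; pass
    ``allow_any_unit=True`` to skip the unit check.
    """
    if not allow_any_unit and ct.unit != "sqrt_percent":
        raise ValueError(
            f"bray_curtis expects sqrt_percent (got {ct.unit!r}); "
            "pass allow_any_unit=True to override")
    values = ct.values
    zero_rows = (values.sum(axis=1) == 0)
    if zero_rows.sum() >= 2:
        bad = ct.data.index[zero_rows].tolist()
        raise ValueError(f"Bray-Curtis undefined between all-zero sites: {bad}")
    d = squareform(pdist(values, metric="braycurtis"), checks=False)
    return DistanceMatrix(ct.site_ids, d)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    ss_among: float
    ss_within: float
    ss_total: float
    df_among: int
    df_within: int
    pairwise: pd.DataFrame | None = None


def _group_indices(labels) -> dict:
    labels = np.asarray(labels)
    return {g: np.flatnonzero(labels == g) for g in pd.unique(labels)}


def _permanova_ss(d2: np.ndarray, groups: dict):
    """Sums of squares from the squared-distance matrix and group index map."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for idx in groups.values():
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    return ss_total, ss_within


def _pseudo_f(ss_total, ss_within, a, n):
    ss_among = ss_total - ss_within
    if ss_within <= 0:
        return math.inf, ss_among
    return (ss_among / (a - 1)) / (ss_within / (n - a)), ss_among


def permanova(d: DistanceMatrix, groups, *, n_permutations: int = 9999,
              seed: int = 0, pairwise: bool = False,
              exhaustive: bool = False) -> PermanovaResult:
    """One-way PERMANOVA on a dissimilarity matrix.

    Tests the null that group centroids coincide, by permuting group labels
    freely (for a single factor this is the standard reduction of permuting
    residuals under the reduced model).  With ``exhaustive=True`` the p-value
    is computed over all label permutations (feasible only for tiny n) as the
    fraction of permutations with F >= the observed F.
    """
    labels = pd.Series(groups, index=d.site_ids) if not isinstance(groups, pd.Series) \
        else groups.reindex(d.site_ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some sites")
    labels = labels.to_numpy()
    group_map = _group_indices(labels)
    a, n = len(group_map), d.n
    if a < 2:
        raise ValueError("permanova requires at least two groups")
    sizes = {g: len(idx) for g, idx in group_map.items()}
    small = [g for g, s in sizes.items() if s < 2]
    if small:
        raise ValueError(f"group(s) with fewer than two members: {small}")

    d2 = d.values ** 2
    ss_total, ss_within = _permanova_ss(d2, group_map)
    f_obs, ss_among = _pseudo_f(ss_total, ss_within, a, n)

    if exhaustive:
        count = total = 0
        for perm in itertools.permutations(range(n)):
            perm_groups = _group_indices(labels[list(perm)])
            _, ssw = _permanova_ss(d2, perm_groups)
            f_perm, _ = _pseudo_f(ss_total, ssw, a, n)
            count += f_perm >= f_obs - 1e-12
            total += 1
        p = count / total
        n_perm_used = total
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm_groups = _group_indices(rng.permutation(labels))
            _, ssw = _permanova_ss(d2, perm_groups)
            f_perm, _ = _pseudo_f(ss_total, ssw, a, n)
            count += f_perm >= f_obs - 1e-12
        p = (1 + count) / (1 + n_permutations)
        n_perm_used = n_permutations

    pw = None
    if pairwise:
        rows = []
        pairs = list(itertools.combinations(sorted(group_map), 2))
        for g1, g2 in pairs:
            idx = np.sort(np.concatenate([group_map[g1], group_map[g2]]))
            sub = DistanceMatrix([d.site_ids[i] for i in idx], d.values[np.ix_(idx, idx)])
            res = permanova(sub, labels[idx], n_permutations=n_permutations,
                            seed=seed, pairwise=False, exhaustive=exhaustive)
            rows.append({"group_1": g1, "group_2": g2, "pseudo_F": res.pseudo_F,
                         "p_raw": res.p_value,
                         "p_bonferroni": min(1.0, res.p_value * len(pairs))})
        pw = pd.DataFrame(rows)

    return PermanovaResult(pseudo_F=f_obs, p_value=p, n_permutations=n_perm_used,
                           ss_among=ss_among, ss_within=ss_within, ss_total=ss_total,
                           df_among=a - 1, df_within=n - a, pairwise=pw)


# ---------------------------------------------------------------------------
# Multivariate dispersion (distance to group centroid)
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances_to_centroid: pd.Series
    group_means: pd.Series
    F: float
    p_value: float
    n_permutations: int


def _gower_embedding(d: np.ndarray):
    """Principal-coordinate embedding, keeping negative-eigenvalue axes apart.

    Returns (real-axis coordinates, imaginary-axis coordinates): squared
    Euclidean distances in the embedding equal squared real distances minus
    squared imaginary distances, reproducing the original d^2 exactly.
    """
    n = d.shape[0]
    a = -0.5 * d ** 2
    centering = np.eye(n) - np.full((n, n), 1.0 / n)
    g = centering @ a @ centering
    g = (g + g.T) / 2
    eigval, eigvec = np.linalg.eigh(g)
    tol = 1e-10 * max(1.0, np.abs(eigval).max())
    pos = eigval > tol
    neg = eigval < -tol
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return real, imag


def _centroid_distances(real, imag, groups: dict) -> np.ndarray:
    n = real.shape[0]
    z = np.zeros(n)
    for idx in groups.values():
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(imag.shape[1])
        sq = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            sq = sq - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.clip(sq, 0.0, None))
    return z


def dispersion_test(d: DistanceMatrix, groups, *, n_permutations: int = 9999,
                    seed: int = 0) -> DispersionResult:
    """Test homogeneity of multivariate dispersions (beta diversity).

    Sites are embedded by principal coordinates (Gower centering of -d^2/2);
    the distance of each site to its group centroid is computed with the
    negative-eigenvalue correction (imaginary axes subtract, clamped at
    zero).  Group equality of mean distances is tested by a one-way ANOVA F,
    with the permutation distribution obtained by permuting group labels
    over the fixed distances (the multivariate analogue of Levene's test).
    """
    labels = pd.Series(groups, index=d.site_ids) if not isinstance(groups, pd.Series) \
        else groups.reindex(d.site_ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some sites")
    labels = labels.to_numpy()
    group_map = _group_indices(labels)
    if len(group_map) < 2 or any(len(i) < 2 for i in group_map.values()):
        raise ValueError("dispersion_test requires >=2 groups with >=2 members")

    real, imag = _gower_embedding(d.values)
    z = _centroid_distances(real, imag, group_map)

    def anova_f(values, gmap):
        grand = values.mean()
        ss_between = sum(len(i) * (values[i].mean() - grand) ** 2 for i in gmap.values())
        ss_within = sum(((values[i] - values[i].mean()) ** 2).sum() for i in gmap.values())
        df_b, df_w = len(gmap) - 1, len(values) - len(gmap)
        if ss_within <= 1e-300:
            return 0.0 if ss_between <= 1e-300 else math.inf
        return (ss_between / df_b) / (ss_within / df_w)

    f_obs = anova_f(z, group_map)
    if np.allclose(z, z[0]):
        f_obs, p = 0.0, 1.0
    else:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            perm_map = _group_indices(rng.permutation(labels))
            count += anova_f(z, perm_map) >= f_obs - 1e-12
        p = (1 + count) / (1 + n_permutations)

    dist = pd.Series(z, index=d.site_ids, name="distance_to_centroid")
    means = pd.Series({g: z[idx].mean() for g, idx in group_map.items()},
                      name="mean_distance")
    return DispersionResult(distances_to_centroid=dist, group_means=means,
                            F=f_obs, p_value=p, n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# SIMPER
# ---------------------------------------------------------------------------

def simper(ct: CommunityTable, groups) -> pd.DataFrame:
    """Per-taxon contributions to average between-group dissimilarity.

    For every between-group site pair (i, j) the Bray-Curtis dissimilarity
    splits into per-taxon terms |y_ik - y_jk| / sum_l (y_il + y_jl).  These
    are averaged over all between-group pairs, pooled across all group pairs
    when more than two groups are present.  The per-taxon averages sum to
    the average between-group dissimilarity exactly.

    Returns a DataFrame sorted by contribution (columns: ``taxon``,
    ``average_dissimilarity``, ``contribution_pct``, ``cumulative_pct``).
    """
    labels = pd.Series(groups, index=ct.site_ids) if not isinstance(groups, pd.Series) \
        else groups.reindex(ct.site_ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some sites")
    group_map = _group_indices(labels.to_numpy())
    if len(group_map) < 2:
        raise ValueError("simper requires at least two groups")

    y = ct.values
    contrib = np.zeros(ct.n_taxa)
    n_pairs = 0
    for g1, g2 in itertools.combinations(group_map, 2):
        for i in group_map[g1]:
            rows_j = group_map[g2]
            diff = np.abs(y[i] - y[rows_j])           # |pairs| x taxa
            denom = (y[i] + y[rows_j]).sum(axis=1)    # per pair
            if (denom == 0).any():
                raise ValueError("Bray-Curtis undefined for a pair of all-zero sites")
            contrib += (diff / denom[:, None]).sum(axis=0)
            n_pairs += len(rows_j)
    contrib /= n_pairs

    table = pd.DataFrame({"taxon": ct.taxon_ids, "average_dissimilarity": contrib})
    table = table.sort_values(["average_dissimilarity", "taxon"],
                              ascending=[False, True], ignore_index=True)
    total = table["average_dissimilarity"].sum()
    table["contribution_pct"] = 100.0 * table["average_dissimilarity"] / total
    table["cumulative_pct"] = table["contribution_pct"].cumsum()
    return table


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class NMDSResult:
    coordinates: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    site_ids: list
    stress_history: list  # per-iteration stress-1 of the best start


def _disparities(dvec: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """Monotone (isotonic) regression of configuration distances on the
    dissimilarity order; ties in the dissimilarities are broken by the
    current configuration distance (Kruskal's primary approach)."""
    order = np.lexsort((dist, dvec))
    iso = IsotonicRegression(increasing=True)
    fitted = iso.fit_transform(np.arange(len(dvec)), dist[order])
    disp = np.empty_like(fitted)
    disp[order] = fitted
    return disp


def kruskal_stress(d: DistanceMatrix | np.ndarray, coordinates: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against a dissimilarity matrix."""
    dvec = d.condensed() if isinstance(d, DistanceMatrix) else squareform(np.asarray(d), checks=False)
    dist = pdist(coordinates)
    disp = _disparities(dvec, dist)
    denom = (dist ** 2).sum()
    if denom == 0:
        return 0.0
    return float(np.sqrt(((dist - disp) ** 2).sum() / denom))


def _smacof_single(dvec: np.ndarray, init: np.ndarray, max_iter: int, tol: float):
    """One SMACOF run; returns (coords, stress-1 history, converged)."""
    n = init.shape[0]
    x = init.copy()
    history = [kruskal_stress(squareform(dvec), x)]
    converged = False
    for _ in range(max_iter):
        dist = pdist(x)
        disp = _disparities(dvec, dist)
        # scale-normalize disparities (stress-1 is scale-invariant in the
        # configuration, so only the relative pattern matters)
        ssum = (disp ** 2).sum()
        if ssum > 0:
            disp = disp * np.sqrt(len(disp) / ssum)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(dist > 0, disp / dist, 0.0)
        b_flat = -squareform(ratio, checks=False)
        np.fill_diagonal(b_flat, -b_flat.sum(axis=1))
        x_new = b_flat @ x / n
        s_new = kruskal_stress(squareform(dvec), x_new)
        if s_new > history[-1]:       # keep history monotone; stop here
            break
        x = x_new
        history.append(s_new)
        if history[-2] - history[-1] < tol:
            converged = True
            break
    return x, history, converged


def nmds(d: DistanceMatrix, k: int = 2, *, n_restarts: int = 20, seed: int = 0,
         max_iter: int = 500, tol: float = 1e-7) -> NMDSResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    The first start is the principal-coordinate configuration; the remaining
    ``n_restarts - 1`` starts are random.  The lowest-stress solution is
    returned.  Deterministic for a fixed seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if d.n < k + 2:
        raise ValueError(f"need at least k + 2 = {k + 2} sites, got {d.n}")
    dvec = d.condensed()
    rng = np.random.default_rng(seed)

    real, _ = _gower_embedding(d.values)
    init0 = np.zeros((d.n, k))
    take = min(k, real.shape[1])
    init0[:, :take] = real[:, :take]
    if take < k:
        init0[:, take:] = rng.normal(scale=1e-4, size=(d.n, k - take))

    best = None
    for start in range(max(1, n_restarts)):
        init = init0 if start == 0 else rng.normal(size=(d.n, k))
        coords, history, conv = _smacof_single(dvec, init, max_iter, tol)
        stress = history[-1]
        if best is None or stress < best[1]:
            best = (coords, stress, history, conv)
    coords, stress, history, conv = best
    return NMDSResult(coordinates=coords, stress=stress, n_restarts=max(1, n_restarts),
                      converged=conv, site_ids=list(d.site_ids), stress_history=history)


# ---------------------------------------------------------------------------
# Environment screening
# ---------------------------------------------------------------------------

def env_screen(et, groups, target: str, *, alpha: float = 0.05) -> pd.DataFrame:
    """One-way ANOVA across groups and Pearson correlation with the target.

    Returns one row per variable: ANOVA F and p across the season groups,
    Pearson r (and two-sided p) against *target*, and significance flags at
    *alpha*.  Zero-variance variables are flagged (``r_defined = False``)
    rather than raising.
    """
    if target not in et.variables:
        raise ValueError(f"target {target!r} not in environment table")
    labels = pd.Series(groups, index=et.site_ids) if not isinstance(groups, pd.Series) \
        else groups.reindex(et.site_ids)
    if labels.isna().any():
        raise ValueError("group labels missing for some sites")
    gmap = _group_indices(labels.to_numpy())
    if any(len(i) < 2 for i in gmap.values()):
        raise ValueError("each group needs >= 2 members for the ANOVA")

    x = et.column(target).to_numpy(dtype=float)
    rows = []
    for var in et.variables:
        v = et.column(var).to_numpy(dtype=float)
        f_stat, f_p = stats.f_oneway(*(v[idx] for idx in gmap.values()))
        if np.ptp(v) == 0 or np.ptp(x) == 0:
            r, r_p, r_def = np.nan, np.nan, False
        else:
            r, r_p = stats.pearsonr(v, x)
            r_def = True
        rows.append({
            "variable": var, "anova_F": float(f_stat), "anova_p": float(f_p),
            "anova_significant": bool(f_p < alpha),
            "pearson_r": float(r) if r_def else np.nan,
            "pearson_p": float(r_p) if r_def else np.nan,
            "r_defined": r_def,
            "pearson_significant": bool(r_def and r_p < alpha and var != target),
        })
    return pd.DataFrame(rows).set_index("variable")
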