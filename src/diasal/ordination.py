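"""Correspondence analysis, canonical correspondence analysis and
variance partitioning.

The abundance table is converted to chi-square standardized residuals
Q = (P - r c^T) / sqrt(r c^T) where P is the matrix of proportions of the
grand total and r, c its row and column totals.  Total inertia is ||Q||^2.
Plain correspondence analysis (CA) is the SVD of Q.  Canonical
correspondence analysis (CCA) projects Q onto the site-weighted span of the
constraining variables before the SVD; the residual carries the
unconstrained axes.  Covariables are partialled out of both the response
and the constraints first (partial CCA), so conditional + constrained +
unconstrained inertia always sums to the total.

The lambda ratio (first constrained eigenvalue over first unconstrained
eigenvalue of a single-constraint CCA) gauges whether the constraint
captures the dominant compositional gradient: a ratio above 1 marks a
variable as a useful calibration target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import CommunityTable, EnvironmentTable

__all__ = [
    "CCAResult",
    "cca",
    "lambda_ratio",
    "variance_partition",
]

_EIG_TOL = 1e-12


@dataclass
class CCAResult:
    constrained_eigenvalues: np.ndarray
    unconstrained_eigenvalues: np.ndarray
    conditional_inertia: float
    total_inertia: float
    site_scores: np.ndarray | None = None
    species_scores: np.ndarray | None = None

    @property
    def constrained_inertia(self) -> float:
        return float(self.constrained_eigenvalues.sum())

    @property
    def explained_fraction(self) -> float:
        denom = self.total_inertia - self.conditional_inertia
        return self.constrained_inertia / denom if denom > 0 else 0.0


def _chi_square_residuals(y: np.ndarray):
    if (y < 0).any():
        raise ValueError("abundances must be nonnegative")
    grand = y.sum()
    if grand <= 0:
        raise ValueError("empty abundance table")
    p = y / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if (r == 0).any() or (c == 0).any():
        raise ValueError("zero row or column total in abundance table")
    expected = np.outer(r, c)
    q = (p - expected) / np.sqrt(expected)
    return q, r, c


def _as_matrix(env, names=None):
    """Coerce constraints/covariables to (matrix, column names)."""
    if env is None:
        return None, []
    if isinstance(env, EnvironmentTable):
        frame = env.data if names is None else env.data[list(names)]
        return frame.to_numpy(dtype=float), list(frame.columns)
    if isinstance(env, pd.DataFrame):
        return env.to_numpy(dtype=float), list(env.columns)
    if isinstance(env, pd.Series):
        return env.to_numpy(dtype=float)[:, None], [env.name or "constraint"]
    arr = np.asarray(env, dtype=float)
    if arr.ndim == 1:
        arr = arr[:, None]
    cols = list(names) if names is not None else [f"x{i}" for i in range(arr.shape[1])]
    return arr, cols


def _weighted_design(x: np.ndarray, r: np.ndarray, names, *, check_rank=True):
    """Center columns under weights r and scale rows by sqrt(r).

    With ``check_rank`` the first linearly dependent column (or a constant
    column) raises, naming the offender.
    """
    sqrt_r = np.sqrt(r)
    xc = x - r @ x
    xw = xc * sqrt_r[:, None]
    if check_rank:
        for j, name in enumerate(names):
            norm = np.linalg.norm(xw[:, j])
            if norm < 1e-12:
                raise ValueError(f"constraint {name!r} has zero weighted variance")
            if j and np.linalg.matrix_rank(xw[:, :j + 1], tol=1e-10) <= \
                    np.linalg.matrix_rank(xw[:, :j], tol=1e-10):
                raise ValueError(f"constraint {name!r} is collinear with the "
                                 "preceding constraints")
    return xw


def _project(q: np.ndarray, basis: np.ndarray):
    """Orthogonal projection of the columns of q onto col(basis)."""
    if basis is None or basis.size == 0:
        return np.zeros_like(q)
    u, s, _ = np.linalg.svd(basis, full_matrices=False)
    keep = s > 1e-12 * max(1.0, s.max() if len(s) else 0.0)
    u = u[:, keep]
    return u @ (u.T @ q)


def _eigenvalues(mat: np.ndarray) -> np.ndarray:
    s = np.linalg.svd(mat, compute_uv=False)
    lam = s ** 2
    lam = lam[lam > _EIG_TOL]
    return lam


def cca(ct, constraints=None, covariables=None, *, constraint_names=None,
        covariable_names=None, scores: bool = False) -> CCAResult:
    """(Partial) canonical correspondence analysis.

    With no constraints this is plain correspondence analysis.  With
    covariables, both the chi-square residual matrix and the constraints
    are first projected off the covariable space under site-total weights.
    """
    y = ct.values if isinstance(ct, CommunityTable) else np.asarray(ct, dtype=float)
    q, r, _ = _chi_square_residuals(y)
    total = float((q ** 2).sum())

    z, z_names = _as_matrix(covariables, covariable_names)
    conditional = 0.0
    if z is not None:
        zw = _weighted_design(z, r, z_names, check_rank=False)
        q_z = _project(q, zw)
        conditional = float((q_z ** 2).sum())
        q = q - q_z
    else:
        zw = None

    x, x_names = _as_matrix(constraints, constraint_names)
    if x is None:
        lam = _eigenvalues(q)
        result = CCAResult(constrained_eigenvalues=np.array([]),
                           unconstrained_eigenvalues=lam,
                           conditional_inertia=conditional, total_inertia=total)
        mat_for_scores = q
    else:
        xw = _weighted_design(x, r, x_names, check_rank=True)
        if zw is not None:
            xw = xw - _project(xw, zw)
        q_hat = _project(q, xw)
        q_res = q - q_hat
        result = CCAResult(constrained_eigenvalues=_eigenvalues(q_hat),
                           unconstrained_eigenvalues=_eigenvalues(q_res),
                           conditional_inertia=conditional, total_inertia=total)
        mat_for_scores = q_hat

    if scores:
        u, s, vt = np.linalg.svd(mat_for_scores, full_matrices=False)
        keep = s ** 2 > _EIG_TOL
        c = (y / y.sum()).sum(axis=0)
        result.site_scores = (u[:, keep] * s[keep]) / np.sqrt(r)[:, None]
        result.species_scores = vt.T[:, keep] / np.sqrt(c)[:, None]
    return result


def lambda_ratio(ct, variable) -> dict:
    """lambda1/lambda2 usefulness diagnostic for a single constraint.

    lambda1 is the constrained eigenvalue of the single-variable CCA,
    lambda2 the first residual eigenvalue.  A ratio above 1 flags the
    variable as carrying the dominant compositional gradient.
    """
    x, names = _as_matrix(variable)
    if x.shape[1] != 1:
        raise ValueError("lambda_ratio expects a single constraint")
    res = cca(ct, constraints=x, constraint_names=names)
    lam1 = float(res.constrained_eigenvalues[0]) if len(res.constrained_eigenvalues) else 0.0
    lam2 = float(res.unconstrained_eigenvalues[0]) if len(res.unconstrained_eigenvalues) else 0.0
    ratio = np.inf if lam2 <= _EIG_TOL else lam1 / lam2
    return {"lambda1": lam1, "lambda2": lam2, "ratio": float(ratio),
            "useful": bool(ratio > 1.0)}


def _constrained_inertia(ct, constraints, covariables=None, *, names=None,
                         cov_names=None) -> float:
    if constraints is None or (hasattr(constraints, "shape") and constraints.shape[1] == 0):
        return 0.0
    res = cca(ct, constraints=constraints, covariables=covariables,
              constraint_names=names, covariable_names=cov_names)
    return res.constrained_inertia


def variance_partition(ct, env: EnvironmentTable, *, variables=None,
                       method: str = "unique_shared") -> pd.DataFrame:
    """Partition explained inertia into per-variable total/unique/shared.

    The full model uses every variable jointly (exact duplicate columns are
    collapsed first).  For each variable v, ``total`` is the inertia
    explained by v alone, ``unique`` the inertia explained by v after
    partialling all other variables out, and ``shared = total - unique``.
    All three are reported as percentages of the full model's explained
    inertia; the full model's share of total inertia is attached as
    DataFrame metadata columns (identical in every row).

    ``method='hierarchical'`` instead averages each variable's incremental
    contribution over all orderings (all-subsets hierarchical partitioning;
    feasible for at most 12 variables), reported in the ``unique`` column
    with ``shared = total - unique``.
    """
    variables = list(variables) if variables is not None else list(env.variables)
    if len(variables) < 2:
        raise ValueError("variance_partition requires at least 2 variables")
    frame = env.data[variables]
    y_rows = ct.n_sites if isinstance(ct, CommunityTable) else np.asarray(ct).shape[0]
    if y_rows <= len(variables) + 1:
        raise ValueError("full model is rank-infeasible: need n > n_variables + 1; "
                         "reduce the variable set")

    # deduplication guard: exact duplicate columns enter the full model once
    unique_cols = []
    for v in variables:
        if not any(frame[v].equals(frame[u]) for u in unique_cols):
            unique_cols.append(v)
    full_frame = frame[unique_cols]
    try:
        e_full = _constrained_inertia(ct, full_frame.to_numpy(dtype=float),
                                      names=unique_cols)
    except ValueError as exc:
        raise ValueError(f"rank-deficient full model ({exc}); reduce the "
                         "variable set") from exc
    if e_full <= 0:
        raise ValueError("full model explains no inertia")

    totals = {}
    for v in variables:
        totals[v] = _constrained_inertia(ct, frame[[v]].to_numpy(dtype=float),
                                         names=[v])

    uniques = {}
    if method == "unique_shared":
        for v in variables:
            # all other variables (duplicates included) act as covariables, so
            # a duplicated variable has zero unique inertia
            others = [u for u in variables if u != v]
            cov = frame[others].to_numpy(dtype=float)
            uniques[v] = _constrained_inertia(
                ct, frame[[v]].to_numpy(dtype=float), covariables=cov,
                names=[v], cov_names=others)
    elif method == "hierarchical":
        if len(unique_cols) > 12:
            raise ValueError("hierarchical mode limited to 12 variables")
        subset_inertia = {(): 0.0}
        for size in range(1, len(unique_cols) + 1):
            for sub in itertools.combinations(unique_cols, size):
                subset_inertia[sub] = _constrained_inertia(
                    ct, frame[list(sub)].to_numpy(dtype=float), names=list(sub))
        p = len(unique_cols)
        import math
        for v in variables:
            vkey = v if v in unique_cols else next(
                u for u in unique_cols if frame[u].equals(frame[v]))
            others = [u for u in unique_cols if u != vkey]
            acc = 0.0
            for size in range(0, p):
                terms = []
                for sub in itertools.combinations(others, size):
                    joint = tuple(sorted(sub + (vkey,), key=unique_cols.index))
                    terms.append(subset_inertia[joint] - subset_inertia[tuple(sorted(sub, key=unique_cols.index))])
                acc += np.mean(terms) / p
            uniques[v] = acc
    else:
        raise ValueError(f"unknown method {method!r}")

    rows = []
    total_inertia = cca(ct).total_inertia
    for v in variables:
        tot = 100.0 * totals[v] / e_full
        unq = 100.0 * uniques[v] / e_full
        rows.append({"variable": v, "total_pct": tot, "unique_pct": unq,
                     "shared_pct": tot - unq,
                     "full_model_explained_pct": 100.0 * e_full / total_inertia})
    return pd.DataFrame(rows).set_index("variable")
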