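"""Weighted-averaging and WA-PLS calibration with leave-one-out validation.

The calibration problem: given a site-by-taxon abundance matrix Y and a
per-site environmental value x (here log10 chloride), build a model that
infers x for a new assemblage.

Weighted averaging (WA) estimates each taxon's optimum as the abundance-
weighted mean of x over the sites where it occurs, infers a raw site value
as the abundance-weighted mean of the optima of the taxa present, and then
deshrinks the range-compressed raw values by a linear regression.  The
deshrinking regression is weighted by site abundance totals, which makes WA
with inverse deshrinking exactly the one-component special case of WA-PLS.

WA-PLS augments WA with further components extracted from the residual
structure of the species data, following the classical iterative algorithm:
species scores are abundance-weighted averages of the current site target
(x for component 1, the regression residuals afterwards), site scores are
abundance-weighted averages of the species scores, components are
orthogonalized and standardized under site-total weights, and x is
regressed on the components.  Every transformation is linear in the species
scores, so for any component count the model collapses to a single
per-taxon coefficient vector: the prediction for a new sample is the plain
weighted average of the collapsed coefficients plus an intercept.

Units: all statistics are in transformed environment units (log10 mg/l for
chloride); back-transformation to mg/l happens in the reconstruction layer.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datasets import CommunityTable

__all__ = [
    "SpeciesCoefficients",
    "WAModel",
    "WAPLSModel",
    "CrossValResult",
    "species_coefficients",
    "wa_calibrate",
    "wapls_calibrate",
    "loo_crossval",
    "select_components",
    "component_significance",
    "performance",
    "model_to_json",
    "model_from_json",
]


def _extract(ct, x):
    """Validate and align community values and environment vector."""
    if isinstance(ct, CommunityTable):
        y = ct.values
        taxa = list(ct.taxon_ids)
        sites = list(ct.site_ids)
    else:
        y = np.asarray(ct, dtype=float)
        taxa = list(range(y.shape[1]))
        sites = list(range(y.shape[0]))
    x = np.asarray(x, dtype=float)
    if x.shape != (y.shape[0],):
        raise ValueError(f"environment vector length {x.shape} does not match "
                         f"{y.shape[0]} sites")
    if (y < 0).any():
        raise ValueError("negative abundances")
    return y, x, taxa, sites


def _drop_empty_taxa(y, taxa, warn=True):
    keep = y.sum(axis=0) > 0
    if not keep.all():
        dropped = [t for t, k in zip(taxa, keep) if not k]
        if warn:
            warnings.warn(f"excluding {len(dropped)} taxa with zero total abundance",
                          stacklevel=3)
        y = y[:, keep]
        taxa = [t for t, k in zip(taxa, keep) if k]
    return y, taxa


# ---------------------------------------------------------------------------
# Species coefficients
# ---------------------------------------------------------------------------

def species_coefficients(ct, x) -> pd.DataFrame:
    """Weighted optimum, tolerance, Hill's N2 and occurrence count per taxon.

    optimum  u_k = sum_i y_ik x_i / sum_i y_ik
    tolerance t_k = sqrt( sum_i y_ik (x_i - u_k)^2 / sum_i y_ik )
    N2_k = 1 / sum_i (y_ik / sum_j y_jk)^2   (effective number of occurrences)

    Taxa with zero total abundance are excluded with a warning.
    """
    y, x, taxa, _ = _extract(ct, x)
    y, taxa = _drop_empty_taxa(y, taxa)
    totals = y.sum(axis=0)
    optimum = (y * x[:, None]).sum(axis=0) / totals
    spread = (y * (x[:, None] - optimum[None, :]) ** 2).sum(axis=0) / totals
    tolerance = np.sqrt(np.clip(spread, 0.0, None))
    shares = y / totals[None, :]
    n2 = 1.0 / (shares ** 2).sum(axis=0)
    occurrences = (y > 0).sum(axis=0)
    return pd.DataFrame({
        "optimum": optimum, "tolerance": tolerance,
        "hills_n2": n2, "occurrences": occurrences,
    }, index=pd.Index(taxa, name="taxon"))


#: alias documenting the domain name of the coefficient table
SpeciesCoefficients = pd.DataFrame


# ---------------------------------------------------------------------------
# Weighted averaging
# ---------------------------------------------------------------------------

@dataclass
class WAModel:
    coefficients: pd.DataFrame      # species_coefficients table
    deshrinking: str                # "inverse" | "classical"
    intercept: float
    slope: float
    input_unit: str
    env_transform: str | None = None

    @property
    def taxa(self) -> list:
        return self.coefficients.index.tolist()

    def raw_estimates(self, ct) -> np.ndarray:
        y, _, taxa, _ = _extract(ct, np.zeros(np.asarray(ct.values if
                                 isinstance(ct, CommunityTable) else ct).shape[0]))
        if taxa != self.taxa:
            raise ValueError("community taxa do not match model taxa; "
                             "harmonize_taxa first")
        totals = y.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("site(s) with zero abundance over the model's taxa")
        u = self.coefficients["optimum"].to_numpy()
        return (y @ u) / totals

    def predict(self, ct) -> np.ndarray:
        raw = self.raw_estimates(ct)
        if self.deshrinking == "inverse":
            return self.intercept + self.slope * raw
        # classical: raw = a + b x  =>  x = (raw - a) / b
        return (raw - self.intercept) / self.slope


def _weighted_lsq(x, y, w):
    """Weighted simple regression of y on x; returns (intercept, slope)."""
    w = w / w.sum()
    xm, ym = w @ x, w @ y
    var = w @ (x - xm) ** 2
    if var <= 1e-300:
        raise ValueError("zero variance of the regressor; deshrinking undefined")
    slope = (w @ ((x - xm) * (y - ym))) / var
    return ym - slope * xm, slope


def wa_calibrate(ct, x, deshrinking: str = "inverse",
                 env_transform: str | None = None) -> WAModel:
    """Fit a weighted-averaging model with deshrinking.

    Inverse deshrinking regresses observed x on the raw weighted-average
    estimates; classical deshrinking regresses the raw estimates on x and
    inverts the fitted line.  Both regressions are weighted by site
    abundance totals (the weighting under which WA with inverse deshrinking
    coincides with one-component WA-PLS).
    """
    if deshrinking not in ("inverse", "classical"):
        raise ValueError(f"unknown deshrinking {deshrinking!r}")
    y, x, taxa, _ = _extract(ct, x)
    if y.shape[0] < 3:
        raise ValueError("wa_calibrate requires at least 3 sites")
    coef = species_coefficients(ct, x)
    unit = ct.unit if isinstance(ct, CommunityTable) else "counts"
    model = WAModel(coefficients=coef, deshrinking=deshrinking,
                    intercept=0.0, slope=1.0, input_unit=unit,
                    env_transform=env_transform)
    y_kept = y[:, [i for i, t in enumerate(taxa) if t in set(coef.index)]]
    totals = y_kept.sum(axis=1)
    raw = (y_kept @ coef["optimum"].to_numpy()) / totals
    if deshrinking == "inverse":
        model.intercept, model.slope = _weighted_lsq(raw, x, totals)
    else:
        model.intercept, model.slope = _weighted_lsq(x, raw, totals)
    if not np.isfinite(model.slope) or model.slope == 0:
        raise ValueError("degenerate deshrinking slope")
    return model


# ---------------------------------------------------------------------------
# WA-PLS
# ---------------------------------------------------------------------------

@dataclass
class WAPLSModel:
    taxa: list
    x_wmean: float                      # site-total-weighted mean of x
    species_vectors: np.ndarray         # (R, m): per-component species score vectors
    constants: np.ndarray               # (R,): additive constants per component
    reg_coefficients: np.ndarray        # (R,): regression coefficients b_a
    input_unit: str
    env_transform: str | None = None
    truncated: bool = False

    @property
    def n_components(self) -> int:
        return len(self.reg_coefficients)

    def collapsed(self, n_components: int):
        """Collapsed per-taxon coefficients (beta0, beta) for r components."""
        r = self._check_r(n_components)
        b = self.reg_coefficients[:r]
        beta = b @ self.species_vectors[:r]
        beta0 = self.x_wmean + b @ self.constants[:r]
        return float(beta0), beta

    def _check_r(self, n_components):
        if not 1 <= n_components <= self.n_components:
            raise ValueError(f"component count {n_components} outside "
                             f"[1, {self.n_components}]")
        return int(n_components)

    def predict(self, ct, n_components: int, *, via: str = "collapsed") -> np.ndarray:
        """Predict x for harmonized samples.

        ``via='collapsed'`` uses the collapsed coefficient vector;
        ``via='components'`` walks the component-wise path (passive site
        scores per component, then the regression).  The two agree to
        numerical precision by construction.
        """
        y = ct.values if isinstance(ct, CommunityTable) else np.asarray(ct, dtype=float)
        taxa = ct.taxon_ids if isinstance(ct, CommunityTable) else list(range(y.shape[1]))
        if list(taxa) != list(self.taxa):
            raise ValueError("community taxa do not match model taxa; "
                             "harmonize_taxa first")
        totals = y.sum(axis=1)
        if (totals == 0).any():
            raise ValueError("site(s) with zero abundance over the model's taxa")
        r = self._check_r(n_components)
        if via == "collapsed":
            beta0, beta = self.collapsed(r)
            return beta0 + (y @ beta) / totals
        if via == "components":
            pred = np.full(y.shape[0], self.x_wmean)
            for a in range(r):
                z = (y @ self.species_vectors[a]) / totals + self.constants[a]
                pred = pred + self.reg_coefficients[a] * z
            return pred
        raise ValueError(f"unknown prediction route {via!r}")


def wapls_calibrate(ct, x, max_components: int,
                    env_transform: str | None = None) -> WAPLSModel:
    """Fit a WA-PLS model with up to *max_components* components."""
    y, x, taxa, _ = _extract(ct, x)
    y, taxa = _drop_empty_taxa(y, taxa)
    n, m = y.shape
    if max_components < 1:
        raise ValueError("max_components must be >= 1")
    rank_bound = min(n - 1, m)
    max_components = min(max_components, rank_bound)

    grand = y.sum()
    row_tot = y.sum(axis=1)
    col_tot = y.sum(axis=0)
    if (row_tot == 0).any():
        raise ValueError("site(s) with zero total abundance")
    r_w = row_tot / grand                      # site weights
    x_wmean = float(r_w @ x)
    xc = x - x_wmean

    species_vectors, constants, bs, zs = [], [], [], []
    target = xc.copy()
    truncated = False
    fitted = np.zeros(n)
    for _ in range(max_components):
        u = (y.T @ target) / col_tot           # species scores
        z = (y @ u) / row_tot                  # site scores
        const = 0.0
        # weighted centering
        mean_z = float(r_w @ z)
        z = z - mean_z
        const -= mean_z
        u_vec = u.copy()
        # weighted orthogonalization against previous components
        for u_prev, c_prev, z_prev in zip(species_vectors, constants, zs):
            gamma = float(r_w @ (z * z_prev))
            z = z - gamma * z_prev
            u_vec = u_vec - gamma * u_prev
            const -= gamma * c_prev
        # weighted standardization
        s2 = float(r_w @ z ** 2)
        if s2 < 1e-12:
            truncated = True
            warnings.warn("WA-PLS component numerically degenerate; truncating",
                          stacklevel=2)
            break
        s = np.sqrt(s2)
        z, u_vec, const = z / s, u_vec / s, const / s
        b = float(r_w @ (xc * z))              # weighted regression coefficient
        species_vectors.append(u_vec)
        constants.append(const)
        zs.append(z)
        bs.append(b)
        fitted = fitted + b * z
        target = xc - fitted
    if not species_vectors:
        raise ValueError("no usable WA-PLS component (degenerate data)")
    unit = ct.unit if isinstance(ct, CommunityTable) else "counts"
    return WAPLSModel(taxa=taxa, x_wmean=x_wmean,
                      species_vectors=np.asarray(species_vectors),
                      constants=np.asarray(constants),
                      reg_coefficients=np.asarray(bs),
                      input_unit=unit, env_transform=env_transform,
                      truncated=truncated)


# ---------------------------------------------------------------------------
# Performance statistics and cross-validation
# ---------------------------------------------------------------------------

@dataclass
class Performance:
    r2: float
    rmse: float
    mean_bias: float
    max_bias: float
    r2_defined: bool = True


def performance(observed, predicted) -> Performance:
    """r^2 (squared Pearson), RMSE, mean bias and max |bias|."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise ValueError("observed/predicted must be equal-length vectors (n >= 2)")
    if np.isnan(obs).any() or np.isnan(pred).any():
        raise ValueError("missing values in observed/predicted")
    err = pred - obs
    rmse = float(np.sqrt((err ** 2).mean()))
    if np.ptp(obs) == 0 or np.ptp(pred) == 0:
        return Performance(r2=np.nan, rmse=rmse, mean_bias=float(err.mean()),
                           max_bias=float(np.abs(err).max()), r2_defined=False)
    r, _ = stats.pearsonr(obs, pred)
    return Performance(r2=float(r ** 2), rmse=rmse, mean_bias=float(err.mean()),
                       max_bias=float(np.abs(err).max()))


@dataclass
class CrossValResult:
    stats: pd.DataFrame                 # indexed by component count
    loo_predictions: pd.DataFrame       # sites x component counts (col 0 = null model)
    selected: int
    method: str
    n_missing: int = 0


def _fit_predict_one(method, y_train, x_train, y_test, max_components):
    """Refit on the training block and predict the held-out rows.

    Returns an array of predictions per component count (index 0 is the
    zero-component null model: the weighted mean of the training x)."""
    keep = y_train.sum(axis=0) > 0
    y_train = y_train[:, keep]
    y_test = y_test[:, keep]
    test_tot = y_test.sum(axis=1)
    out = np.full((y_test.shape[0], max_components + 1), np.nan)
    if (test_tot == 0).any():
        return out
    w = y_train.sum(axis=1)
    out[:, 0] = (w @ x_train) / w.sum()
    if method == "wa":
        model = wa_calibrate(y_train, x_train)
        out[:, 1] = model.predict(y_test)
    else:
        model = wapls_calibrate(y_train, x_train, max_components)
        for r in range(1, model.n_components + 1):
            out[:, r] = model.predict(y_test, r)
    return out


def loo_crossval(ct, x, max_components: int, method: str = "wapls",
                 improvement: float = 0.05) -> CrossValResult:
    """Leave-one-out cross-validation of a WA or WA-PLS calibration.

    Each site is left out in turn, the model refit on the remainder (taxa
    that lose all abundance are re-screened), and the site predicted.  A
    left-out site sharing no taxa with the remainder is flagged missing and
    excluded from the statistics with a warning.
    """
    if method not in ("wa", "wapls"):
        raise ValueError(f"unknown method {method!r}")
    y, x, taxa, sites = _extract(ct, x)
    y, taxa = _drop_empty_taxa(y, taxa, warn=False)
    n = y.shape[0]
    if n < 5:
        raise ValueError("leave-one-out requires at least 5 sites")
    if method == "wa":
        max_components = 1

    loo = np.full((n, max_components + 1), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        loo[i] = _fit_predict_one(method, y[mask], x[mask], y[~mask],
                                  max_components)[0]

    missing = np.isnan(loo[:, 1])
    if missing.any():
        warnings.warn(f"{missing.sum()} site(s) unpredictable under LOO "
                      "(no shared taxa); excluded", stacklevel=2)
    ok = ~missing

    # apparent (full-data) fit
    if method == "wa":
        full = wa_calibrate(y, x)
        apparent = full.predict(y)[:, None]
        n_comp = 1
    else:
        full = wapls_calibrate(y, x, max_components)
        n_comp = full.n_components
        apparent = np.column_stack([full.predict(y, r) for r in range(1, n_comp + 1)])

    rows = []
    for r in range(1, n_comp + 1):
        app = performance(x, apparent[:, r - 1])
        cv = performance(x[ok], loo[ok, r])
        rows.append({"n_components": r, "rmse": app.rmse, "r2_apparent": app.r2,
                     "rmsep": cv.rmse, "r2_loo": cv.r2})
    table = pd.DataFrame(rows).set_index("n_components")
    selected = select_components(table, improvement=improvement)
    preds = pd.DataFrame(loo[:, :n_comp + 1], index=pd.Index(sites, name="site_id"),
                         columns=list(range(n_comp + 1)))
    return CrossValResult(stats=table, loo_predictions=preds, selected=selected,
                          method=method, n_missing=int(missing.sum()))


def select_components(cv, improvement: float = 0.05) -> int:
    """Smallest set of useful components under the 5%-improvement rule.

    Component r > 1 is useful when it lowers the cross-validated RMSEP by at
    least *improvement* (as a fraction) relative to the one-component model.
    Components must be consecutively useful; the first non-useful component
    stops the scan, and the default answer is 1.
    """
    rmsep = cv.stats["rmsep"] if isinstance(cv, CrossValResult) else cv["rmsep"]
    rmsep = np.asarray(rmsep, dtype=float)
    if len(rmsep) == 0:
        raise ValueError("empty cross-validation result")
    selected = 1
    for r in range(2, len(rmsep) + 1):
        reduction = (rmsep[0] - rmsep[r - 1]) / rmsep[0]
        if reduction >= improvement - 1e-12:
            selected = r
        else:
            break
    return selected


def component_significance(ct, x, max_components: int, *,
                           n_randomizations: int = 999, seed: int = 0) -> pd.Series:
    """Randomization p-value for each WA-PLS component's LOO improvement.

    For component r the paired per-site squared LOO errors of the r- and
    (r-1)-component models are compared (the 0-component reference predicts
    the weighted mean).  Under the null of no improvement the sign of each
    paired difference is exchangeable; p is the fraction of sign-flipped
    mean differences at least as negative as observed (+1/+1 correction).
    """
    cv = loo_crossval(ct, x, max_components, method="wapls")
    x = np.asarray(x, dtype=float)
    preds = cv.loo_predictions.to_numpy()
    ok = ~np.isnan(preds[:, 1])
    rng = np.random.default_rng(seed)
    pvals = {}
    for r in range(1, preds.shape[1] - 1 + 1):
        e_prev = (preds[ok, r - 1] - x[ok]) ** 2
        e_curr = (preds[ok, r] - x[ok]) ** 2
        diff = e_curr - e_prev
        obs = diff.mean()
        signs = rng.choice([-1.0, 1.0], size=(n_randomizations, len(diff)))
        randomized = (signs * diff).mean(axis=1)
        count = int((randomized <= obs + 1e-15).sum())
        pvals[r] = (1 + count) / (1 + n_randomizations)
    return pd.Series(pvals, name="p_value").rename_axis("n_components")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def model_to_json(model) -> str:
    """Serialize a WAModel or WAPLSModel to a JSON string."""
    if isinstance(model, WAModel):
        payload = {
            "kind": "wa",
            "taxa": list(model.taxa),
            "deshrinking": model.deshrinking,
            "intercept": model.intercept,
            "slope": model.slope,
            "input_unit": model.input_unit,
            "env_transform": model.env_transform,
            "coefficients": {
                col: model.coefficients[col].tolist()
                for col in ("optimum", "tolerance", "hills_n2")
            },
            "occurrences": model.coefficients["occurrences"].astype(int).tolist(),
        }
    elif isinstance(model, WAPLSModel):
        payload = {
            "kind": "wapls",
            "taxa": list(model.taxa),
            "x_wmean": model.x_wmean,
            "species_vectors": model.species_vectors.tolist(),
            "constants": model.constants.tolist(),
            "reg_coefficients": model.reg_coefficients.tolist(),
            "input_unit": model.input_unit,
            "env_transform": model.env_transform,
            "truncated": model.truncated,
        }
    else:
        raise TypeError(f"cannot serialize {type(model).__name__}")
    return json.dumps(payload, sort_keys=True)


def model_from_json(text: str):
    """Inverse of :func:`model_to_json`."""
    payload = json.loads(text)
    if payload["kind"] == "wa":
        coef = pd.DataFrame(payload["coefficients"],
                            index=pd.Index(payload["taxa"], name="taxon"))
        coef["occurrences"] = payload["occurrences"]
        return WAModel(coefficients=coef, deshrinking=payload["deshrinking"],
                       intercept=payload["intercept"], slope=payload["slope"],
                       input_unit=payload["input_unit"],
                       env_transform=payload["env_transform"])
    if payload["kind"] == "wapls":
        return WAPLSModel(taxa=payload["taxa"], x_wmean=payload["x_wmean"],
                          species_vectors=np.asarray(payload["species_vectors"]),
                          constants=np.asarray(payload["constants"]),
                          reg_coefficients=np.asarray(payload["reg_coefficients"]),
                          input_unit=payload["input_unit"],
                          env_transform=payload["env_transform"],
                          truncated=payload["truncated"])
    raise ValueError(f"unknown model kind {payload.get('kind')!r}")
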