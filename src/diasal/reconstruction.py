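"""Apply calibrations to independent data and compare seasonal models.

A trained model infers log10 chloride from a new assemblage; the
reconstruction layer handles the preprocessing the model expects
(percentages, square root), taxon harmonization, back-transformation to
mg/l, and the validation diagnostics: observed-vs-inferred r^2 and RMSEP,
the residual-versus-observed regression (whose negative slope is the
signature of the edge effect of averaging-based calibrations), and
bias-band fractions in concentration units.

:func:`compare_seasonal_models` runs the whole experiment of interest:
fit spring, summer, autumn and pooled all-season models with identical
settings, cross-validate each, and score each against the independent
validation set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import calibration as cal
from .datasets import (CommunityTable, EnvironmentTable, coverage_filter,
                       harmonize_taxa, relative_abundance, sqrt_transform)
from .ordination import lambda_ratio

__all__ = [
    "Reconstruction",
    "ValidationDiagnostics",
    "reconstruct",
    "validation_diagnostics",
    "compare_seasonal_models",
    "preprocess_counts",
]

#: |prediction - observation| bands (mg/l) reported by the diagnostics:
#: "good" reconstructions and "grossly wrong" reconstructions
DEFAULT_BIAS_BANDS = ((0.0, 500.0), (2000.0, 4000.0))


def preprocess_counts(ct: CommunityTable, coverage: float | None = 0.98):
    """Counts -> percentages -> coverage filter -> square root.

    Returns the transformed table and the list of taxa dropped by the
    coverage screen (empty when ``coverage`` is None).
    """
    if ct.unit == "counts":
        ct = relative_abundance(ct)
    dropped = []
    if coverage is not None:
        ct, dropped = coverage_filter(ct, coverage)
    if ct.unit == "percent":
        ct = sqrt_transform(ct)
    return ct, dropped


@dataclass
class Reconstruction:
    """Per-site inferred salinity from one model."""

    table: pd.DataFrame         # predicted (transformed), predicted_mgl, matched_fraction
    model_id: str
    n_components: int | None
    env_transform: str | None

    @property
    def predicted(self) -> pd.Series:
        return self.table["predicted"]

    @property
    def predicted_mgl(self) -> pd.Series:
        return self.table["predicted_mgl"]


def reconstruct(model, ct: CommunityTable, *, components: int | None = None,
                coverage: float | None = None, model_id: str = "model") -> Reconstruction:
    """Apply a trained WA or WA-PLS model to an independent community table.

    The table is run through the model's preprocessing (percentages and
    square root when the model was trained on ``sqrt_percent``), harmonized
    against the model's taxa, and predicted with the requested component
    count (WA-PLS only; defaults to the model's full component set).  A
    warning is raised when any site retains less than half of its abundance
    after harmonization.
    """
    if isinstance(model, cal.WAPLSModel):
        n_comp = model.n_components if components is None else components
        if not 1 <= n_comp <= model.n_components:
            raise ValueError(f"component count {n_comp} exceeds the model's "
                             f"{model.n_components}")
    elif isinstance(model, cal.WAModel):
        if components not in (None, 1):
            raise ValueError("WA models have a single component")
        n_comp = 1
    else:
        raise TypeError(f"unsupported model type {type(model).__name__}")

    work = ct
    if model.input_unit == "sqrt_percent":
        work, _ = preprocess_counts(work, coverage)
    elif model.input_unit == "percent" and work.unit == "counts":
        work = relative_abundance(work)

    harmonized, report = harmonize_taxa(model.taxa, work)
    low = report.matched_abundance_fraction[report.matched_abundance_fraction < 0.5]
    if len(low):
        warnings.warn(f"{len(low)} site(s) retain <50% of abundance after "
                      "harmonization", stacklevel=2)

    if isinstance(model, cal.WAPLSModel):
        pred = model.predict(harmonized, n_comp)
    else:
        pred = model.predict(harmonized)

    if model.env_transform == "log10":
        pred_mgl = 10.0 ** pred
    elif model.env_transform in (None, "raw"):
        pred_mgl = pred.copy()
    else:
        raise ValueError(f"unknown env transform {model.env_transform!r}")

    table = pd.DataFrame({
        "predicted": pred,
        "predicted_mgl": pred_mgl,
        "matched_fraction": report.matched_abundance_fraction.to_numpy(),
    }, index=harmonized.data.index)
    return Reconstruction(table=table, model_id=model_id, n_components=n_comp,
                          env_transform=model.env_transform)


@dataclass
class ValidationDiagnostics:
    r2: float
    rmsep: float
    residual_slope: float
    residual_intercept: float
    bias_band_fractions: dict        # (lo, hi) mg/l -> fraction of sites
    residuals: pd.Series             # predicted - observed, transformed units


def validation_diagnostics(rec: Reconstruction, observed_mgl,
                           bands=DEFAULT_BIAS_BANDS) -> ValidationDiagnostics:
    """Score a reconstruction against observed chloride (mg/l).

    Statistics are computed in the calibration's transformed units
    (log10 mg/l when the model was trained on log10 chloride); the bias
    bands are evaluated on absolute errors in mg/l.  Residuals follow the
    convention predicted - observed, so under-estimation at the high end
    of the gradient appears as a negative residual-versus-observed slope.
    """
    obs_mgl = pd.Series(np.asarray(observed_mgl, dtype=float),
                        index=rec.table.index if not isinstance(observed_mgl, pd.Series)
                        else observed_mgl.index)
    if len(obs_mgl) != len(rec.table):
        raise ValueError("observed values do not match reconstruction length")
    obs_mgl = obs_mgl.reindex(rec.table.index)
    if obs_mgl.isna().any():
        raise ValueError("observed values missing for some reconstructed sites")
    if (obs_mgl <= 0).any():
        raise ValueError("observed chloride must be positive")

    obs = np.log10(obs_mgl.to_numpy()) if rec.env_transform == "log10" \
        else obs_mgl.to_numpy()
    pred = rec.predicted.to_numpy()
    perf = cal.performance(obs, pred)
    residuals = pred - obs
    slope, intercept = np.polyfit(obs, residuals, 1) if np.ptp(obs) > 0 else (0.0, float(residuals.mean()))

    abs_err_mgl = np.abs(rec.predicted_mgl.to_numpy() - obs_mgl.to_numpy())
    fractions = {tuple(b): float(((abs_err_mgl >= b[0]) & (abs_err_mgl < b[1])).mean())
                 for b in bands}
    return ValidationDiagnostics(
        r2=perf.r2, rmsep=perf.rmse, residual_slope=float(slope),
        residual_intercept=float(intercept), bias_band_fractions=fractions,
        residuals=pd.Series(residuals, index=rec.table.index, name="residual"))


@dataclass
class SeasonComparison:
    table: pd.DataFrame
    models: dict
    crossval: dict
    reconstructions: dict
    diagnostics: dict
    coefficients: dict


def compare_seasonal_models(train_ct: CommunityTable, train_et: EnvironmentTable,
                            valid_ct: CommunityTable | None = None,
                            valid_et: EnvironmentTable | None = None, *,
                            target: str = "Cl", max_components: int = 3,
                            improvement: float = 0.05, coverage: float | None = 0.98,
                            n2_min: float | None = None, min_sites: int = 5,
                            bands=DEFAULT_BIAS_BANDS) -> SeasonComparison:
    """Fit and score single-season and all-season calibrations.

    For each of spring, summer, autumn and the pooled all-season dataset:
    preprocess with identical settings, cross-validate a WA-PLS model and
    select its component count, compute the lambda1/lambda2 diagnostic,
    and (when a validation pair is supplied) reconstruct the independent
    dataset and attach the validation diagnostics.  Seasons with fewer than
    *min_sites* sites are skipped with a warning.

    The environmental target is taken from *train_et* in mg/l and
    log10-transformed internally.
    """
    if train_ct.season is None:
        raise ValueError("training community lacks season labels")
    if target not in train_et.variables:
        raise ValueError(f"target {target!r} not in the environment table")

    model_sets = {s: [site for site in train_ct.site_ids
                      if train_ct.season.loc[site] == s]
                  for s in pd.unique(train_ct.season)}
    model_sets["all"] = list(train_ct.site_ids)

    already_log = train_et.transform_state.get(target) == "log10"
    rows, models, crossval, recs, diags, coefs = [], {}, {}, {}, {}, {}
    for model_id, sites in model_sets.items():
        if len(sites) < min_sites:
            warnings.warn(f"model {model_id!r} skipped: only {len(sites)} sites",
                          stacklevel=2)
            continue
        sub_ct = train_ct.subset_sites(sites)
        sub_env = train_et.subset_sites(sites).column(target).to_numpy(dtype=float)
        x = sub_env if already_log else np.log10(sub_env)
        prepped, _ = preprocess_counts(sub_ct, coverage)
        if n2_min is not None:
            coef0 = cal.species_coefficients(prepped, x)
            keep = coef0.index[coef0["hills_n2"] >= n2_min]
            prepped = CommunityTable(prepped.data[list(keep)], unit=prepped.unit,
                                     season=prepped.season, location=prepped.location)

        cv = cal.loo_crossval(prepped, x, max_components, method="wapls",
                              improvement=improvement)
        n_comp = cv.selected
        model = cal.wapls_calibrate(prepped, x, max_components,
                                    env_transform="log10" if not already_log else None)
        lam = lambda_ratio(prepped, pd.Series(x, name=target))
        coefs[model_id] = cal.species_coefficients(prepped, x)
        models[model_id] = model
        crossval[model_id] = cv

        row = {
            "model": model_id,
            "n_sites": len(sites),
            "n_components": n_comp,
            "r2_apparent": cv.stats.loc[n_comp, "r2_apparent"],
            "r2_loo": cv.stats.loc[n_comp, "r2_loo"],
            "rmse": cv.stats.loc[n_comp, "rmse"],
            "rmsep_loo": cv.stats.loc[n_comp, "rmsep"],
            "lambda1": lam["lambda1"], "lambda2": lam["lambda2"],
            "lambda_ratio": lam["ratio"],
        }
        if valid_ct is not None and valid_et is not None:
            rec = reconstruct(model, valid_ct, components=n_comp,
                              coverage=coverage, model_id=model_id)
            obs_raw = valid_et.column(target)
            obs_mgl = 10.0 ** obs_raw if valid_et.transform_state.get(target) == "log10" \
                else obs_raw
            diag = validation_diagnostics(rec, obs_mgl, bands=bands)
            recs[model_id] = rec
            diags[model_id] = diag
            row.update({
                "validation_r2": diag.r2,
                "validation_rmsep": diag.rmsep,
                "residual_slope": diag.residual_slope,
            })
            for band, frac in diag.bias_band_fractions.items():
                row[f"frac_abs_err_{int(band[0])}_{int(band[1])}"] = frac
        rows.append(row)

    table = pd.DataFrame(rows).set_index("model")
    return SeasonComparison(table=table, models=models, crossval=crossval,
                            reconstructions=recs, diagnostics=diags,
                            coefficients=coefs)
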