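"""Figure-and-table report for a fitted cohort.

Renders the CL histogram overlaid with the three weighted component
curves and the total mixture density, marks the derived cut-points, and
tabulates the parameter estimates with their bootstrap CIs.  Everything
plotted is also written to a machine-readable JSON next to the figure.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .bootstrap import BootstrapSummary
from .classify import ClassificationTable
from .em import FitResult
from .mixture import as_centiloid_array, component_pdfs
from .params import PARAM_NAMES

_CURVE_PAD_SD = 4.0


def density_curves(fit: FitResult, x: np.ndarray, n_grid: int = 800) -> dict:
    """Weighted component curves and the total density on a plotting grid."""
    p = fit.params
    lo = min(float(np.min(x)), p.mu_neg - _CURVE_PAD_SD * p.sigma_neg)
    hi = max(float(np.max(x)), p.mu_pos + _CURVE_PAD_SD * p.sigma_pos)
    grid = np.linspace(lo, hi, n_grid)
    comps = component_pdfs(grid, p, fit.config)
    weights = np.array([p.pi_neg, p.pi_int, p.pi_pos])
    if not fit.config.include_intermediate:
        weights[1] = 0.0
    weighted = comps * weights
    return {
        "grid": grid,
        "negative": weighted[:, 0],
        "intermediate": weighted[:, 1],
        "positive": weighted[:, 2],
        "total": weighted.sum(axis=1),
    }


def render_report(
    data,
    fit: FitResult,
    summary: BootstrapSummary | None,
    classification: ClassificationTable | None,
    out_path,
) -> dict[str, Path]:
    """Write ``report.png`` and ``report.json`` under ``out_path``.

    Returns the paths written.  All inputs must refer to the same cohort.
    """
    out_dir = Path(out_path)
    out_dir.mkdir(parents=True, exist_ok=True)
    x = as_centiloid_array(data)
    curves = density_curves(fit, x)
    cuts = classification.cut_points if classification is not None else []

    fig, ax = plt.subplots(figsize=(7.5, 4.5))
    ax.hist(x, bins=60, density=True, color="0.85", edgecolor="0.6", label="scans")
    ax.plot(curves["grid"], curves["negative"], color="tab:blue", label="negative")
    if fit.config.include_intermediate:
        ax.plot(
            curves["grid"], curves["intermediate"], color="tab:orange",
            label="intermediate",
        )
    ax.plot(curves["grid"], curves["positive"], color="tab:red", label="positive")
    ax.plot(curves["grid"], curves["total"], color="k", lw=1.5, label="mixture")
    for c in cuts:
        ax.axvline(c, color="0.3", ls="--", lw=1)
    ax.set_xlabel("Centiloid")
    ax.set_ylabel("density")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    png_path = out_dir / "report.png"
    fig.savefig(png_path, dpi=150)
    plt.close(fig)

    payload = {
        "schema_version": 1,
        "n_scans": int(x.size),
        "params": fit.params.as_dict(),
        "loglik": float(fit.loglik),
        "converged": bool(fit.converged),
        "cut_points": [float(c) for c in cuts],
        "curves": {k: np.asarray(v).tolist() for k, v in curves.items()},
    }
    if summary is not None:
        payload["ci"] = {
            name: {"lower": summary.ci[name][0], "upper": summary.ci[name][1]}
            for name in PARAM_NAMES
        }
        payload["B_requested"] = summary.B_requested
        payload["B_succeeded"] = summary.B_succeeded
    if classification is not None:
        counts = classification.table["label"].value_counts().to_dict()
        payload["label_counts"] = {k: int(v) for k, v in counts.items()}
    json_path = out_dir / "report.json"
    json_path.write_text(json.dumps(payload, indent=1))
    return {"png": png_path, "json": json_path}
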