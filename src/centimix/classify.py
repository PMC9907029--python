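"""Per-scan classification and cut-point derivation.

Posterior component probabilities ("responsibilities") follow directly
from the weighted component densities; the label is the posterior argmax.
Cut-points are the CL values where adjacent posteriors cross, searched by
bisection inside the open interval (mu_neg, mu_pos) — crossings outside
that interval are tail artifacts and are not reported.  When the
intermediate proportion is (near) zero a boundary may have no crossing;
it is then reported absent rather than fabricated, and in two-component
mode the single negative/positive crossing is reported instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .mixture import as_centiloid_array, component_pdfs
from .params import FitConfig, MixtureParams

_LABELS = np.array(["negative", "intermediate", "positive"])


@dataclass
class ClassificationTable:
    """Per-scan posteriors and labels plus the derived cut-points (CL).

    ``cut_neg_int`` / ``cut_int_pos`` are None when the corresponding
    posterior crossing does not exist inside (mu_neg, mu_pos).  In
    two-component mode ``cut_neg_pos`` holds the single crossing.
    """

    table: pd.DataFrame
    cut_neg_int: float | None
    cut_int_pos: float | None
    cut_neg_pos: float | None = None

    @property
    def cut_points(self) -> list[float]:
        return sorted(
            c for c in (self.cut_neg_int, self.cut_int_pos, self.cut_neg_pos)
            if c is not None
        )


def posterior_probs(
    x, params: MixtureParams, config: FitConfig | None = None
) -> np.ndarray:
    """Posterior component probabilities, shape (n, 3); rows sum to 1."""
    cfg = config or FitConfig()
    comps = component_pdfs(x, params, cfg)
    weights = np.array([params.pi_neg, params.pi_int, params.pi_pos])
    if not cfg.include_intermediate:
        weights[1] = 0.0
    weighted = comps * weights
    totals = np.maximum(weighted.sum(axis=1), 1e-300)
    return weighted / totals[:, None]


def _crossing(diff, lo: float, hi: float, n_scan: int = 512) -> float | None:
    """First sign change of ``diff`` from + to - on (lo, hi), refined by
    bisection; None when no such change exists."""
    xs = np.linspace(lo, hi, n_scan)
    vals = diff(xs)
    sign = np.sign(vals)
    for i in range(len(xs) - 1):
        if sign[i] > 0 and sign[i + 1] < 0:
            return float(brentq(lambda t: float(diff(np.array([t]))[0]), xs[i], xs[i + 1]))
        if sign[i] > 0 and sign[i + 1] == 0:
            return float(xs[i + 1])
    return None


def find_cut_points(
    params: MixtureParams, config: FitConfig | None = None
) -> dict[str, float | None]:
    """CL values where adjacent weighted component densities cross.

    Equal weighted densities is the same condition as equal posteriors,
    since the posteriors share the total density as denominator.
    """
    cfg = config or FitConfig()
    lo, hi = params.mu_neg, params.mu_pos
    eps = 1e-9 * max(1.0, hi - lo)
    lo, hi = lo + eps, hi - eps

    def weighted(xs: np.ndarray) -> np.ndarray:
        comps = component_pdfs(xs, params, cfg)
        w = np.array([params.pi_neg, params.pi_int, params.pi_pos])
        if not cfg.include_intermediate:
            w[1] = 0.0
        return comps * w

    if cfg.include_intermediate and params.pi_int > 0:
        cut_ni = _crossing(lambda xs: weighted(xs)[:, 0] - weighted(xs)[:, 1], lo, hi)
        # scan from the positive side: last +->- crossing of (int - pos)
        # seen from the left equals first crossing of (pos - int) from the
        # right; reuse the same scanner on the reversed axis
        cut_ip = _crossing(
            lambda xs: weighted(lo + hi - xs)[:, 2] - weighted(lo + hi - xs)[:, 1],
            lo,
            hi,
        )
        cut_ip = None if cut_ip is None else lo + hi - cut_ip
        return {"neg_int": cut_ni, "int_pos": cut_ip, "neg_pos": None}
    cut_np = _crossing(lambda xs: weighted(xs)[:, 0] - weighted(xs)[:, 2], lo, hi)
    return {"neg_int": None, "int_pos": None, "neg_pos": cut_np}


def classify(
    data,
    params: MixtureParams,
    config: FitConfig | None = None,
    collapse_intermediate: bool = False,
) -> ClassificationTable:
    """Label every scan by posterior argmax and report the cut-points.

    ``collapse_intermediate=True`` folds intermediate calls into
    negative/positive by the side of the midpoint between the two
    cut-points (binary positivity reading).
    """
    cfg = config or FitConfig()
    params.validate(sigma_floor=0.0)
    x = as_centiloid_array(data)
    post = posterior_probs(x, params, cfg)
    labels = _LABELS[np.argmax(post, axis=1)]
    cuts = find_cut_points(params, cfg)
    if collapse_intermediate and cfg.include_intermediate:
        usable = [c for c in (cuts["neg_int"], cuts["int_pos"]) if c is not None]
        split = float(np.mean(usable)) if usable else 0.5 * (params.mu_neg + params.mu_pos)
        mid = labels == "intermediate"
        labels = labels.copy()
        labels[mid] = np.where(x[mid] < split, "negative", "positive")
    out = pd.DataFrame(
        {
            "centiloid": x,
            "p_neg": post[:, 0],
            "p_int": post[:, 1],
            "p_pos": post[:, 2],
            "label": labels,
        }
    )
    if hasattr(data, "columns") and "subject_id" in data.columns:
        out.insert(0, "subject_id", np.asarray(data["subject_id"]))
    return ClassificationTable(
        table=out,
        cut_neg_int=cuts["neg_int"],
        cut_int_pos=cuts["int_pos"],
        cut_neg_pos=cuts["neg_pos"],
    )
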