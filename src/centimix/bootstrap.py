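"""Nonparametric bootstrap around the mixture fit.

Each replicate resamples the cohort with replacement, draws a fresh random
initialization, runs a single EM fit, and stores the relabeled parameter
vector.  Percentile 95% confidence intervals are the empirical 2.5th and
97.5th percentiles of the converged replicates; non-converged replicates
are excluded and counted.  Per-replicate RNG streams are derived from the
master seed and the replicate index, so results are reproducible and
independent of execution order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em import FitResult, _em_single, fit_em, random_init
from .mixture import as_centiloid_array
from .params import FitConfig, MixtureParams, PARAM_NAMES


@dataclass
class BootstrapSummary:
    """Full-data point fit plus per-parameter percentile CIs.

    ``replicates`` holds the converged replicate parameter vectors (rows in
    ``PARAM_NAMES`` order); it is kept in memory for diagnostics but not
    serialized.
    """

    point: MixtureParams
    ci: dict[str, tuple[float, float]]
    B_requested: int
    B_succeeded: int
    seed: int
    config: FitConfig
    unreliable: bool = False
    replicates: np.ndarray | None = None
    point_fit: FitResult | None = None

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "point": self.point.as_dict(),
            "ci": {k: {"lower": lo, "upper": hi} for k, (lo, hi) in self.ci.items()},
            "B_requested": int(self.B_requested),
            "B_succeeded": int(self.B_succeeded),
            "seed": int(self.seed),
            "unreliable": bool(self.unreliable),
            "config": self.config.as_dict(),
        }


def percentile_ci(samples, level: float = 0.95) -> tuple[float, float]:
    """Empirical percentile interval with linear interpolation.

    For ``level=0.95`` these are the 2.5th and 97.5th percentiles;
    invariant under permutation of the input.
    """
    arr = np.asarray(samples, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("percentile_ci requires at least one sample")
    if not np.all(np.isfinite(arr)):
        raise ValueError("percentile_ci requires finite samples")
    if not 0.0 < level < 1.0:
        raise ValueError(f"level={level} must lie in (0, 1)")
    tail = 100.0 * (1.0 - level) / 2.0
    lo, hi = np.percentile(arr, [tail, 100.0 - tail])
    return float(lo), float(hi)


def summarize_replicates(
    point: FitResult,
    replicates: np.ndarray,
    B_requested: int,
    seed: int,
    level: float = 0.95,
) -> BootstrapSummary:
    """Assemble a summary from a stack of replicate parameter vectors."""
    B_succ = int(replicates.shape[0])
    ci = {
        name: percentile_ci(replicates[:, j], level)
        for j, name in enumerate(PARAM_NAMES)
    }
    return BootstrapSummary(
        point=point.params,
        ci=ci,
        B_requested=B_requested,
        B_succeeded=B_succ,
        seed=seed,
        config=point.config,
        unreliable=B_succ < 0.5 * B_requested,
        replicates=replicates,
        point_fit=point,
    )


def bootstrap_fit(
    data,
    B: int,
    config: FitConfig | None = None,
    seed: int = 0,
    level: float = 0.95,
    resample: bool = True,
    reinit: bool = True,
) -> BootstrapSummary:
    """Bootstrap the mixture fit and return percentile CIs.

    ``resample`` and ``reinit`` exist as test hooks: with both disabled
    every replicate repeats the identical fit, so all intervals collapse
    onto the point estimate.
    """
    if B < 1:
        raise ValueError(f"B={B} must be >= 1")
    cfg = (config or FitConfig()).validate()
    x = as_centiloid_array(data)
    point = fit_em(x, cfg)
    if not resample and not reinit:
        # zero-spread test hook: every replicate repeats the point fit
        replicates = np.tile(point.params.as_array(), (B, 1))
        return summarize_replicates(point, replicates, B, seed, level)
    rows = []
    for b in range(B):
        rng = np.random.default_rng([seed, b])
        xb = x[rng.integers(0, x.size, x.size)] if resample else x
        try:
            init = random_init(xb, rng, cfg) if reinit else point.params
            rep = _em_single(xb, init, cfg)
        except (ValueError, FloatingPointError):
            continue
        if rep.converged:
            rows.append(rep.params.as_array())
    if not rows:
        raise RuntimeError("no bootstrap replicate converged")
    replicates = np.vstack(rows)
    return summarize_replicates(point, replicates, B, seed, level)


def compare_strata(
    summary_a: BootstrapSummary, summary_b: BootstrapSummary
) -> dict:
    """Per-parameter CI-overlap verdicts between two strata.

    Two fits are comparable only under the same model settings.  Returns a
    mapping with one boolean per parameter plus ``overall`` (all overlap),
    the criterion used to declare tracer-equivalent estimates.
    """
    if summary_a.config.model_key() != summary_b.config.model_key():
        raise ValueError(
            "cannot compare strata fitted under different model configs: "
            f"{summary_a.config.model_key()} vs {summary_b.config.model_key()}"
        )
    verdicts: dict = {}
    for name in PARAM_NAMES:
        lo_a, hi_a = summary_a.ci[name]
        lo_b, hi_b = summary_b.ci[name]
        verdicts[name] = bool(max(lo_a, lo_b) <= min(hi_a, hi_b))
    verdicts["overall"] = all(verdicts[name] for name in PARAM_NAMES)
    return verdicts
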