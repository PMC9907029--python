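"""Constrained EM for the three-part mixture, with random re-initialization.

The M-step is constrained in one deliberate way: the intermediate component
has no parameters of its own, so the Gaussian means and SDs are updated
from the Gaussian responsibilities only, the intermediate density is then
recomputed from the updated Gaussians, and the intermediate component
enters the M-step only through the proportion update.  Because of the tie
this update is not a textbook EM step and monotonic ascent of the
log-likelihood is not guaranteed in theory; the full trace is recorded and
any decrease is counted in the result diagnostics rather than asserted
away.

The intermediate density is expensive (a quadrature per evaluation), so it
is recomputed once per M-step on a fixed 0.5-CL grid spanning the data and
linearly interpolated at the data points; at that step the interpolation
error is negligible against the density scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mixture import _norm_pdf, as_centiloid_array, intermediate_pdf_grid
from .params import FitConfig, MixtureParams

#: grid step (CL) for the cached intermediate density
GRID_STEP = 0.5
_MIN_SCANS = 10
_DENS_FLOOR = 1e-300


@dataclass
class FitResult:
    """Outcome of one EM fit (best of ``n_starts`` runs).

    ``responsibilities`` holds the per-scan posterior component
    probabilities (columns: negative, intermediate, positive) under the
    returned parameters; each row sums to 1.
    """

    params: MixtureParams
    loglik: float
    converged: bool
    n_iter: int
    responsibilities: np.ndarray
    config: FitConfig
    loglik_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_sigma_clamps: int = 0
    monotone_violations: int = 0

    def as_dict(self) -> dict:
        return {
            "schema_version": 1,
            "params": self.params.as_dict(),
            "loglik": float(self.loglik),
            "converged": bool(self.converged),
            "n_iter": int(self.n_iter),
            "n_sigma_clamps": int(self.n_sigma_clamps),
            "monotone_violations": int(self.monotone_violations),
            "config": self.config.as_dict(),
        }


def random_init(data, rng_seed, config: FitConfig | None = None) -> MixtureParams:
    """Draw a random starting point from the sample's empirical range.

    Means are drawn uniformly on the two halves of the data range split at
    the median (so the ordering ``mu_neg < mu_pos`` holds by construction),
    SDs uniformly on [0.25, 1] times the sample SD floored at the
    configured ``sigma_floor``, and proportions from the flat Dirichlet on
    the simplex (over two components when the intermediate part is
    excluded).

    ``rng_seed`` may be an integer seed or a ``numpy.random.Generator``.
    """
    cfg = (config or FitConfig()).validate()
    x = as_centiloid_array(data)
    if x.size < _MIN_SCANS:
        raise ValueError(f"random_init requires >= {_MIN_SCANS} scans, got {x.size}")
    lo, med, hi = float(np.min(x)), float(np.median(x)), float(np.max(x))
    if lo == hi:
        raise ValueError("degenerate sample: all centiloid values identical")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    mu_neg = rng.uniform(lo, med)
    mu_pos = rng.uniform(med, hi)
    while mu_pos <= mu_neg:  # guard the measure-zero boundary draw
        mu_pos = rng.uniform(med, hi)
    sd = float(np.std(x))
    sigma_neg = max(rng.uniform(0.25, 1.0) * sd, cfg.sigma_floor)
    sigma_pos = max(rng.uniform(0.25, 1.0) * sd, cfg.sigma_floor)
    if cfg.include_intermediate:
        pi = rng.dirichlet(np.ones(3))
        pi_neg, pi_int, pi_pos = (float(p) for p in pi)
    else:
        pi_neg, pi_pos = (float(p) for p in rng.dirichlet(np.ones(2)))
        pi_int = 0.0
    return MixtureParams(
        pi_neg=pi_neg, pi_int=pi_int, pi_pos=pi_pos,
        mu_neg=mu_neg, mu_pos=mu_pos,
        sigma_neg=sigma_neg, sigma_pos=sigma_pos,
    ).validate(sigma_floor=0.0)


def _weighted_densities(
    x: np.ndarray,
    params: MixtureParams,
    cfg: FitConfig,
    grid: np.ndarray | None,
) -> np.ndarray:
    """Weighted component densities at the data points, shape (n, 3)."""
    out = np.empty((x.size, 3))
    out[:, 0] = params.pi_neg * _norm_pdf(x, params.mu_neg, params.sigma_neg)
    if cfg.include_intermediate and params.pi_int > 0:
        g_grid = intermediate_pdf_grid(grid, params, cfg.quad_nodes)
        out[:, 1] = params.pi_int * np.interp(x, grid, g_grid)
    else:
        out[:, 1] = 0.0
    out[:, 2] = params.pi_pos * _norm_pdf(x, params.mu_pos, params.sigma_pos)
    return out


def _em_single(
    x: np.ndarray, init: MixtureParams, cfg: FitConfig
) -> FitResult:
    """Run EM from one starting point."""
    grid = None
    if cfg.include_intermediate:
        grid = np.arange(float(np.min(x)), float(np.max(x)) + GRID_STEP, GRID_STEP)
    params = init
    trace: list[float] = []
    n_clamps = 0
    violations = 0
    converged = False
    prev_ll = -np.inf
    resp = np.full((x.size, 3), np.nan)
    it = 0
    for it in range(1, cfg.max_iter + 1):
        # E-step
        weighted = _weighted_densities(x, params, cfg, grid)
        totals = np.maximum(weighted.sum(axis=1), _DENS_FLOOR)
        resp = weighted / totals[:, None]
        ll = float(np.sum(np.log(totals)))
        if trace and ll < trace[-1] - 1e-8 * max(1.0, abs(trace[-1])):
            violations += 1
        trace.append(ll)
        if np.isfinite(prev_ll):
            if abs(ll - prev_ll) < cfg.rel_tol * max(1.0, abs(prev_ll)):
                converged = True
                break
        prev_ll = ll
        # M-step: proportions from all three responsibilities
        pi = resp.mean(axis=0)
        if not cfg.include_intermediate:
            pi[1] = 0.0
            pi = pi / pi.sum()
        # Gaussian moments from the Gaussian responsibilities only
        new_mu, new_sd = [], []
        for col, floor_sd in ((0, cfg.sigma_floor), (2, cfg.sigma_floor)):
            w = resp[:, col]
            wsum = max(float(w.sum()), 1e-12)
            mu = float(np.dot(w, x) / wsum)
            var = float(np.dot(w, (x - mu) ** 2) / wsum)
            sd = np.sqrt(max(var, 0.0))
            if sd < floor_sd:
                sd = floor_sd
                n_clamps += 1
            new_mu.append(mu)
            new_sd.append(sd)
        params = MixtureParams(
            pi_neg=float(pi[0]), pi_int=float(pi[1]), pi_pos=float(pi[2]),
            mu_neg=new_mu[0], mu_pos=new_mu[1],
            sigma_neg=new_sd[0], sigma_pos=new_sd[1],
        )
        # the tied intermediate density is implicitly recomputed from the
        # updated Gaussians at the next E-step
    result = FitResult(
        params=params,
        loglik=trace[-1] if trace else -np.inf,
        converged=converged,
        n_iter=it,
        responsibilities=resp,
        config=cfg,
        loglik_trace=np.asarray(trace),
        n_sigma_clamps=n_clamps,
        monotone_violations=violations,
    )
    return _canonicalize(result)


def _canonicalize(result: FitResult) -> FitResult:
    """Enforce mu_neg < mu_pos by relabeling (never rejecting)."""
    if result.params.mu_neg > result.params.mu_pos:
        result.params = result.params.swapped()
        result.responsibilities = result.responsibilities[:, [2, 1, 0]]
    elif result.params.mu_neg == result.params.mu_pos:
        result.params = result.params.canonical()
    return result


def fit_em(data, config: FitConfig | None = None) -> FitResult:
    """Fit the mixture by EM over ``n_starts`` random initializations.

    Returns the best-log-likelihood result, relabeled so that
    ``mu_neg < mu_pos``.  Starts that error out (degenerate resamples) are
    dropped; if every start fails to converge the best-so-far result is
    returned with ``converged=False`` instead of raising, so that bootstrap
    loops never abort on rare bad replicates.
    """
    cfg = (config or FitConfig()).validate()
    x = as_centiloid_array(data)
    if x.size < _MIN_SCANS:
        raise ValueError(f"fit_em requires >= {_MIN_SCANS} scans, got {x.size}")
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_starts)
    best: FitResult | None = None
    for ss in seeds:
        rng = np.random.default_rng(ss)
        try:
            init = random_init(x, rng, cfg)
            result = _em_single(x, init, cfg)
        except (ValueError, FloatingPointError):
            continue
        if best is None or result.loglik > best.loglik:
            best = result
    if best is None:
        raise RuntimeError("all EM starts failed on this sample")
    return best


def fit_em_from(data, init: MixtureParams, config: FitConfig | None = None) -> FitResult:
    """Run a single EM fit from a caller-supplied starting point."""
    cfg = (config or FitConfig()).validate()
    x = as_centiloid_array(data)
    if x.size < _MIN_SCANS:
        raise ValueError(f"fit_em_from requires >= {_MIN_SCANS} scans, got {x.size}")
    return _em_single(x, init.validate(sigma_floor=0.0), cfg)
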