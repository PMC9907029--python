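"""Densities of the three-part Centiloid mixture.

The negative and positive components are ordinary Gaussians.  The
intermediate component follows the partial-volume ("mixel") construction
from MRI voxel classification: an intermediate scan is a convex combination
of the two pure classes with a mixing fraction alpha that is uniform on
[0, 1].  Conditional on alpha the value is Gaussian with mean
``(1-alpha)*mu_neg + alpha*mu_pos`` and SD
``(1-alpha)*sigma_neg + alpha*sigma_pos``; marginalising alpha gives

    g(x) = integral_0^1 N(x; m(alpha), s(alpha)^2) d(alpha)

which we evaluate by fixed-node Gauss-Legendre quadrature.  The component
has no free location or scale of its own — everything is tied to the two
Gaussians, so the mixture contributes only one extra free parameter (the
intermediate proportion).
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .params import FitConfig, MixtureParams

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))
#: SD used in place of exactly-zero component noise so the quadrature
#: degenerates smoothly to the uniform limit instead of dividing by zero
_TINY_SD = 1e-12


def _norm_pdf(x: np.ndarray, mu: float | np.ndarray, sd: float | np.ndarray) -> np.ndarray:
    z = (x - mu) / sd
    return np.exp(-0.5 * z * z) / (sd * _SQRT_2PI)


@lru_cache(maxsize=8)
def _alpha_nodes(quad_nodes: int) -> tuple[np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights mapped from [-1, 1] to [0, 1]."""
    t, w = np.polynomial.legendre.leggauss(quad_nodes)
    return (t + 1.0) / 2.0, w / 2.0


def intermediate_pdf(
    x, params: MixtureParams, quad_nodes: int = 64
) -> np.ndarray | float:
    """Marginal mixel density g(x) of the tied intermediate component.

    Vectorized over ``x``.  In the zero-noise limit (both SDs -> 0) g tends
    to the uniform density of height ``1/(mu_pos - mu_neg)`` on
    ``[mu_neg, mu_pos]``.
    """
    x_arr = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x_arr)):
        raise ValueError("intermediate_pdf requires finite x values")
    alpha, w = _alpha_nodes(int(quad_nodes))
    means = (1.0 - alpha) * params.mu_neg + alpha * params.mu_pos
    sds = np.maximum((1.0 - alpha) * params.sigma_neg + alpha * params.sigma_pos, _TINY_SD)
    # quadrature sum over alpha nodes; shape (nodes, n) -> (n,)
    dens = w @ _norm_pdf(x_arr[None, :] if x_arr.ndim else x_arr, means[:, None], sds[:, None])
    if x_arr.ndim == 0:
        return float(dens[0] if np.ndim(dens) else dens)
    return dens


def intermediate_pdf_grid(
    grid: np.ndarray, params: MixtureParams, quad_nodes: int
) -> np.ndarray:
    """g evaluated on a prepared grid (no input checks; fitting hot path)."""
    alpha, w = _alpha_nodes(int(quad_nodes))
    means = (1.0 - alpha) * params.mu_neg + alpha * params.mu_pos
    sds = np.maximum((1.0 - alpha) * params.sigma_neg + alpha * params.sigma_pos, _TINY_SD)
    return w @ _norm_pdf(grid[None, :], means[:, None], sds[:, None])


def component_pdfs(
    x, params: MixtureParams, config: FitConfig | None = None
) -> np.ndarray:
    """Unweighted component densities, shape (n, 3): negative, intermediate,
    positive.  The intermediate column is zero when the model excludes it."""
    cfg = config or FitConfig()
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.empty((x_arr.size, 3), dtype=float)
    out[:, 0] = _norm_pdf(x_arr, params.mu_neg, max(params.sigma_neg, _TINY_SD))
    if cfg.include_intermediate:
        out[:, 1] = intermediate_pdf(x_arr, params, cfg.quad_nodes)
    else:
        out[:, 1] = 0.0
    out[:, 2] = _norm_pdf(x_arr, params.mu_pos, max(params.sigma_pos, _TINY_SD))
    return out


def mixture_pdf(x, params: MixtureParams, config: FitConfig | None = None):
    """Total mixture density f(x) = pi_neg*N_neg + pi_int*g + pi_pos*N_pos.

    With ``include_intermediate=False`` the intermediate term is dropped
    (its proportion is treated as fixed at zero).
    """
    cfg = config or FitConfig()
    comps = component_pdfs(x, params, cfg)
    weights = np.array([params.pi_neg, params.pi_int, params.pi_pos])
    if not cfg.include_intermediate:
        weights = np.array([params.pi_neg, 0.0, params.pi_pos])
    dens = comps @ weights
    if np.ndim(x) == 0:
        return float(dens[0])
    return dens


def log_likelihood(data, params: MixtureParams, config: FitConfig | None = None) -> float:
    """Sum of log mixture densities over the sample.

    ``data`` may be an array of CL values or a cohort table with a
    ``centiloid`` column.
    """
    values = as_centiloid_array(data)
    if values.size == 0:
        raise ValueError("log_likelihood requires a non-empty sample")
    dens = mixture_pdf(values, params, config)
    return float(np.sum(np.log(np.maximum(dens, 1e-300))))


def as_centiloid_array(data) -> np.ndarray:
    """Extract a 1-D float array of CL values from an array or cohort table."""
    if hasattr(data, "columns"):  # pandas DataFrame
        if "centiloid" not in data.columns:
            raise ValueError("cohort table lacks a 'centiloid' column")
        values = np.asarray(data["centiloid"], dtype=float)
    else:
        values = np.asarray(data, dtype=float).ravel()
    if values.size and not np.all(np.isfinite(values)):
        raise ValueError("centiloid values must be finite")
    return values
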