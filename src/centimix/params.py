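"""Parameter containers for the three-part Centiloid mixture model.

The model describes a distribution of global amyloid-PET burden values on
the Centiloid (CL) scale as a mixture of three components:

* a "negative" Gaussian (amyloid-negative scans, centred near 0 CL),
* a "positive" Gaussian (established amyloid pathology, near 100 CL),
* an "intermediate" partial-volume ("mixel") component whose location and
  scale are tied to the two Gaussians, so only its mixing proportion is a
  free parameter.

The full model therefore has seven parameters: three mixing proportions,
two means and two standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace, asdict
from typing import Iterable

import numpy as np

#: canonical ordering of the seven free parameters, used everywhere a
#: parameter vector or per-parameter table is produced
PARAM_NAMES: tuple[str, ...] = (
    "pi_neg",
    "pi_int",
    "pi_pos",
    "mu_neg",
    "mu_pos",
    "sigma_neg",
    "sigma_pos",
)

_PROP_TOL = 1e-9


class InvalidParamsError(ValueError):
    """Raised when a parameter set violates a model invariant."""


@dataclass(frozen=True)
class MixtureParams:
    """The seven parameters of the three-part mixture.

    Invariants (checked by :meth:`validate`):

    * proportions are non-negative and sum to 1 (within 1e-9),
    * standard deviations are non-negative (and at least ``sigma_floor``
      when one is enforced, as during fitting),
    * ``mu_neg < mu_pos`` — the canonical component ordering that resolves
      label switching.
    """

    pi_neg: float
    pi_int: float
    pi_pos: float
    mu_neg: float
    mu_pos: float
    sigma_neg: float
    sigma_pos: float

    def validate(self, sigma_floor: float = 0.0) -> "MixtureParams":
        """Check all invariants; return self or raise :class:`InvalidParamsError`.

        ``sigma_floor`` defaults to 0 so that degenerate (noise-free)
        generating parameter sets are representable; fitting code passes
        its configured floor.
        """
        pis = (self.pi_neg, self.pi_int, self.pi_pos)
        for name, p in zip(PARAM_NAMES[:3], pis):
            if not np.isfinite(p) or p < 0:
                raise InvalidParamsError(f"proportion {name}={p!r} must be finite and >= 0")
        if abs(sum(pis) - 1.0) > _PROP_TOL:
            raise InvalidParamsError(
                f"proportions must sum to 1 within {_PROP_TOL}; got {sum(pis)!r}"
            )
        for name, s in (("sigma_neg", self.sigma_neg), ("sigma_pos", self.sigma_pos)):
            if not np.isfinite(s) or s < sigma_floor:
                raise InvalidParamsError(
                    f"{name}={s!r} must be finite and >= sigma floor {sigma_floor}"
                )
        if not (np.isfinite(self.mu_neg) and np.isfinite(self.mu_pos)):
            raise InvalidParamsError("component means must be finite")
        if not self.mu_neg < self.mu_pos:
            raise InvalidParamsError(
                f"canonical ordering requires mu_neg < mu_pos; got "
                f"{self.mu_neg!r} >= {self.mu_pos!r}"
            )
        return self

    def as_array(self) -> np.ndarray:
        return np.array(
            [getattr(self, name) for name in PARAM_NAMES], dtype=float
        )

    @classmethod
    def from_array(cls, arr: Iterable[float]) -> "MixtureParams":
        vals = list(map(float, arr))
        if len(vals) != len(PARAM_NAMES):
            raise InvalidParamsError(f"expected {len(PARAM_NAMES)} values, got {len(vals)}")
        return cls(**dict(zip(PARAM_NAMES, vals)))

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAM_NAMES}

    def swapped(self) -> "MixtureParams":
        """Exchange the negative and positive component labels.

        The intermediate component is symmetric under this exchange (its
        density only depends on the unordered pair of endpoints), so only
        the Gaussian parameters and their proportions move.
        """
        return MixtureParams(
            pi_neg=self.pi_pos,
            pi_int=self.pi_int,
            pi_pos=self.pi_neg,
            mu_neg=self.mu_pos,
            mu_pos=self.mu_neg,
            sigma_neg=self.sigma_pos,
            sigma_pos=self.sigma_neg,
        )

    def canonical(self) -> "MixtureParams":
        """Relabel so that ``mu_neg < mu_pos`` (relabel, never reject)."""
        if self.mu_neg > self.mu_pos:
            return self.swapped()
        if self.mu_neg == self.mu_pos:
            # degenerate tie: nudge apart so downstream ordering checks hold
            return replace(self, mu_pos=self.mu_pos + 1e-9)
        return self


@dataclass(frozen=True)
class FitConfig:
    """Settings of the constrained EM fit.

    Defaults are chosen for robust desk-scale use and are echoed into every
    result so a fit is always interpretable on its own.

    max_iter: EM iteration cap per start.
    rel_tol: relative log-likelihood change below which EM stops.
    sigma_floor: lower clamp on both Gaussian SDs, in CL; prevents
        component collapse onto a single datum.
    quad_nodes: Gauss-Legendre nodes for the intermediate density integral.
    include_intermediate: when False the intermediate proportion is pinned
        at 0 and the model is a plain two-component GMM.
    n_starts: random re-initializations for the full-data fit; the best
        final log-likelihood wins.
    seed: master seed for the initialization draws.
    """

    max_iter: int = 500
    rel_tol: float = 1e-6
    sigma_floor: float = 0.5
    quad_nodes: int = 64
    include_intermediate: bool = True
    n_starts: int = 5
    seed: int = 0

    def validate(self) -> "FitConfig":
        if self.max_iter < 1:
            raise InvalidParamsError(f"max_iter={self.max_iter} must be >= 1")
        if not self.rel_tol > 0:
            raise InvalidParamsError(f"rel_tol={self.rel_tol} must be > 0")
        if self.quad_nodes < 8:
            raise InvalidParamsError(f"quad_nodes={self.quad_nodes} must be >= 8")
        if not self.sigma_floor > 0:
            raise InvalidParamsError(f"sigma_floor={self.sigma_floor} must be > 0")
        if self.n_starts < 1:
            raise InvalidParamsError(f"n_starts={self.n_starts} must be >= 1")
        return self

    def as_dict(self) -> dict:
        return asdict(self)

    def model_key(self) -> dict:
        """The subset of settings that defines the fitted model (used to
        refuse comparisons between fits run under different models)."""
        return {
            "include_intermediate": self.include_intermediate,
            "quad_nodes": self.quad_nodes,
            "sigma_floor": self.sigma_floor,
        }
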