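"""Synthetic Centiloid cohorts drawn from the three-part mixture.

Two named presets emulate the shapes of the two study populations the
model is aimed at: ``dpms`` (memory-clinic, clearly bimodal with modes
near 0 and ~93 CL) and ``pnhs`` (pre-dementia, dominated by a Gaussian
around 0 CL and skewed toward higher values by a minority of intermediate
and positive scans).  The generator is the exact sampling inverse of the
fitted model, so parameter recovery is well-defined: a scan first draws a
latent component label with the mixing proportions, then a CL value from
that component (intermediate scans draw a uniform mixing fraction alpha
and then a Gaussian whose mean and SD interpolate linearly between the
two pure components at alpha).

Latent labels are kept alongside every draw — hidden from fitting, but
available to tests that score classification accuracy.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .params import InvalidParamsError, MixtureParams

LABELS = ("negative", "intermediate", "positive")
TRACERS = ("FMM", "FBB")


@dataclass(frozen=True)
class GeneratorPreset:
    """A named generating condition: mixture parameters plus cohort size
    and the fraction of scans labeled with the FMM tracer."""

    name: str
    params: MixtureParams
    n: int
    tracer_split: float = 0.5

    def validate(self) -> "GeneratorPreset":
        if self.n < 1:
            raise InvalidParamsError(f"preset n={self.n} must be >= 1")
        if not 0.0 <= self.tracer_split <= 1.0:
            raise InvalidParamsError(
                f"tracer_split={self.tracer_split} must lie in [0, 1]"
            )
        # sigma_floor=0 here: degenerate noise-free generators are legal
        self.params.validate(sigma_floor=0.0)
        return self


def _load_preset_table() -> dict:
    text = (
        importlib.resources.files("centimix").joinpath("presets.yaml").read_text()
    )
    return yaml.safe_load(text)


def load_preset(name: str) -> GeneratorPreset:
    """Load a named preset from the package's editable preset file."""
    table = _load_preset_table()
    if name not in table:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(table)}")
    entry = table[name]
    return GeneratorPreset(
        name=name,
        params=MixtureParams(**entry["params"]),
        n=int(entry["n"]),
        tracer_split=float(entry.get("tracer_split", 0.5)),
    ).validate()


def dpms_preset() -> GeneratorPreset:
    """Memory-clinic preset: bimodal, modes near 0 and ~93 CL."""
    return load_preset("dpms")


def pnhs_preset() -> GeneratorPreset:
    """Pre-dementia preset: negative-dominated, right-skewed by a 20%
    intermediate and 7% positive fraction."""
    return load_preset("pnhs")


def generate_cohort(preset: GeneratorPreset, seed: int) -> pd.DataFrame:
    """Draw a cohort table from a preset; identical seed, identical table.

    Columns: ``subject_id``, ``tracer``, ``centiloid``, ``latent_label``.
    """
    preset.validate()
    p = preset.params
    rng = np.random.default_rng(seed)
    n = preset.n
    labels = rng.choice(3, size=n, p=[p.pi_neg, p.pi_int, p.pi_pos])
    values = np.empty(n)
    neg = labels == 0
    pos = labels == 2
    mid = labels == 1
    values[neg] = rng.normal(p.mu_neg, p.sigma_neg, size=int(neg.sum()))
    values[pos] = rng.normal(p.mu_pos, p.sigma_pos, size=int(pos.sum()))
    n_mid = int(mid.sum())
    if n_mid:
        alpha = rng.uniform(0.0, 1.0, size=n_mid)
        means = (1.0 - alpha) * p.mu_neg + alpha * p.mu_pos
        sds = (1.0 - alpha) * p.sigma_neg + alpha * p.sigma_pos
        values[mid] = rng.normal(means, sds)
    tracer = np.where(
        rng.uniform(size=n) < preset.tracer_split, TRACERS[0], TRACERS[1]
    )
    return pd.DataFrame(
        {
            "subject_id": [f"{preset.name}-{i:05d}" for i in range(n)],
            "tracer": tracer,
            "centiloid": values,
            "latent_label": [LABELS[k] for k in labels],
        }
    )
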