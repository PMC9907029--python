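"""Cohort table I/O and result serialization.

The canonical table dialect is UTF-8 CSV with "." decimals: columns
``subject_id``, ``centiloid`` (required), ``tracer``, ``cohort``,
``latent_label`` (optional).  Unknown tracer strings are mapped to
``unknown`` with a warning so that a tracer typo never drops scans.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .params import FitConfig, MixtureParams

logger = logging.getLogger("centimix")

REQUIRED_COLUMNS = ("subject_id", "centiloid")
OPTIONAL_COLUMNS = ("tracer", "cohort", "latent_label")
KNOWN_TRACERS = ("FMM", "FBB")


def read_cohort(path, format: str = "csv") -> pd.DataFrame:
    """Load a cohort CSV into a typed table, preserving row count."""
    if format != "csv":
        raise ValueError(f"unsupported cohort format {format!r}")
    path = Path(path)
    # round_trip parsing keeps write->read->write bit-exact
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"missing column: {col}")
    cl = pd.to_numeric(df["centiloid"], errors="coerce")
    bad = np.flatnonzero(~np.isfinite(cl.to_numpy()))
    if bad.size:
        raise ValueError(
            f"non-numeric or non-finite centiloid value at row {bad[0] + 2} "
            f"of {path.name} (1-based, counting the header)"
        )
    df["centiloid"] = cl.astype(float)
    if df["subject_id"].isna().any() or (df["subject_id"].str.len() == 0).any():
        raise ValueError("subject_id must be non-empty for every row")
    if "tracer" in df.columns:
        tracer = df["tracer"].astype(str)
        unknown = ~tracer.isin(KNOWN_TRACERS)
        if unknown.any():
            logger.warning(
                "read_cohort: %d scans with unrecognized tracer labels mapped "
                "to 'unknown'", int(unknown.sum()),
            )
            tracer = tracer.where(~unknown, "unknown")
        df["tracer"] = tracer
    else:
        df["tracer"] = "unknown"
    if df.duplicated(subset=[c for c in ("subject_id", "cohort") if c in df.columns]).any():
        raise ValueError(
            "duplicate subject_id (within the same cohort label, if present)"
        )
    return df


def write_cohort(df: pd.DataFrame, path, include_latent: bool = False) -> Path:
    """Write a cohort table as canonical CSV; round-trips bit-exactly."""
    path = Path(path)
    cols = [c for c in ("subject_id", "tracer", "centiloid", "cohort") if c in df.columns]
    if include_latent and "latent_label" in df.columns:
        cols.append("latent_label")
    df.to_csv(path, index=False, columns=cols, float_format="%.17g")
    return path


def write_json(payload: dict, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=1, sort_keys=True))
    return path


def read_fit_json(path) -> tuple[MixtureParams, FitConfig]:
    """Load the parameters and config echoed into a fit or bootstrap JSON."""
    payload = json.loads(Path(path).read_text())
    params_dict = payload.get("params") or payload.get("point")
    if params_dict is None:
        raise ValueError(f"{path}: no 'params' or 'point' entry")
    cfg_dict = payload.get("config", {})
    cfg = FitConfig(**{k: v for k, v in cfg_dict.items() if k in FitConfig.__dataclass_fields__})
    return MixtureParams(**params_dict), cfg
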