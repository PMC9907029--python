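"""End-to-end pipeline driven by a YAML configuration.

Stages: obtain the cohort (simulate a preset or read a CSV), fit, bootstrap,
classify, report.  Every run writes a manifest recording the package
version, the master seed, a hash of the configuration, and the status of
each stage; on failure the completed stages' outputs are retained and the
manifest marks the failed stage.

Annotated configuration example::

    input:
      preset: pnhs        # or: file: cohort.csv
      n: 1600             # optional override of the preset size
      seed: 1             # cohort-generation seed
    fit:
      include_intermediate: true
      n_starts: 5
      seed: 1
    bootstrap:
      B: 200
      seed: 1
    out_dir: results/pnhs
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .bootstrap import bootstrap_fit
from .classify import classify
from .em import fit_em
from .io import write_cohort, write_json, read_cohort
from .params import FitConfig
from .report import render_report
from .simulate import generate_cohort, load_preset

logger = logging.getLogger("centimix")


class PipelineError(RuntimeError):
    pass


def _validate_config(cfg: dict) -> dict:
    if "input" not in cfg or "out_dir" not in cfg:
        raise PipelineError("config must define 'input' and 'out_dir'")
    inp = cfg["input"]
    if ("preset" in inp) == ("file" in inp):
        raise PipelineError("input must define exactly one of 'preset' or 'file'")
    boot = cfg.get("bootstrap", {})
    if "B" in boot and int(boot["B"]) < 1:
        raise PipelineError(f"bootstrap B={boot['B']} must be >= 1")
    return cfg


def run_pipeline(config_path) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    config_path = Path(config_path)
    cfg = _validate_config(yaml.safe_load(config_path.read_text()))
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = hashlib.sha256(
        json.dumps(cfg, sort_keys=True).encode()
    ).hexdigest()[:16]
    master_seed = int(cfg.get("input", {}).get("seed", 0))
    manifest: dict = {
        "schema_version": 1,
        "centimix_version": __version__,
        "config_hash": config_hash,
        "master_seed": master_seed,
        "stages": {},
        "outputs": {},
    }
    manifest_path = out_dir / "manifest.json"

    def _finish_stage(stage: str, **outputs):
        manifest["stages"][stage] = "ok"
        manifest["outputs"].update({k: str(v) for k, v in outputs.items()})
        write_json(manifest, manifest_path)

    stage = "input"
    try:
        inp = cfg["input"]
        if "preset" in inp:
            preset = load_preset(inp["preset"])
            if "n" in inp:
                preset = type(preset)(
                    name=preset.name, params=preset.params,
                    n=int(inp["n"]), tracer_split=preset.tracer_split,
                )
            cohort = generate_cohort(preset, master_seed)
            logger.info("[input] simulated %d scans from preset %s", len(cohort), preset.name)
        else:
            cohort = read_cohort(inp["file"])
            logger.info("[input] read %d scans from %s", len(cohort), inp["file"])
        cohort_path = write_cohort(cohort, out_dir / "cohort.csv")
        _finish_stage(stage, cohort=cohort_path)

        stage = "fit"
        fit_opts = dict(cfg.get("fit", {}))
        fit_cfg = FitConfig(**{
            k: v for k, v in fit_opts.items() if k in FitConfig.__dataclass_fields__
        })
        fit = fit_em(cohort, fit_cfg)
        fit_payload = fit.as_dict()
        fit_payload.update({"master_seed": master_seed, "config_hash": config_hash})
        fit_path = write_json(fit_payload, out_dir / "fit.json")
        logger.info("[fit] loglik=%.2f converged=%s", fit.loglik, fit.converged)
        _finish_stage(stage, fit=fit_path)

        stage = "bootstrap"
        boot_cfg = cfg.get("bootstrap", {})
        B = int(boot_cfg.get("B", 200))
        summary = bootstrap_fit(cohort, B=B, config=fit_cfg,
                                seed=int(boot_cfg.get("seed", master_seed)))
        boot_payload = summary.as_dict()
        boot_payload.update({"master_seed": master_seed, "config_hash": config_hash})
        boot_path = write_json(boot_payload, out_dir / "bootstrap.json")
        logger.info("[bootstrap] %d/%d replicates converged",
                    summary.B_succeeded, summary.B_requested)
        _finish_stage(stage, bootstrap=boot_path)

        stage = "classify"
        classification = classify(cohort, fit.params, fit_cfg)
        cls_path = out_dir / "classification.csv"
        classification.table.to_csv(cls_path, index=False, float_format="%.17g")
        _finish_stage(stage, classification=cls_path)

        stage = "report"
        paths = render_report(cohort, fit, summary, classification, out_dir)
        _finish_stage(stage, report_png=paths["png"], report_json=paths["json"])
    except Exception as exc:
        manifest["stages"][stage] = f"failed: {exc}"
        write_json(manifest, manifest_path)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    return manifest
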