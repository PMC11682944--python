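"""End-to-end run: residues → risk quotients → exceedances → profit scenarios.

One :class:`RunConfig` drives the whole analysis so a run is reproducible
from a single file: generate (or load) a residue table, score acute and
chronic risk quotients against a toxicity reference, count threshold
exceedances, flag sites whose chronic RQ exceeds the level of concern, and
evaluate the profit scenario grid and sensitivity analysis.  Outputs are
CSV tables plus a JSON run summary embedding the config hash and headline
numbers, so downstream checks can target a single artifact.
"""

from __future__ import annotations

import hashlib
import json
import logging
from decimal import Decimal
from pathlib import Path
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, model_validator

from . import __version__
from .io import read_residues, read_toxicity, write_residues, write_toxicity
from .profit import (
    ProfitParameters,
    SensitivityOverride,
    scenario_grid,
    sensitivity_analysis,
)
from .risk import (
    ConsumptionConstants,
    ThresholdRegistry,
    compute_site_rqs,
    exceedance_report,
    total_rq,
)
from .synthetic import (
    SyntheticConfig,
    default_synthetic_config,
    default_toxicity_reference,
    generate_residues,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("apiarisk")


class RunConfig(BaseModel):
    """Configuration for one pipeline run."""

    mode: Literal["synthetic", "csv"] = "synthetic"
    synthetic: Optional[SyntheticConfig] = None
    residues_csv: Optional[str] = None
    toxicity_csv: Optional[str] = None  # None = packaged placeholder reference
    thresholds: ThresholdRegistry = ThresholdRegistry()
    constants: ConsumptionConstants = ConsumptionConstants()
    censoring_policy: Literal["zero", "half_lod"] = "zero"
    chronic_policy: Literal["min", "lc50", "ldd50"] = "min"
    profit: ProfitParameters = ProfitParameters()
    sensitivity_overrides: Optional[tuple[SensitivityOverride, ...]] = None
    output_dir: str = "apiarisk_run"
    seed: Optional[int] = None
    log_level: str = "INFO"

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    @model_validator(mode="after")
    def _validate(self) -> "RunConfig":
        if self.mode == "csv" and self.residues_csv is None:
            raise ValueError("mode 'csv' requires residues_csv")
        if self.mode == "synthetic" and self.residues_csv is not None:
            raise ValueError("mode 'synthetic' must not set residues_csv")
        return self

    def resolved_synthetic(self) -> SyntheticConfig:
        cfg = self.synthetic or default_synthetic_config()
        if self.seed is not None:
            cfg = cfg.model_copy(update={"seed": self.seed})
        return cfg


def _config_hash(config: RunConfig) -> str:
    # hash the analytical configuration only: where outputs land (and how
    # verbosely) must not change the identity of a run
    dumped = config.model_dump(mode="json", exclude={"output_dir", "log_level"})
    canonical = json.dumps(dumped, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _jsonable(value):
    if isinstance(value, Decimal):
        return float(value)
    return value


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the run summary (also written to disk).

    Deterministic for a fixed seed and config.  Writes, under
    ``config.output_dir``: ``residues.csv`` (synthetic mode),
    ``toxicity_reference.csv``, ``rq_results.csv``, ``skipped_compounds.csv``,
    ``total_rq.csv``, ``exceedance_report.csv``, ``scenario_grid.csv``,
    ``sensitivity.csv`` and ``run_summary.json``.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    stage = "load inputs"
    try:
        if config.mode == "synthetic":
            syn = config.resolved_synthetic()
            logger.info("generating synthetic residues (seed=%d)", syn.seed)
            residues = generate_residues(syn)
            write_residues(residues, out / "residues.csv")
        else:
            residues = read_residues(config.residues_csv)
        if config.toxicity_csv is not None:
            tox = read_toxicity(config.toxicity_csv)
        else:
            tox = default_toxicity_reference()
        write_toxicity(tox, out / "toxicity_reference.csv")

        stage = "risk quotients"
        lod_by_compound = None
        if config.censoring_policy == "half_lod" and config.mode == "synthetic":
            lod_by_compound = {
                c.name: c.lod_ug_per_kg for c in config.resolved_synthetic().compounds
            }
        rqs = compute_site_rqs(
            residues,
            tox,
            constants=config.constants,
            registry=config.thresholds,
            censoring_policy=config.censoring_policy,
            lod_by_compound=lod_by_compound,
            chronic_policy=config.chronic_policy,
        )
        rqs.results.to_csv(out / "rq_results.csv", index=False)
        rqs.skipped.to_csv(out / "skipped_compounds.csv", index=False)

        stage = "totals and exceedances"
        totals = total_rq(rqs.of_kind("acute"), "acute")
        totals.to_csv(out / "total_rq.csv", index=False)
        exceedances = exceedance_report(rqs.results, config.thresholds)
        exceedances.to_csv(out / "exceedance_report.csv", index=False)

        chronic = rqs.of_kind("chronic")
        flagged_sites = sorted(
            chronic.loc[chronic["rq"] > config.thresholds.chronic, "site_id"].unique()
        )

        stage = "profit scenarios"
        grid = scenario_grid(config.profit)
        grid.to_csv(out / "scenario_grid.csv", index=False)
        overrides = config.sensitivity_overrides
        sens = (
            sensitivity_analysis(config.profit)
            if overrides is None
            else sensitivity_analysis(config.profit, overrides)
        )
        sens.to_csv(out / "sensitivity.csv", index=False)
    except Exception as exc:
        marker = {"failed_stage": stage, "error": str(exc)}
        (out / "FAILED.json").write_text(json.dumps(marker, indent=2))
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    baseline = grid[(grid["effect"] == "none")].iloc[0]
    chronic_exc = exceedances[exceedances["threshold_name"] == "chronic"]
    summary = {
        "package_version": __version__,
        "config_hash": _config_hash(config),
        "seed": (config.resolved_synthetic().seed if config.mode == "synthetic" else None),
        "n_residue_records": int(len(residues)),
        "n_rq_results": int(len(rqs.results)),
        "n_skipped_compounds": int(len(rqs.skipped)),
        "flagged_sites": flagged_sites,
        "n_flagged_sites": len(flagged_sites),
        "chronic_exceedance_site_counts": {
            row.compound: int(row.n_sites_exceeding)
            for row in chronic_exc.itertuples()
            if row.n_sites_exceeding > 0
        },
        "headline": {
            "baseline_profit": _jsonable(baseline["profit_h0"]),
            "scenario_grid": [
                {k: _jsonable(v) for k, v in row.items()}
                for row in grid.to_dict(orient="records")
            ],
        },
    }
    (out / "run_summary.json").write_text(json.dumps(summary, indent=2, default=_jsonable))
    logger.info("run complete: %s", out / "run_summary.json")
    return summary
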