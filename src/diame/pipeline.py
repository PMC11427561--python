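"""Pipeline orchestration: fixed stage order, configuration and run manifest.

Stage order is a hard constraint of the analysis design:

    read -> q-value/contaminant filtering -> ME-run exclusion ->
    re-normalization -> protein summarization -> metrics / co-variation

ME exclusion must precede re-normalization (an included ME run would anchor the
normalization at its ~10x scale); configurations that enable normalization
while disabling ME exclusion are rejected at validation time.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import entrapment, quantnorm, report_io
from .filtering import FilterConfig, apply_qvalue_filters, drop_me_runs, filter_contaminants

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised for invalid pipeline configurations."""


@dataclass
class PipelineConfig:
    """Stage toggles, module parameters, paths and the seed."""

    report_path: str
    annotation_path: str
    output_dir: str
    dialect: str = "diann"
    seed: int = 0
    filter_qvalues: bool = True
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    exclude_me_runs: bool = True
    normalize: bool = True
    normalization_method: str = "mass"
    summarize: bool = True
    entrapment_metrics: bool = False
    species_map_path: str | None = None

    def validate(self) -> None:
        if self.normalize and not self.exclude_me_runs:
            raise ConfigError(
                "normalization without prior ME-run exclusion is not allowed: "
                "ME runs would bias the normalization anchor"
            )


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    filt = raw.pop("filter_config", None)
    cfg = PipelineConfig(**raw)
    if filt:
        if "contaminant_ids" in filt:
            filt["contaminant_ids"] = set(filt["contaminant_ids"])
        cfg.filter_config = FilterConfig(**filt)
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in fixed order and write a run manifest.

    Every intermediate table is written to the output directory; the manifest
    records the seed, per-stage record counts and output checksums.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": [], "outputs": {}, "flags": []}

    def note(stage: str, table: report_io.ReportTable) -> None:
        manifest["stages"].append(
            {"stage": stage, "records": len(table), "runs": len(table.runs)}
        )
        log.info("%s: %d records, %d runs", stage, len(table), len(table.runs))

    try:
        table = report_io.read_report(cfg.report_path, dialect=cfg.dialect)
        annotations = report_io.read_annotations(cfg.annotation_path)
        note("read", table)

        if cfg.species_map_path:
            smap = report_io.read_species_map(cfg.species_map_path)
            table = report_io.assign_species(table, smap)

        if cfg.filter_qvalues:
            table = apply_qvalue_filters(table, cfg.filter_config)
            table = filter_contaminants(table, cfg.filter_config.contaminant_ids)
            note("filter", table)

        if cfg.entrapment_metrics:
            ftr = entrapment.ftr_table(table)
            ftr.to_csv(out / "entrapment_metrics.tsv", sep="\t", index=False)

        if cfg.exclude_me_runs:
            table = drop_me_runs(table, annotations)
            note("drop_me_runs", table)

        if cfg.normalize:
            table, shifts = quantnorm.normalize_traces(table, method=cfg.normalization_method)
            shifts.to_frame().to_csv(out / "shifts.tsv", sep="\t")
            note("normalize", table)
        else:
            manifest["flags"].append("unnormalized")

        report_io.write_report(table, out / "report_processed.tsv")

        if cfg.summarize:
            matrix = quantnorm.summarize_proteins(table, annotations)
            report_io.write_matrix(matrix, out / "protein_matrix.tsv")
            manifest["stages"].append(
                {"stage": "summarize", "records": int(matrix.notna().to_numpy().sum()), "runs": matrix.shape[1]}
            )
    except Exception as exc:  # annotate stage failures with their origin
        stage = manifest["stages"][-1]["stage"] if manifest["stages"] else "read"
        raise RuntimeError(f"pipeline failed after stage {stage!r}: {exc}") from exc

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _checksum(f)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
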