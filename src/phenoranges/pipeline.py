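"""End-to-end driver: records -> strata -> meta-analyses -> ranges -> report.

This is a thin orchestration layer over the library modules.  Its one extra
responsibility is determinism of the artifacts: the summary JSON and the
plot-data tables are serialized with sorted keys and canonical float
formatting, so identical input plus identical configuration produces
byte-identical output.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml
from pydantic import BaseModel, Field

from .bias import leave_one_out, loo_table
from .meta import MetaConfig, MetaResult, run_meta
from .ranges import (
    AgreementReport,
    ControlRange,
    ExpectedRange,
    RangeConfig,
    StrainClassification,
    build_control_range,
    classify_strain,
    compare_with_expert,
    expected_range,
    labels_from_classifications,
    render_forest,
)
from .records import ColumnMap, MeasurementRecord, ParseReport, StrainGroupTable, expand_strain_groups, parse_records
from .stratify import StrataResult, StratifyConfig, build_strata, stratum_manifest


class PipelineConfig(BaseModel):
    """Run configuration (loadable from YAML)."""

    columns: dict[str, str] = Field(default_factory=dict)
    stratify: StratifyConfig = Field(default_factory=StratifyConfig)
    meta: MetaConfig = Field(default_factory=MetaConfig)
    ranges: RangeConfig = Field(default_factory=RangeConfig)
    founders: Optional[list[str]] = None
    veto: list[str] = Field(default_factory=list)
    exclusions: list[str] = Field(default_factory=list)  # record_ids or study_ids

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class PipelineReport:
    config: PipelineConfig
    strata: StrataResult
    results: list[MetaResult]
    ranges: list[ExpectedRange]
    control: Optional[ControlRange] = None
    classifications: list[StrainClassification] = field(default_factory=list)
    agreement: Optional[AgreementReport] = None
    excluded_records: int = 0


def run_pipeline(
    records: Sequence[MeasurementRecord],
    config: Optional[PipelineConfig] = None,
    strain_table: Optional[StrainGroupTable] = None,
    expert_labels: Optional[dict[str, str]] = None,
) -> PipelineReport:
    """Run the full workflow on already-parsed records."""
    cfg = config or PipelineConfig()
    if strain_table is not None:
        records = expand_strain_groups(records, strain_table)
    if cfg.exclusions:
        excl = set(cfg.exclusions)
        kept = [r for r in records if r.record_id not in excl and r.study_id not in excl]
        excluded = len(records) - len(kept)
        records = kept
    else:
        excluded = 0
    strata = build_strata(records, cfg.stratify)
    results: list[MetaResult] = []
    ranges: list[ExpectedRange] = []
    for key in sorted(strata.strata):
        m = strata.strata[key]
        res = run_meta(m, cfg.meta)
        results.append(res)
        ranges.append(expected_range(res, m, cfg.ranges))

    control = None
    classifications: list[StrainClassification] = []
    agreement = None
    if cfg.founders:
        by_strain = {er.key.strain_or_group: er for er in ranges}
        control = build_control_range(
            cfg.founders, by_strain, veto=cfg.veto, config=cfg.ranges
        )
        classifications = [
            classify_strain(er, control) for s, er in sorted(by_strain.items())
        ]
        if expert_labels is not None:
            agreement = compare_with_expert(
                labels_from_classifications(classifications), expert_labels
            )
    return PipelineReport(
        config=cfg,
        strata=strata,
        results=results,
        ranges=ranges,
        control=control,
        classifications=classifications,
        agreement=agreement,
        excluded_records=excluded,
    )


def load_and_run(
    records_path: str | Path,
    config: Optional[PipelineConfig] = None,
    strain_table_path: Optional[str | Path] = None,
    expert_labels_path: Optional[str | Path] = None,
) -> tuple[PipelineReport, ParseReport]:
    """Parse a records file and run the pipeline on the valid records."""
    cfg = config or PipelineConfig()
    parse = parse_records(records_path, ColumnMap(cfg.columns))
    table = StrainGroupTable.from_tsv(strain_table_path) if strain_table_path else None
    labels = read_expert_labels(expert_labels_path) if expert_labels_path else None
    report = run_pipeline(parse.records, cfg, strain_table=table, expert_labels=labels)
    return report, parse


def read_expert_labels(path: str | Path) -> dict[str, str]:
    """Two-column TSV (strain, label) of expert normal/abnormal calls."""
    labels: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0].casefold() in ("strain", "key"):
                continue
            labels[parts[0]] = parts[1]
    return labels


# ---------------------------------------------------------------------------
# Deterministic serialization
# ---------------------------------------------------------------------------

def _num(x: float) -> Optional[float]:
    return None if (x is None or not math.isfinite(x)) else float(x)


def _result_dict(res: MetaResult) -> dict:
    return {
        "key": res.key.label(),
        "k": res.k,
        "model": res.pooled.model,
        "mean": _num(res.pooled.mean),
        "se": _num(res.pooled.se),
        "ci95": [_num(res.pooled.ci95[0]), _num(res.pooled.ci95[1])],
        "Q": _num(res.het.Q) if res.het else None,
        "df": res.het.df if res.het else None,
        "i2": _num(res.het.i2) if res.het else None,
        "i2_percent": _num(100 * res.het.i2) if res.het else None,
        "tau2": _num(res.het.tau2) if res.het else None,
        "confidence": res.confidence,
        "asymmetry_score": _num(res.asymmetry_score),
        "quadrant": res.quadrant,
        "flags": sorted(res.flags),
    }


def summary_dict(report: PipelineReport) -> dict:
    out: dict = {
        "config": report.config.model_dump(mode="json"),
        "n_strata": len(report.results),
        "excluded_records": report.excluded_records,
        "skipped_records": sorted(report.strata.skipped),
        "results": [_result_dict(r) for r in report.results],
        "expected_ranges": [
            {
                "key": er.key.label(),
                "center": _num(er.center),
                "sd_used": _num(er.sd_used),
                "low": _num(er.low),
                "high": _num(er.high),
                "k": er.k,
                "confidence": er.confidence,
                "flags": sorted(er.flags),
            }
            for er in report.ranges
        ],
    }
    if report.control is not None:
        out["control_range"] = {
            "phenotype": report.control.phenotype,
            "founders": list(report.control.founders),
            "included": list(report.control.included),
            "low": _num(report.control.low),
            "high": _num(report.control.high),
            "iteration_log": [
                {"strain": s, "action": a, "low": _num(lo), "high": _num(hi)}
                for s, a, (lo, hi) in report.control.iteration_log
            ],
        }
        out["classifications"] = [
            {"strain": c.strain, "status": c.status} for c in report.classifications
        ]
    if report.agreement is not None:
        out["expert_agreement"] = {
            "percent": _num(report.agreement.percent),
            "n": report.agreement.n,
            "disagreements": [list(d) for d in report.agreement.disagreements],
        }
    return out


def summary_json(report: PipelineReport) -> str:
    return json.dumps(summary_dict(report), sort_keys=True, indent=2) + "\n"


def write_outputs(
    report: PipelineReport,
    out_dir: str | Path,
    plots: bool = False,
    sex_shapes: bool = False,
) -> dict[str, Path]:
    """Write summary JSON, manifest, results/forest tables and optional plots."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["summary"] = out_dir / "summary.json"
    paths["summary"].write_text(summary_json(report))

    manifest = stratum_manifest(report.strata)
    paths["manifest"] = out_dir / "stratum_manifest.tsv"
    manifest.to_csv(paths["manifest"], sep="\t", index=False)

    rows = list(zip(report.results, report.ranges))
    forest_path = str(out_dir / "forest.svg") if plots else None
    table, fig_path = render_forest(
        rows, path=forest_path, sex_shapes=sex_shapes, control=report.control
    )
    paths["forest_data"] = out_dir / "forest_data.tsv"
    table.to_csv(paths["forest_data"], sep="\t", index=False)
    if fig_path:
        paths["forest_plot"] = Path(fig_path)
    return paths


def sensitivity_tables(report: PipelineReport, strata: StrataResult, config: MetaConfig):
    """Leave-one-out tables per stratum (k >= 3 only)."""
    tables = {}
    for key in sorted(strata.strata):
        m = strata.strata[key]
        if m.k >= 3:
            tables[key.label()] = loo_table(leave_one_out(m, config))
    return tables
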