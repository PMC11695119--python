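"""Batch orchestration: tables + plate export + order feed in, HL7 result
messages + review document + indicator/CDS artifacts out.

The run is directory-in / directory-out and fully deterministic given an
injected clock: per sample the export is translated, the result matched to
its ancillary order by specimen id, and one pipe-delimited result message
written; samples that cannot be matched are quarantined (never dropped);
then a review document covering every (sample, gene) is rendered, and
indicator/CDS rules are evaluated when supplied. Table validation failures
abort before any output is written.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Callable, Sequence

import yaml

from . import hl7, indicators as ind, report
from .engine import (
    InstrumentExport,
    SampleGeneResult,
    parse_instrument_export,
    process_batch,
)
from .tables import TranslatorTables, load_translation_tables, validate_tables


class TableValidationError(ValueError):
    """Translator tables failed validation; the run aborts before output."""


@dataclass
class RunConfig:
    probe_table: Path
    genotype_table: Path
    phenotype_table: Path
    export_path: Path
    order_dir: Path
    output_dir: Path
    mode: hl7.MessageMode = hl7.MessageMode.DUAL
    replacements: dict[str, str] = field(default_factory=dict)
    indicator_rules_path: Path | None = None
    drug_gene_rules_path: Path | None = None
    med_orders_path: Path | None = None  # CSV: sample,medication,timestamp
    run_id: str = "RUN1"
    clock: Callable[[], datetime] | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        base = Path(path).parent

        def p(key: str) -> Path:
            return (base / raw[key]).resolve()

        def opt(key: str) -> Path | None:
            return (base / raw[key]).resolve() if raw.get(key) else None

        return cls(
            probe_table=p("probe_table"),
            genotype_table=p("genotype_table"),
            phenotype_table=p("phenotype_table"),
            export_path=p("export_path"),
            order_dir=p("order_dir"),
            output_dir=(base / raw["output_dir"]).resolve(),
            mode=hl7.MessageMode(raw.get("mode", "dual")),
            replacements=raw.get("replacements", {}) or {},
            indicator_rules_path=opt("indicator_rules"),
            drug_gene_rules_path=opt("drug_gene_rules"),
            med_orders_path=opt("med_orders"),
            run_id=str(raw.get("run_id", "RUN1")),
        )


@dataclass
class RunSummary:
    samples: int = 0
    resulted_genes: int = 0
    non_resulted_genes: int = 0
    quarantined_results: int = 0
    messages_written: int = 0
    indicators: int = 0
    alerts_fired: int = 0
    orders_loaded: int = 0

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def load_order_feed(order_dir: str | Path) -> list[hl7.OrderContext]:
    """Parse every ``*.hl7`` file in the order directory (sorted by name)."""
    contexts = []
    for path in sorted(Path(order_dir).glob("*.hl7")):
        message = hl7.parse_hl7(path.read_text(encoding="utf-8"))
        contexts.append(hl7.extract_order_context(message))
    return contexts


def _load_med_orders(path: Path) -> list[tuple[str, ind.MedicationOrder]]:
    orders = []
    with path.open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            ts = datetime.fromisoformat(row.get("timestamp") or "2024-01-01T00:00:00")
            orders.append((row["sample"].strip(), ind.MedicationOrder(row["medication"].strip(), ts)))
    return orders


def run_pipeline(config: RunConfig) -> RunSummary:
    """Execute the full automated workflow for one plate; see module docs."""
    clock = config.clock or datetime.now
    tables = load_translation_tables(config.probe_table, config.genotype_table, config.phenotype_table)
    findings = validate_tables(tables)
    errors = [f for f in findings if f.severity == "error"]
    if errors:
        raise TableValidationError(
            "; ".join(f"{f.table} row {f.row}: {f.message}" for f in errors[:5])
        )

    export = parse_instrument_export(config.export_path)
    orders = load_order_feed(config.order_dir)
    results = process_batch(export, tables, config.replacements)
    mapping = hl7.default_mapping(tables.panel_genes)

    out = Path(config.output_dir)
    msg_dir = out / "messages"
    msg_dir.mkdir(parents=True, exist_ok=True)
    log_path = out / f"{config.run_id}_log.jsonl"
    summary = RunSummary(samples=len(export.sample_ids()), orders_loaded=len(orders))

    by_sample: dict[str, list[SampleGeneResult]] = {}
    for r in results:
        by_sample.setdefault(r.sample_id, []).append(r)

    quarantine_rows: list[tuple[str, str, str]] = []
    log_records: list[dict] = []
    msg_counter = 0
    for sample_id, sample_results in by_sample.items():
        resulted = [r for r in sample_results if r.resulted]
        summary.resulted_genes += len(resulted)
        summary.non_resulted_genes += len(sample_results) - len(resulted)
        try:
            order = hl7.match_order(sample_id, orders)
        except hl7.MatchError as exc:
            quarantine_rows.append((sample_id, "order_match", str(exc)))
            summary.quarantined_results += len(sample_results)
            log_records.append({"event": "quarantine", "sample": sample_id, "reason": str(exc)})
            continue
        if not resulted:
            log_records.append({"event": "no_resulted_genes", "sample": sample_id})
            continue
        msg_counter += 1
        message = hl7.assemble_result_message(
            order,
            resulted,
            mapping,
            mode=config.mode,
            clock=clock,
            control_id=f"{config.run_id}-{msg_counter:05d}",
        )
        (msg_dir / f"{sample_id}.hl7").write_text(message.serialize(), encoding="utf-8")
        summary.messages_written += 1
        log_records.append(
            {"event": "message_written", "sample": sample_id, "obx": len(message.segments_of("OBX"))}
        )

    with (out / "quarantine.csv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["sample", "stage", "reason"])
        w.writerows(quarantine_rows)

    report.generate_review_document(results, export, clock, out / f"{config.run_id}_review")

    if config.indicator_rules_path:
        rules = ind.load_indicator_rules(config.indicator_rules_path)
        flags = ind.evaluate_indicator_rules(results, rules)
        summary.indicators = len(flags)
        if config.drug_gene_rules_path and config.med_orders_path:
            dg_rules = ind.load_drug_gene_rules(config.drug_gene_rules_path)
            by_sample_flags: dict[str, list[ind.GenomicIndicator]] = {}
            for flag in flags:
                by_sample_flags.setdefault(flag.linked_result_ref.split(":")[0], []).append(flag)
            all_alerts: list[ind.CDSAlert] = []
            for sample_id, med_order in _load_med_orders(config.med_orders_path):
                all_alerts.extend(
                    ind.trigger_cds(med_order, by_sample_flags.get(sample_id, []), dg_rules)
                )
            ind.append_alert_audit(all_alerts, out / "alerts.jsonl")
            summary.alerts_fired = len(all_alerts)

    with log_path.open("w", encoding="utf-8") as fh:
        for rec in log_records:
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    (out / "summary.json").write_text(json.dumps(summary.as_dict(), indent=2, sort_keys=True), encoding="utf-8")
    return summary
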