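"""Genomic indicators and drug–gene clinical decision support.

A genomic indicator is a chart-level flag derived from a resulted phenotype:
it carries interpretation text for providers and patients and a link back to
the originating lab result, and it is the trigger criterion for CDS alerts
at medication ordering (e.g. clopidogrel ordered for a CYP2C19 poor
metabolizer). Indicator rules match on (gene, phenotype) exactly after
case-normalisation; indicators are created for every matched phenotype —
including normal function — with an ``actionable`` flag controlling CDS
eligibility.

Multi-gene drugs are supported only as independent single-gene rules, and
phenoconversion (drug–drug-interaction-induced phenotype shift) is out of
scope; the alert payload may carry a static caution string.
"""

from __future__ import annotations

import csv
import enum
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable, Sequence

from .engine import SampleGeneResult


class OverrideAction(str, enum.Enum):
    KEEP_ORDER = "KeepOrder"
    DISMISS = "Dismiss"


class DefaultAction(str, enum.Enum):
    REMOVE_ORDER = "RemoveOrder"
    KEEP_ORDER = "KeepOrder"


@dataclass(frozen=True)
class IndicatorRule:
    rule_id: str
    gene: str
    phenotype_match: str
    indicator_name: str
    provider_text: str
    patient_text: str
    actionable: bool


@dataclass(frozen=True)
class GenomicIndicator:
    indicator_name: str
    gene: str
    phenotype: str
    provider_text: str
    patient_text: str
    linked_result_ref: str  # "<sample_id>:<gene>" of the originating result
    actionable: bool = True


@dataclass(frozen=True)
class DrugGeneRule:
    medication: str
    gene: str
    phenotype_match: str
    recommendation_text: str
    default_action: DefaultAction
    override_options: tuple[OverrideAction, ...]
    rule_id: str = ""


@dataclass(frozen=True)
class MedicationOrder:
    medication: str
    timestamp: datetime


@dataclass(frozen=True)
class CDSAlert:
    medication: str
    triggering_indicator: GenomicIndicator
    recommendation_text: str
    default_action: DefaultAction
    override_options: tuple[OverrideAction, ...]
    fired_at: datetime


@dataclass
class RetroOutcome:
    """Indicators newly added by a retroactive run plus an exceptions report
    listing legacy records whose phenotype text matched no rule."""

    added: list[GenomicIndicator]
    exceptions: list[tuple[str, str, str]] = field(default_factory=list)  # (sample, gene, phenotype text)


def _norm(text: str) -> str:
    return " ".join(text.casefold().split())


def result_ref(result: SampleGeneResult) -> str:
    return f"{result.sample_id}:{result.gene}"


def evaluate_indicator_rules(
    results: Sequence[SampleGeneResult],
    rules: Sequence[IndicatorRule],
) -> list[GenomicIndicator]:
    """One indicator per Resulted result whose (gene, phenotype) matches a
    rule; non-matches are silent (see :func:`indicator_coverage_report`)."""
    index = {(_norm(r.gene), _norm(r.phenotype_match)): r for r in rules}
    indicators: list[GenomicIndicator] = []
    for result in results:
        if not result.resulted:
            continue
        rule = index.get((_norm(result.gene), _norm(result.phenotype or "")))
        if rule is None:
            continue
        indicators.append(
            GenomicIndicator(
                indicator_name=rule.indicator_name,
                gene=result.gene,
                phenotype=result.phenotype or "",
                provider_text=rule.provider_text,
                patient_text=rule.patient_text,
                linked_result_ref=result_ref(result),
                actionable=rule.actionable,
            )
        )
    return indicators


def indicator_coverage_report(
    results: Sequence[SampleGeneResult],
    rules: Sequence[IndicatorRule],
) -> list[SampleGeneResult]:
    """Resulted results whose phenotype matched no indicator rule."""
    index = {(_norm(r.gene), _norm(r.phenotype_match)) for r in rules}
    return [
        r for r in results
        if r.resulted and (_norm(r.gene), _norm(r.phenotype or "")) not in index
    ]


def retro_process_legacy(
    legacy: Sequence[SampleGeneResult],
    rules: Sequence[IndicatorRule],
    existing: Iterable[GenomicIndicator] = (),
) -> RetroOutcome:
    """Retroactively add indicators for results entered before go-live.

    Legacy results carry only gene + phenotype text (often no activity
    score). Output equals fresh evaluation of equivalent results, minus any
    indicator already on the chart — re-running is a no-op. Legacy records
    whose phenotype text matches no rule go to the exceptions report.
    """
    existing_keys = {(i.indicator_name, i.linked_result_ref) for i in existing}
    fresh = evaluate_indicator_rules(legacy, rules)
    added = [i for i in fresh if (i.indicator_name, i.linked_result_ref) not in existing_keys]
    matched_refs = {i.linked_result_ref for i in fresh}
    exceptions = [
        (r.sample_id, r.gene, r.phenotype or "")
        for r in legacy
        if r.resulted and result_ref(r) not in matched_refs
    ]
    return RetroOutcome(added=added, exceptions=exceptions)


def trigger_cds(
    order: MedicationOrder,
    indicators: Sequence[GenomicIndicator],
    rules: Sequence[DrugGeneRule],
) -> list[CDSAlert]:
    """Fire alerts for one medication order against the chart's indicators.

    One alert per matching (medication, gene, phenotype) rule, in rule_id
    order; only actionable indicators trigger. No match → no alert.
    """
    alerts: list[CDSAlert] = []
    for rule in sorted(rules, key=lambda r: r.rule_id):
        if _norm(rule.medication) != _norm(order.medication):
            continue
        for ind in indicators:
            if not ind.actionable:
                continue
            if _norm(ind.gene) == _norm(rule.gene) and _norm(ind.phenotype) == _norm(rule.phenotype_match):
                alerts.append(
                    CDSAlert(
                        medication=order.medication,
                        triggering_indicator=ind,
                        recommendation_text=rule.recommendation_text,
                        default_action=rule.default_action,
                        override_options=rule.override_options,
                        fired_at=order.timestamp,
                    )
                )
    return alerts


def alert_impact_summary(before_count: int, after_count: int) -> int:
    """Signed percent change in fired-alert volume, rounded to the nearest
    integer percent (half away from zero)."""
    if before_count <= 0:
        raise ValueError("undefined baseline: before_count must be positive")
    change = 100.0 * (after_count - before_count) / before_count
    return int(change + 0.5) if change >= 0 else -int(-change + 0.5)


def load_indicator_rules(path: str | Path) -> list[IndicatorRule]:
    with Path(path).open(newline="", encoding="utf-8") as fh:
        return [
            IndicatorRule(
                rule_id=row["rule_id"].strip(),
                gene=row["gene"].strip(),
                phenotype_match=row["phenotype_match"].strip(),
                indicator_name=row["indicator_name"].strip(),
                provider_text=row.get("provider_text", "").strip(),
                patient_text=row.get("patient_text", "").strip(),
                actionable=row.get("actionable", "true").strip().lower() in ("true", "1", "yes"),
            )
            for row in csv.DictReader(fh)
        ]


def load_drug_gene_rules(path: str | Path) -> list[DrugGeneRule]:
    rules = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            overrides = tuple(
                OverrideAction(o.strip())
                for o in row.get("override_options", "").split(";")
                if o.strip()
            )
            rules.append(
                DrugGeneRule(
                    medication=row["medication"].strip(),
                    gene=row["gene"].strip(),
                    phenotype_match=row["phenotype_match"].strip(),
                    recommendation_text=row.get("recommendation_text", "").strip(),
                    default_action=DefaultAction(row["default_action"].strip()),
                    override_options=overrides,
                    rule_id=row.get("rule_id", "").strip(),
                )
            )
    return rules


def append_alert_audit(alerts: Sequence[CDSAlert], path: str | Path) -> None:
    """Append fired alerts to a JSON-lines audit log."""
    with Path(path).open("a", encoding="utf-8") as fh:
        for a in alerts:
            fh.write(
                json.dumps(
                    {
                        "medication": a.medication,
                        "indicator": a.triggering_indicator.indicator_name,
                        "gene": a.triggering_indicator.gene,
                        "phenotype": a.triggering_indicator.phenotype,
                        "default_action": a.default_action.value,
                        "override_options": [o.value for o in a.override_options],
                        "fired_at": a.fired_at.isoformat(),
                    },
                    sort_keys=True,
                )
                + "\n"
            )
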