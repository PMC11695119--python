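"""Instrument export → per-sample, per-gene diplotype/phenotype results.

This is the translation step that replaces third-party allele-typing
software: raw TaqMan allele-call strings are matched against the probe table
to give per-assay calls (Normal / Heterozygous / Mutant, plus NoCall for
anything unrecognised), the per-gene call combination is looked up verbatim
in the genotype rule table to give a star-allele diplotype, and the
phenotype table supplies the reportable content. Lookup is pure — nothing is
inferred beyond what the tables enumerate. Any NoCall within a gene blocks
that gene's result (status ``IncompleteNoCall``) rather than guessing, and a
failing gene never suppresses a sample's other genes.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

from .tables import (
    CALL_HET,
    CALL_MUTANT,
    CALL_NORMAL,
    PhenotypeRecord,
    ProbeDefinition,
    TranslatorTables,
)


class ExportFormatError(ValueError):
    """The instrument export file violates its documented layout."""


class ContractError(ValueError):
    """An operation was invoked outside its stated preconditions."""


class UnmappedDiplotypeError(KeyError):
    """A diplotype has no phenotype record — signals translator-table drift."""


class Call(str, enum.Enum):
    NORMAL = CALL_NORMAL
    HETEROZYGOUS = CALL_HET
    MUTANT = CALL_MUTANT
    NO_CALL = "NoCall"


class ResultStatus(str, enum.Enum):
    RESULTED = "Resulted"
    UNMAPPED_COMBINATION = "UnmappedCombination"
    INCOMPLETE_NO_CALL = "IncompleteNoCall"


@dataclass(frozen=True)
class RawCall:
    sample_id: str
    assay_id: str
    raw_value: str


@dataclass
class InstrumentExport:
    calls: list[RawCall]
    source_files: list[str]
    export_timestamp: datetime

    def sample_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.calls:
            seen.setdefault(c.sample_id, None)
        return list(seen)

    def by_sample_assay(self) -> dict[tuple[str, str], RawCall]:
        return {(c.sample_id, c.assay_id): c for c in self.calls}


@dataclass(frozen=True)
class AssayCall:
    sample_id: str
    gene: str
    assay_id: str
    call: Call


@dataclass(frozen=True)
class SampleGeneResult:
    """Reportable result for one sample × gene.

    ``status`` is ``Resulted`` iff both diplotype and phenotype are present;
    the abnormal flag is copied from the phenotype table, never computed.
    """

    sample_id: str
    gene: str
    diplotype: str | None = None
    phenotype: str | None = None
    activity_score: float | None = None
    comment: str = ""
    abnormal: bool = False
    status: ResultStatus = ResultStatus.RESULTED
    var_display: str = ""
    lrr_display: str = ""

    @property
    def resulted(self) -> bool:
        return self.status is ResultStatus.RESULTED


EXPORT_COLUMNS = ("sample", "assay_id", "call")


def parse_instrument_export(path: str | Path) -> InstrumentExport:
    """Read a plate export CSV (columns: sample, assay_id, call).

    One RawCall per data row, verbatim — interpretation (including
    "Undetermined") is deferred to translation. Blank sample or assay cells
    and duplicate (sample, assay) pairs are format errors, not silent drops.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"instrument export not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = [h.strip().lower() for h in next(reader)]
        except StopIteration:
            raise ExportFormatError(f"{path.name}: empty file") from None
        for col in EXPORT_COLUMNS:
            if col not in header:
                raise ExportFormatError(f"{path.name}: missing required column '{col}'")
        idx = {col: header.index(col) for col in EXPORT_COLUMNS}
        calls: list[RawCall] = []
        seen: set[tuple[str, str]] = set()
        for rownum, raw in enumerate(reader, start=2):
            if not any(cell.strip() for cell in raw):
                continue
            sample = raw[idx["sample"]].strip()
            assay = raw[idx["assay_id"]].strip()
            value = raw[idx["call"]].strip()
            if not sample or not assay:
                raise ExportFormatError(f"{path.name} row {rownum}: blank sample or assay_id")
            key = (sample, assay)
            if key in seen:
                raise ExportFormatError(f"{path.name} row {rownum}: duplicate (sample, assay) pair {key}")
            seen.add(key)
            calls.append(RawCall(sample_id=sample, assay_id=assay, raw_value=value))
    return InstrumentExport(
        calls=calls,
        source_files=[path.name],
        export_timestamp=datetime.now(timezone.utc),
    )


def translate_raw_call(raw: RawCall, probe: ProbeDefinition) -> AssayCall:
    """Map one raw instrument string to Normal/Heterozygous/Mutant/NoCall.

    Anything not matching the probe's three call strings — "Undetermined",
    an empty cell, an unexpected allele order — is a NoCall.
    """
    if raw.assay_id != probe.assay_id:
        raise ContractError(
            f"raw call assay '{raw.assay_id}' does not match probe '{probe.assay_id}'"
        )
    if raw.raw_value == probe.ref_call:
        call = Call.NORMAL
    elif raw.raw_value == probe.het_call:
        call = Call.HETEROZYGOUS
    elif raw.raw_value == probe.var_call:
        call = Call.MUTANT
    else:
        call = Call.NO_CALL
    return AssayCall(sample_id=raw.sample_id, gene=probe.gene, assay_id=raw.assay_id, call=call)


def apply_gene_symbol_replacements(raw_symbol: str, replacements: Mapping[str, str]) -> str:
    """Normalise an assay-specific gene label to its reporting symbol.

    Total: unknown symbols pass through unchanged.
    """
    return replacements.get(raw_symbol, raw_symbol)


def call_diplotype(
    sample_id: str,
    gene: str,
    calls: Mapping[str, AssayCall],
    tables: TranslatorTables,
) -> tuple[ResultStatus, str | None]:
    """Exact-match the per-assay call combination against the rule table.

    Any NoCall among the gene's assays blocks the call; an enumerated match
    yields (Resulted, diplotype); anything else is UnmappedCombination.
    """
    gene_assays = [p.assay_id for p in tables.probes_for_gene(gene)]
    missing = [a for a in gene_assays if a not in calls]
    if missing:
        raise ContractError(f"sample '{sample_id}' gene '{gene}': missing assay calls {missing}")
    if any(calls[a].call is Call.NO_CALL for a in gene_assays):
        return ResultStatus.INCOMPLETE_NO_CALL, None
    pattern = frozenset((a, calls[a].call.value) for a in gene_assays)
    diplotype = tables.rule_index().get((gene, pattern))
    if diplotype is None:
        return ResultStatus.UNMAPPED_COMBINATION, None
    return ResultStatus.RESULTED, diplotype


def resolve_phenotype(gene: str, diplotype: str, tables: TranslatorTables) -> PhenotypeRecord:
    """Fetch the unique phenotype record for (gene, diplotype)."""
    rec = tables.phenotype_index().get((gene, diplotype))
    if rec is None:
        raise UnmappedDiplotypeError(f"unmapped diplotype ({gene}, {diplotype})")
    return rec


def process_batch(
    export: InstrumentExport,
    tables: TranslatorTables,
    replacements: Mapping[str, str] | None = None,
) -> list[SampleGeneResult]:
    """Translate a whole plate: one result per (sample, panel gene).

    Deterministic ordering: samples in first-appearance order of the export,
    genes in panel order. Assays absent from the export are treated as
    NoCall, so the affected gene is reported IncompleteNoCall rather than
    aborting the batch; every other gene of the sample still results.
    """
    replacements = replacements or {}
    probe_by_assay = tables.probe_by_assay()
    raw_index = export.by_sample_assay()
    rule_index = tables.rule_index()
    pheno_index = tables.phenotype_index()

    assays_by_gene: dict[str, list[str]] = {}
    for p in tables.probes:
        gene = apply_gene_symbol_replacements(p.gene, replacements)
        assays_by_gene.setdefault(gene, []).append(p.assay_id)

    results: list[SampleGeneResult] = []
    for sample_id in export.sample_ids():
        for gene in tables.panel_genes:
            assay_ids = assays_by_gene.get(gene, [])
            calls: dict[str, AssayCall] = {}
            for assay_id in assay_ids:
                raw = raw_index.get((sample_id, assay_id))
                if raw is None:
                    calls[assay_id] = AssayCall(sample_id, gene, assay_id, Call.NO_CALL)
                else:
                    calls[assay_id] = translate_raw_call(raw, probe_by_assay[assay_id])
            if not assay_ids or any(c.call is Call.NO_CALL for c in calls.values()):
                results.append(SampleGeneResult(sample_id, gene, status=ResultStatus.INCOMPLETE_NO_CALL))
                continue
            pattern = frozenset((a, calls[a].call.value) for a in assay_ids)
            diplotype = rule_index.get((gene, pattern))
            if diplotype is None:
                results.append(SampleGeneResult(sample_id, gene, status=ResultStatus.UNMAPPED_COMBINATION))
                continue
            rec = pheno_index.get((gene, diplotype))
            if rec is None:
                results.append(SampleGeneResult(sample_id, gene, status=ResultStatus.UNMAPPED_COMBINATION))
                continue
            results.append(
                SampleGeneResult(
                    sample_id=sample_id,
                    gene=gene,
                    diplotype=diplotype,
                    phenotype=rec.phenotype,
                    activity_score=rec.activity_score,
                    comment=rec.comment,
                    abnormal=rec.abnormal,
                    status=ResultStatus.RESULTED,
                    var_display=rec.var_display,
                    lrr_display=rec.lrr_display,
                )
            )
    return results


def results_to_csv(results: list[SampleGeneResult], path: str | Path) -> None:
    """Audit export: one tidy row per sample × gene."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["sample", "gene", "status", "diplotype", "phenotype", "activity_score", "abnormal", "comment"]
        )
        for r in results:
            w.writerow(
                [
                    r.sample_id,
                    r.gene,
                    r.status.value,
                    r.diplotype or "",
                    r.phenotype or "",
                    "" if r.activity_score is None else f"{r.activity_score:g}",
                    "true" if r.abnormal else "false",
                    r.comment,
                ]
            )
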