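"""Translator tables driving the raw-call → diplotype → phenotype translation.

The whole translation step is table-driven, in a three-file design:

* a **probe table** mapping each TaqMan assay to its gene and to the three raw
  instrument call strings meaning homozygous reference, heterozygous and
  homozygous variant;
* a **genotype table** enumerating, per gene, every combination of per-assay
  calls (Normal / Heterozygous / Mutant) together with the star-allele
  diplotype it translates to — diplotype calling is pure lookup, no phasing
  inference;
* a **phenotype table** mapping each (gene, diplotype) to its reportable
  content: CPIC-style predicted phenotype, optional activity score, lab
  comment, EHR abnormal flag, and the display strings used by the two EHR
  record styles (LRR and VAR).

Files are comma-delimited UTF-8 with a header row; header names are matched
case-insensitively after trimming. Unknown extra columns are preserved as
opaque notes so institution-specific extensions never break loading.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

CALL_NORMAL = "Normal"
CALL_HET = "Heterozygous"
CALL_MUTANT = "Mutant"
CALL_VALUES = (CALL_NORMAL, CALL_HET, CALL_MUTANT)


class SchemaError(ValueError):
    """A translator file is structurally unusable (missing column, no data)."""


@dataclass(frozen=True)
class ProbeDefinition:
    """One genotyping assay: its gene and the three raw call strings."""

    assay_id: str
    gene: str
    marker_id: str
    ref_call: str
    het_call: str
    var_call: str
    notes: str = ""


@dataclass(frozen=True)
class GenotypeRule:
    """One enumerated assay-call combination and the diplotype it yields."""

    gene: str
    call_pattern: Mapping[str, str]  # assay_id -> Normal|Heterozygous|Mutant
    diplotype: str

    def pattern_key(self) -> frozenset:
        return frozenset(self.call_pattern.items())


@dataclass(frozen=True)
class PhenotypeRecord:
    """Reportable content for one (gene, diplotype)."""

    gene: str
    diplotype: str
    phenotype: str
    activity_score: float | None
    comment: str
    abnormal: bool
    var_display: str
    lrr_display: str


@dataclass
class TranslatorTables:
    """The three coupled lookup tables plus the derived panel gene order."""

    probes: list[ProbeDefinition]
    genotype_rules: list[GenotypeRule]
    phenotypes: list[PhenotypeRecord]
    panel_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.panel_genes:
            seen: dict[str, None] = {}
            for rule in self.genotype_rules:
                seen.setdefault(rule.gene, None)
            self.panel_genes = list(seen)

    def probes_for_gene(self, gene: str) -> list[ProbeDefinition]:
        return [p for p in self.probes if p.gene == gene]

    def probe_by_assay(self) -> dict[str, ProbeDefinition]:
        return {p.assay_id: p for p in self.probes}

    def rule_index(self) -> dict[tuple[str, frozenset], str]:
        """(gene, frozen call pattern) -> diplotype, for exact-match lookup."""
        return {(r.gene, r.pattern_key()): r.diplotype for r in self.genotype_rules}

    def phenotype_index(self) -> dict[tuple[str, str], PhenotypeRecord]:
        return {(rec.gene, rec.diplotype): rec for rec in self.phenotypes}


@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    table: str
    row: int  # 1-based data row within that table
    message: str


PROBE_COLUMNS = ("assay_id", "gene", "marker_id", "ref_call", "het_call", "var_call")
PHENOTYPE_COLUMNS = (
    "gene",
    "diplotype",
    "phenotype",
    "activity_score",
    "comment",
    "abnormal",
    "var_display",
    "lrr_display",
)

_TRUE_STRINGS = {"true", "1", "yes", "y", "t"}


def _read_rows(path: str | Path, required: Iterable[str]) -> tuple[list[str], list[dict[str, str]]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"translator file not found: {path}")
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            raw_header = next(reader)
        except StopIteration:
            raise SchemaError(f"{path.name}: empty data section") from None
        header = [h.strip().lower() for h in raw_header]
        for col in required:
            if col not in header:
                raise SchemaError(f"{path.name}: missing required column '{col}'")
        rows = []
        for raw in reader:
            if not any(cell.strip() for cell in raw):
                continue
            row = {header[i]: (raw[i].strip() if i < len(raw) else "") for i in range(len(header))}
            rows.append(row)
    if not rows:
        raise SchemaError(f"{path.name}: empty data section")
    return header, rows


def load_translation_tables(
    probe_path: str | Path,
    genotype_path: str | Path,
    phenotype_path: str | Path,
) -> TranslatorTables:
    """Parse the three translator CSVs, preserving file row order.

    Whitespace is trimmed; cross-table references are NOT checked here — run
    :func:`validate_tables` on the result before using it clinically.
    """
    _, probe_rows = _read_rows(probe_path, PROBE_COLUMNS)
    probes = [
        ProbeDefinition(
            assay_id=r["assay_id"],
            gene=r["gene"],
            marker_id=r.get("marker_id", ""),
            ref_call=r["ref_call"],
            het_call=r["het_call"],
            var_call=r["var_call"],
            notes=r.get("notes", ""),
        )
        for r in probe_rows
    ]

    geno_header, geno_rows = _read_rows(genotype_path, ("gene", "diplotype"))
    assay_columns = [c for c in geno_header if c not in ("gene", "diplotype")]
    # assay_id columns keep their original (trimmed) case from the probe file;
    # header lowering must not orphan them, so remap via the probe table.
    case_map = {p.assay_id.lower(): p.assay_id for p in probes}
    rules = []
    for r in geno_rows:
        pattern = {
            case_map.get(col, col): r[col]
            for col in assay_columns
            if r.get(col, "")
        }
        rules.append(GenotypeRule(gene=r["gene"], call_pattern=pattern, diplotype=r["diplotype"]))

    _, pheno_rows = _read_rows(phenotype_path, ("gene", "diplotype", "phenotype"))
    phenotypes = []
    for r in pheno_rows:
        score_text = r.get("activity_score", "")
        score = float(score_text) if score_text else None
        phenotypes.append(
            PhenotypeRecord(
                gene=r["gene"],
                diplotype=r["diplotype"],
                phenotype=r["phenotype"],
                activity_score=score,
                comment=r.get("comment", ""),
                abnormal=r.get("abnormal", "").lower() in _TRUE_STRINGS,
                var_display=r.get("var_display", ""),
                lrr_display=r.get("lrr_display", ""),
            )
        )
    return TranslatorTables(probes=probes, genotype_rules=rules, phenotypes=phenotypes)


def save_translation_tables(
    tables: TranslatorTables,
    probe_path: str | Path,
    genotype_path: str | Path,
    phenotype_path: str | Path,
) -> None:
    """Write the three CSVs back out in the documented column layout."""
    with Path(probe_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(PROBE_COLUMNS) + ["notes"])
        for p in tables.probes:
            w.writerow([p.assay_id, p.gene, p.marker_id, p.ref_call, p.het_call, p.var_call, p.notes])

    assay_ids: list[str] = []
    for p in tables.probes:
        if p.assay_id not in assay_ids:
            assay_ids.append(p.assay_id)
    for rule in tables.genotype_rules:  # keep columns for assays absent from probes
        for aid in rule.call_pattern:
            if aid not in assay_ids:
                assay_ids.append(aid)
    with Path(genotype_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["gene"] + assay_ids + ["diplotype"])
        for rule in tables.genotype_rules:
            w.writerow(
                [rule.gene]
                + [rule.call_pattern.get(aid, "") for aid in assay_ids]
                + [rule.diplotype]
            )

    with Path(phenotype_path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(PHENOTYPE_COLUMNS))
        for rec in tables.phenotypes:
            w.writerow(
                [
                    rec.gene,
                    rec.diplotype,
                    rec.phenotype,
                    "" if rec.activity_score is None else f"{rec.activity_score:g}",
                    rec.comment,
                    "true" if rec.abnormal else "false",
                    rec.var_display,
                    rec.lrr_display,
                ]
            )


def validate_tables(tables: TranslatorTables) -> list[Finding]:
    """Check every intra- and cross-table invariant; findings, not exceptions.

    The findings list is deterministic and ordered by (table, row). An empty
    list means the tables are safe to drive translation.
    """
    findings: list[Finding] = []

    seen_assays: dict[str, int] = {}
    for i, p in enumerate(tables.probes, start=1):
        if not p.gene:
            findings.append(Finding("error", "probe", i, f"assay '{p.assay_id}': empty gene"))
        if p.assay_id in seen_assays:
            findings.append(
                Finding("error", "probe", i, f"duplicate assay_id '{p.assay_id}' (first at row {seen_assays[p.assay_id]})")
            )
        else:
            seen_assays[p.assay_id] = i
        calls = (p.ref_call, p.het_call, p.var_call)
        if len(set(calls)) != 3:
            findings.append(
                Finding("error", "probe", i, f"assay '{p.assay_id}': ref/het/var call strings not pairwise distinct")
            )

    probe_by_assay = tables.probe_by_assay()
    pheno_keys = {(rec.gene, rec.diplotype) for rec in tables.phenotypes}
    seen_patterns: dict[tuple[str, frozenset], int] = {}
    for i, rule in enumerate(tables.genotype_rules, start=1):
        for assay_id, call in sorted(rule.call_pattern.items()):
            probe = probe_by_assay.get(assay_id)
            if probe is None:
                findings.append(
                    Finding("error", "genotype", i, f"rule references unknown assay_id '{assay_id}'")
                )
            elif probe.gene != rule.gene:
                findings.append(
                    Finding(
                        "error", "genotype", i,
                        f"assay '{assay_id}' belongs to gene '{probe.gene}', rule is for '{rule.gene}'",
                    )
                )
            if call not in CALL_VALUES:
                findings.append(
                    Finding("error", "genotype", i, f"invalid call value '{call}' for assay '{assay_id}'")
                )
        key = (rule.gene, rule.pattern_key())
        if key in seen_patterns:
            findings.append(
                Finding("error", "genotype", i, f"duplicate call pattern for gene '{rule.gene}' (first at row {seen_patterns[key]})")
            )
        else:
            seen_patterns[key] = i
        if (rule.gene, rule.diplotype) not in pheno_keys:
            findings.append(
                Finding("error", "genotype", i, f"unmapped diplotype: no phenotype record for ({rule.gene}, {rule.diplotype})")
            )

    seen_pheno: dict[tuple[str, str], int] = {}
    for i, rec in enumerate(tables.phenotypes, start=1):
        key = (rec.gene, rec.diplotype)
        if key in seen_pheno:
            findings.append(
                Finding("error", "phenotype", i, f"duplicate (gene, diplotype) ({rec.gene}, {rec.diplotype}) (first at row {seen_pheno[key]})")
            )
        else:
            seen_pheno[key] = i
        if not rec.phenotype:
            findings.append(Finding("error", "phenotype", i, f"empty phenotype for ({rec.gene}, {rec.diplotype})"))
        if rec.activity_score is not None and rec.activity_score < 0:
            findings.append(
                Finding("error", "phenotype", i, f"negative activity score for ({rec.gene}, {rec.diplotype})")
            )

    table_order = {"probe": 0, "genotype": 1, "phenotype": 2}
    findings.sort(key=lambda f: (table_order[f.table], f.row))
    return findings
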