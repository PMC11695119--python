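"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here with no external
data: internally consistent toy translator tables, TaqMan-style plate
exports sampled under Hardy–Weinberg equilibrium with a configurable
no-call rate, and a matching ancillary-order feed.

The toy panel model: each gene is covered by ``k`` biallelic assays, and
assay ``i`` defines star allele ``*(i+1)`` (the reference allele is ``*1``).
Assays are sampled independently — no linkage between variant sites — so
truth assignment from per-assay calls is unambiguous, and the genotype rule
table enumerates all ``3^k`` call combinations per gene. Independence means
combinations with more than two total variant copies are reachable; the
enumerated table resolves them by keeping the two highest-numbered alleles
(a toy convention, documented as such).

The default configuration mirrors an eight-gene pharmacogene panel
(CYP2C19, CYP2D6, CYP2C9, CYP3A5, CYP4F2, the CYP2C cluster, SLCO1B1,
VKORC1) on a 96-well plate, with activity scores reported for CYP2D6 and
CYP2C9 and non-metabolizer phenotype wording for the transporter and
sensitivity genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import numpy as np

from .engine import InstrumentExport, RawCall
from .hl7 import HL7Message, Segment, escape_text, format_hl7_timestamp
from .tables import (
    CALL_HET,
    CALL_MUTANT,
    CALL_NORMAL,
    GenotypeRule,
    PhenotypeRecord,
    ProbeDefinition,
    TranslatorTables,
)


class ConfigError(ValueError):
    """The simulation configuration violates its invariants."""


NO_CALL_VALUE = "Undetermined"

_BASE_PAIRS = (("A", "G"), ("C", "T"), ("G", "T"), ("A", "C"), ("C", "G"))

#: phenotype wording per variant-allele count, by style
_PHENOTYPE_STYLES = {
    "metabolizer": ("Normal Metabolizer", "Intermediate Metabolizer", "Poor Metabolizer"),
    "function": ("Normal Function", "Decreased Function", "Poor Function"),
    "sensitivity": ("Normal Sensitivity", "Increased Sensitivity", "High Sensitivity"),
}


@dataclass(frozen=True)
class GeneSpec:
    """One toy gene: assay count, optional allele activity values, wording."""

    name: str
    n_assays: int
    allele_activities: dict[str, float] | None = None  # "*1" -> 1.0, ...
    phenotype_style: str = "metabolizer"

    def alleles(self) -> list[str]:
        return [f"*{i}" for i in range(1, self.n_assays + 2)]


@dataclass
class SimulationConfig:
    genes: list[GeneSpec]
    n_samples: int = 96
    variant_allele_freqs: dict[str, float] = field(default_factory=dict)
    nocall_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [g.name for g in self.genes]
        if len(names) != len(set(names)):
            raise ConfigError("duplicate gene names in configuration")
        for g in self.genes:
            if g.n_assays < 1:
                raise ConfigError(f"gene '{g.name}' must have at least one assay")
            if g.phenotype_style not in _PHENOTYPE_STYLES:
                raise ConfigError(f"unknown phenotype style '{g.phenotype_style}'")
            if g.allele_activities is not None:
                missing = set(g.alleles()) - set(g.allele_activities)
                if missing:
                    raise ConfigError(f"gene '{g.name}': missing activity values for {sorted(missing)}")
        if self.n_samples < 1:
            raise ConfigError("n_samples must be >= 1")
        if not 0.0 <= self.nocall_rate <= 1.0:
            raise ConfigError("nocall_rate must be in [0, 1]")
        for assay_id, f in self.variant_allele_freqs.items():
            if not 0.0 <= f <= 1.0:
                raise ConfigError(f"variant allele frequency for '{assay_id}' outside [0, 1]")
        # fill unset frequencies with a deterministic mild default
        for g in self.genes:
            for i in range(1, g.n_assays + 1):
                self.variant_allele_freqs.setdefault(assay_id_for(g.name, i), 0.15 if i == 1 else 0.08)


def assay_id_for(gene: str, index: int) -> str:
    return f"{gene}_A{index}"


def default_allele_activities(n_assays: int) -> dict[str, float]:
    """*1 fully functional; higher-numbered variant alleles lose function."""
    acts = {"*1": 1.0}
    for j in range(2, n_assays + 2):
        acts[f"*{j}"] = max(0.0, 1.0 - 0.5 * (j - 1))
    return acts


PANEL_GENE_NAMES = (
    "CYP2C19",
    "CYP2D6",
    "CYP2C9",
    "CYP3A5",
    "CYP4F2",
    "CYP2C_CLUSTER",
    "SLCO1B1",
    "VKORC1",
)


def default_config(
    n_genes: int = 2,
    n_samples: int = 96,
    nocall_rate: float = 0.0,
    seed: int = 0,
) -> SimulationConfig:
    """The standard study panel: first ``n_genes`` of the eight-gene panel.

    CYP2C19 and CYP2D6 come first so the two-gene toy panel exercises both a
    plain metabolizer gene and an activity-score gene.
    """
    if not 1 <= n_genes <= len(PANEL_GENE_NAMES):
        raise ConfigError(f"n_genes must be in 1..{len(PANEL_GENE_NAMES)}")
    specs = []
    for name in PANEL_GENE_NAMES[:n_genes]:
        n_assays = 2 if name in ("CYP2C19", "CYP2D6", "CYP2C9") else 1
        activities = default_allele_activities(n_assays) if name in ("CYP2D6", "CYP2C9") else None
        style = "metabolizer"
        if name == "SLCO1B1":
            style = "function"
        elif name in ("VKORC1", "CYP4F2"):
            style = "sensitivity"
        specs.append(GeneSpec(name=name, n_assays=n_assays, allele_activities=activities, phenotype_style=style))
    return SimulationConfig(genes=specs, n_samples=n_samples, nocall_rate=nocall_rate, seed=seed)


def _diplotype_from_copies(gene: GeneSpec, copies: Sequence[int]) -> tuple[str, str]:
    """Resolve per-assay variant copy counts to a diplotype's two alleles.

    Expand the variant-allele multiset, pad with *1 below two copies, and
    keep the two highest-numbered alleles when over two (toy convention for
    the unlinked-assay combinations a real panel would flag for review).
    """
    alleles: list[int] = []
    for i, c in enumerate(copies):
        alleles.extend([i + 2] * c)
    alleles.sort()
    while len(alleles) < 2:
        alleles.insert(0, 1)
    pair = sorted(alleles[-2:])
    return f"*{pair[0]}", f"*{pair[1]}"


def _phenotype_for(gene: GeneSpec, allele_a: str, allele_b: str) -> tuple[str, float | None]:
    if gene.allele_activities is not None:
        score = gene.allele_activities[allele_a] + gene.allele_activities[allele_b]
        if score == 0:
            pheno = "Poor Metabolizer"
        elif score < 1.25:
            pheno = "Intermediate Metabolizer"
        elif score <= 2.25:
            pheno = "Normal Metabolizer"
        else:
            pheno = "Ultrarapid Metabolizer"
        return pheno, score
    wording = _PHENOTYPE_STYLES[gene.phenotype_style]
    n_variant = (allele_a != "*1") + (allele_b != "*1")
    return wording[n_variant], None


def truth_for_copies(gene: GeneSpec, copies: Sequence[int]) -> tuple[str, str, float | None]:
    """(diplotype, phenotype, activity score) for one call combination."""
    a, b = _diplotype_from_copies(gene, copies)
    pheno, score = _phenotype_for(gene, a, b)
    return f"{a}/{b}", pheno, score


_CALL_OF_COPIES = {0: CALL_NORMAL, 1: CALL_HET, 2: CALL_MUTANT}


def generate_toy_panel_tables(config: SimulationConfig) -> TranslatorTables:
    """Emit internally consistent probe/genotype/phenotype tables.

    Genotype rules enumerate every reachable call combination (3^k per
    k-assay gene), so diplotype calling downstream is pure lookup and
    ``validate_tables`` returns zero findings by construction.
    """
    probes: list[ProbeDefinition] = []
    rules: list[GenotypeRule] = []
    phenos: dict[tuple[str, str], PhenotypeRecord] = {}
    for gi, gene in enumerate(config.genes):
        for i in range(1, gene.n_assays + 1):
            b1, b2 = _BASE_PAIRS[(gi + i) % len(_BASE_PAIRS)]
            probes.append(
                ProbeDefinition(
                    assay_id=assay_id_for(gene.name, i),
                    gene=gene.name,
                    marker_id=f"rs{90000 + gi * 100 + i}",
                    ref_call=f"{b1}/{b1}",
                    het_call=f"{b1}/{b2}",
                    var_call=f"{b2}/{b2}",
                    notes=f"defines {gene.name} *{i + 1}",
                )
            )
        for copies in itertools.product((0, 1, 2), repeat=gene.n_assays):
            diplotype, pheno, score = truth_for_copies(gene, copies)
            pattern = {
                assay_id_for(gene.name, i + 1): _CALL_OF_COPIES[c]
                for i, c in enumerate(copies)
            }
            rules.append(GenotypeRule(gene=gene.name, call_pattern=pattern, diplotype=diplotype))
            key = (gene.name, diplotype)
            if key not in phenos:
                normal = pheno.startswith("Normal")
                phenos[key] = PhenotypeRecord(
                    gene=gene.name,
                    diplotype=diplotype,
                    phenotype=pheno,
                    activity_score=score,
                    comment=f"{gene.name} {diplotype}: predicted {pheno} by panel translation tables.",
                    abnormal=not normal,
                    var_display=pheno,
                    lrr_display=pheno,
                )
    return TranslatorTables(probes=probes, genotype_rules=rules, phenotypes=list(phenos.values()))


@dataclass
class GroundTruth:
    """Simulator bookkeeping: per (sample, gene) the true diplotype,
    phenotype and activity score, recorded before no-call injection."""

    records: dict[tuple[str, str], tuple[str, str, float | None]]

    def diplotype(self, sample_id: str, gene: str) -> str:
        return self.records[(sample_id, gene)][0]

    def phenotype(self, sample_id: str, gene: str) -> str:
        return self.records[(sample_id, gene)][1]


def simulate_plate(
    config: SimulationConfig,
    out_path: str | Path | None = None,
) -> tuple[InstrumentExport, GroundTruth]:
    """Sample a plate export under Hardy–Weinberg with no-call injection.

    Per sample and assay the variant-copy count is drawn from the assay's
    allele frequency (homozygous variant f², heterozygous 2f(1−f)); truth is
    recorded before a fraction ``nocall_rate`` of raw values is replaced by
    "Undetermined". Same seed → byte-identical export CSV.
    """
    rng = np.random.default_rng(config.seed)
    calls: list[RawCall] = []
    truth: dict[tuple[str, str], tuple[str, str, float | None]] = {}
    raw_strings: dict[str, tuple[str, str, str]] = {}
    for gi, g in enumerate(config.genes):
        for i in range(1, g.n_assays + 1):
            b1, b2 = _BASE_PAIRS[(gi + i) % len(_BASE_PAIRS)]
            raw_strings[assay_id_for(g.name, i)] = (f"{b1}/{b1}", f"{b1}/{b2}", f"{b2}/{b2}")

    for s in range(1, config.n_samples + 1):
        sample_id = f"S-{s:04d}"
        for gene in config.genes:
            copies: list[int] = []
            for i in range(1, gene.n_assays + 1):
                assay_id = assay_id_for(gene.name, i)
                f = config.variant_allele_freqs[assay_id]
                u = rng.random()
                if u < f * f:
                    c = 2
                elif u < f * f + 2 * f * (1 - f):
                    c = 1
                else:
                    c = 0
                copies.append(c)
                ref, het, var = raw_strings[assay_id]
                value = (ref, het, var)[c]
                if rng.random() < config.nocall_rate:
                    value = NO_CALL_VALUE
                calls.append(RawCall(sample_id=sample_id, assay_id=assay_id, raw_value=value))
            truth[(sample_id, gene.name)] = truth_for_copies(gene, copies)

    export = InstrumentExport(
        calls=calls,
        source_files=[f"sim_plate_seed{config.seed}.csv"],
        export_timestamp=datetime(2024, 1, 1, tzinfo=timezone.utc),
    )
    if out_path is not None:
        write_export_csv(export, out_path)
    return export, GroundTruth(records=truth)


def write_export_csv(export: InstrumentExport, path: str | Path) -> None:
    lines = ["sample,assay_id,call"]
    lines += [f"{c.sample_id},{c.assay_id},{c.raw_value}" for c in export.calls]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_truth_csv(truth: GroundTruth, path: str | Path) -> None:
    lines = ["sample,gene,diplotype,phenotype,activity_score"]
    for (sample, gene), (dip, pheno, score) in truth.records.items():
        lines.append(f"{sample},{gene},{dip},{pheno},{'' if score is None else f'{score:g}'}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def simulate_order_feed(
    export: InstrumentExport,
    patients: Sequence[tuple[str, str]] | None = None,
    order_time: datetime | None = None,
    test_code: str = "GATORPGX",
) -> list[HL7Message]:
    """One ancillary order message per sample; specimen id = sample id.

    Synthetic demographics are deterministic functions of the sample index
    unless explicit (patient_id, patient_name) pairs are supplied.
    """
    order_time = order_time or datetime(2024, 1, 1, 8, 0, 0)
    ts = format_hl7_timestamp(order_time)
    messages: list[HL7Message] = []
    for idx, sample_id in enumerate(export.sample_ids(), start=1):
        if patients is not None and idx - 1 < len(patients):
            patient_id, patient_name = patients[idx - 1]
        else:
            patient_id, patient_name = f"P{idx:04d}", f"SIM^PATIENT{idx:04d}"
        msh = Segment("MSH")
        msh.set(2, "^~\\&")
        msh.set(3, "EHR")
        msh.set(5, "PGXBRIDGE")
        msh.set(7, ts)
        msh.set(9, "ORM^O01")
        msh.set(10, f"ORD{idx:06d}")
        msh.set(11, "P")
        msh.set(12, "2.5.1")
        pid = Segment("PID")
        pid.set(1, "1")
        pid.set(3, escape_text(patient_id))
        pid.set(5, patient_name)
        orc = Segment("ORC")
        orc.set(1, "NW")
        orc.set(2, f"PLC{idx:06d}")
        orc.set(3, f"FIL{idx:06d}")
        obr = Segment("OBR")
        obr.set(1, "1")
        obr.set(2, f"PLC{idx:06d}")
        obr.set(3, escape_text(sample_id))
        obr.set(4, f"{test_code}^Pharmacogenomics Panel")
        obr.set(6, ts)
        messages.append(HL7Message(segments=[msh, pid, orc, obr]))
    return messages


def default_indicator_rules(tables: TranslatorTables) -> list:
    """An indicator rule per distinct abnormal (gene, phenotype) plus the
    normal-function phenotypes flagged non-actionable."""
    from .indicators import IndicatorRule

    seen: dict[tuple[str, str], bool] = {}
    for rec in tables.phenotypes:
        seen.setdefault((rec.gene, rec.phenotype), rec.abnormal)
    rules = []
    for n, ((gene, pheno), abnormal) in enumerate(sorted(seen.items()), start=1):
        rules.append(
            IndicatorRule(
                rule_id=f"IND{n:03d}",
                gene=gene,
                phenotype_match=pheno,
                indicator_name=f"{gene} {pheno}",
                provider_text=f"Patient is predicted {pheno} for {gene}; review gene-drug guidance before prescribing affected medications.",
                patient_text=f"Your genetic test shows a {pheno.lower()} result for the {gene} gene.",
                actionable=abnormal,
            )
        )
    return rules


def default_drug_gene_rules() -> list:
    """Illustrative single-gene drug rules, including the clopidogrel /
    CYP2C19 poor-metabolizer alert whose default is to remove the order."""
    from .indicators import DefaultAction, DrugGeneRule, OverrideAction

    both = (OverrideAction.KEEP_ORDER, OverrideAction.DISMISS)
    return [
        DrugGeneRule(
            rule_id="CDS001",
            medication="clopidogrel",
            gene="CYP2C19",
            phenotype_match="Poor Metabolizer",
            recommendation_text="Consider prasugrel or ticagrelor: CYP2C19 poor metabolizers have reduced clopidogrel activation.",
            default_action=DefaultAction.REMOVE_ORDER,
            override_options=both,
        ),
        DrugGeneRule(
            rule_id="CDS002",
            medication="clopidogrel",
            gene="CYP2C19",
            phenotype_match="Intermediate Metabolizer",
            recommendation_text="Consider alternative antiplatelet therapy: reduced clopidogrel activation expected.",
            default_action=DefaultAction.KEEP_ORDER,
            override_options=(OverrideAction.DISMISS,),
        ),
        DrugGeneRule(
            rule_id="CDS003",
            medication="codeine",
            gene="CYP2D6",
            phenotype_match="Poor Metabolizer",
            recommendation_text="Avoid codeine: insufficient morphine formation expected; select a non-tramadol alternative.",
            default_action=DefaultAction.REMOVE_ORDER,
            override_options=both,
        ),
        DrugGeneRule(
            rule_id="CDS004",
            medication="codeine",
            gene="CYP2D6",
            phenotype_match="Ultrarapid Metabolizer",
            recommendation_text="Avoid codeine: risk of morphine toxicity in ultrarapid metabolizers.",
            default_action=DefaultAction.REMOVE_ORDER,
            override_options=both,
        ),
        DrugGeneRule(
            rule_id="CDS005",
            medication="warfarin",
            gene="CYP2C9",
            phenotype_match="Poor Metabolizer",
            recommendation_text="Reduce warfarin starting dose and increase INR monitoring frequency.",
            default_action=DefaultAction.KEEP_ORDER,
            override_options=(OverrideAction.DISMISS,),
        ),
    ]
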