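"""Raw-call translation, diplotype lookup and batch processing."""

import itertools

import pytest

from pgxbridge import (
    Call,
    RawCall,
    ResultStatus,
    apply_gene_symbol_replacements,
    call_diplotype,
    parse_instrument_export,
    process_batch,
    resolve_phenotype,
    simulate_plate,
    translate_raw_call,
)
from pgxbridge.engine import (
    AssayCall,
    ContractError,
    ExportFormatError,
    UnmappedDiplotypeError,
)
from pgxbridge.simulate import write_export_csv
from pgxbridge.tables import TranslatorTables


def rule_scan_oracle(gene, calls, tables):
    """Independent diplotype oracle: linear scan of the rule list comparing
    plain dicts (emulates reading the printed table row by row)."""
    if any(c.call is Call.NO_CALL for c in calls.values()):
        return ResultStatus.INCOMPLETE_NO_CALL, None
    wanted = {assay_id: c.call.value for assay_id, c in calls.items()}
    for rule in tables.genotype_rules:
        if rule.gene == gene and dict(rule.call_pattern) == wanted:
            return ResultStatus.RESULTED, rule.diplotype
    return ResultStatus.UNMAPPED_COMBINATION, None


class TestParseExport:
    def test_one_rawcall_per_row(self, tmp_path, toy_config):
        export, _ = simulate_plate(toy_config)
        path = tmp_path / "plate.csv"
        write_export_csv(export, path)
        parsed = parse_instrument_export(path)
        assert len(parsed.calls) == len(export.calls)
        assert parsed.source_files == ["plate.csv"]

    def test_undetermined_preserved_verbatim(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("sample,assay_id,call\nS-1,A1,Undetermined\n")
        parsed = parse_instrument_export(path)
        assert parsed.calls == [RawCall("S-1", "A1", "Undetermined")]

    def test_missing_call_column_is_format_error(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("sample,assay_id\nS-1,A1\n")
        with pytest.raises(ExportFormatError, match="call"):
            parse_instrument_export(path)

    def test_duplicate_sample_assay_pair_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("sample,assay_id,call\nS-1,A1,A/A\nS-1,A1,A/G\n")
        with pytest.raises(ExportFormatError, match="row 3"):
            parse_instrument_export(path)

    def test_blank_sample_rejected(self, tmp_path):
        path = tmp_path / "e.csv"
        path.write_text("sample,assay_id,call\n ,A1,A/A\n")
        with pytest.raises(ExportFormatError, match="blank"):
            parse_instrument_export(path)


class TestTranslateRawCall:
    @pytest.mark.parametrize(
        "raw_value,expected",
        [
            ("ref", Call.NORMAL),
            ("het", Call.HETEROZYGOUS),
            ("var", Call.MUTANT),
            ("Undetermined", Call.NO_CALL),
            ("", Call.NO_CALL),
            ("G/A", Call.NO_CALL),  # unexpected nucleotide order falls through
        ],
    )
    def test_table_match_and_fallback(self, toy_tables, raw_value, expected):
        probe = toy_tables.probes[0]
        value = {"ref": probe.ref_call, "het": probe.het_call, "var": probe.var_call}.get(
            raw_value, raw_value
        )
        out = translate_raw_call(RawCall("S-1", probe.assay_id, value), probe)
        assert out.call is expected
        assert out.gene == probe.gene

    def test_assay_mismatch_is_contract_error(self, toy_tables):
        probe = toy_tables.probes[0]
        with pytest.raises(ContractError):
            translate_raw_call(RawCall("S-1", "OTHER", "A/A"), probe)


@pytest.mark.parametrize(
    "symbol,mapping,expected",
    [
        ("CYP2C19", {}, "CYP2C19"),
        ("2D6", {"2D6": "CYP2D6"}, "CYP2D6"),
        ("", {}, ""),
    ],
)
def test_gene_symbol_replacements(symbol, mapping, expected):
    assert apply_gene_symbol_replacements(symbol, mapping) == expected


def _calls(tables, gene, states):
    assays = [p.assay_id for p in tables.probes_for_gene(gene)]
    return {a: AssayCall("S-1", gene, a, s) for a, s in zip(assays, states)}


class TestCallDiplotype:
    def test_all_normal_is_reference_diplotype(self, toy_tables):
        calls = _calls(toy_tables, "CYP2C19", [Call.NORMAL, Call.NORMAL])
        assert call_diplotype("S-1", "CYP2C19", calls, toy_tables) == (ResultStatus.RESULTED, "*1/*1")

    def test_single_het_matches_oracle(self, toy_tables):
        """The *2-defining assay heterozygous, others normal → *1/*2,
        cross-checked against the independent rule-scanning oracle."""
        calls = _calls(toy_tables, "CYP2C19", [Call.HETEROZYGOUS, Call.NORMAL])
        got = call_diplotype("S-1", "CYP2C19", calls, toy_tables)
        assert got == rule_scan_oracle("CYP2C19", calls, toy_tables)
        assert got == (ResultStatus.RESULTED, "*1/*2")

    def test_nocall_blocks_gene(self, toy_tables):
        calls = _calls(toy_tables, "CYP2C19", [Call.NO_CALL, Call.NORMAL])
        assert call_diplotype("S-1", "CYP2C19", calls, toy_tables) == (
            ResultStatus.INCOMPLETE_NO_CALL,
            None,
        )

    def test_pattern_absent_from_table_is_unmapped(self, toy_tables):
        pruned = TranslatorTables(
            probes=toy_tables.probes,
            genotype_rules=[
                r
                for r in toy_tables.genotype_rules
                if not (r.gene == "CYP2C19" and r.diplotype == "*2/*2")
            ],
            phenotypes=toy_tables.phenotypes,
            panel_genes=list(toy_tables.panel_genes),
        )
        calls = _calls(pruned, "CYP2C19", [Call.MUTANT, Call.NORMAL])
        assert call_diplotype("S-1", "CYP2C19", calls, pruned) == (
            ResultStatus.UNMAPPED_COMBINATION,
            None,
        )

    def test_missing_assay_is_contract_error(self, toy_tables):
        with pytest.raises(ContractError, match="missing assay"):
            call_diplotype("S-1", "CYP2C19", {}, toy_tables)

    def test_exhaustive_oracle_equivalence(self, toy_tables):
        """Every 4^k call combination per gene agrees with the independent
        rule-scanning oracle on both status and diplotype."""
        states = [Call.NORMAL, Call.HETEROZYGOUS, Call.MUTANT, Call.NO_CALL]
        for gene in toy_tables.panel_genes:
            k = len(toy_tables.probes_for_gene(gene))
            for combo in itertools.product(states, repeat=k):
                calls = _calls(toy_tables, gene, list(combo))
                assert call_diplotype("S-1", gene, calls, toy_tables) == rule_scan_oracle(
                    gene, calls, toy_tables
                ), (gene, combo)


class TestResolvePhenotype:
    def test_intermediate_metabolizer_flags_abnormal(self, toy_tables):
        rec = resolve_phenotype("CYP2C19", "*1/*2", toy_tables)
        assert rec.phenotype == "Intermediate Metabolizer"
        assert rec.abnormal is True

    def test_homozygous_variant_is_poor_metabolizer(self, toy_tables):
        assert resolve_phenotype("CYP2C19", "*2/*2", toy_tables).phenotype == "Poor Metabolizer"

    def test_activity_score_present_for_scored_gene(self, toy_tables):
        assert resolve_phenotype("CYP2D6", "*1/*1", toy_tables).activity_score == 2.0

    def test_unmapped_diplotype_raises(self, toy_tables):
        with pytest.raises(UnmappedDiplotypeError):
            resolve_phenotype("CYP2C19", "*99/*99", toy_tables)


class TestProcessBatch:
    def test_full_plate_recovers_simulator_truth(self, toy_config, toy_tables):
        export, truth = simulate_plate(toy_config)
        results = process_batch(export, toy_tables)
        assert len(results) == toy_config.n_samples * len(toy_tables.panel_genes)
        assert all(r.resulted for r in results)
        for r in results:
            assert r.diplotype == truth.diplotype(r.sample_id, r.gene)
            assert r.phenotype == truth.phenotype(r.sample_id, r.gene)

    def test_nocall_isolated_to_one_gene(self, toy_config, toy_tables):
        export, _ = simulate_plate(toy_config)
        victim = export.calls[0]  # first assay of sample 1's CYP2C19
        export.calls[0] = RawCall(victim.sample_id, victim.assay_id, "Undetermined")
        results = process_batch(export, toy_tables)
        by_key = {(r.sample_id, r.gene): r for r in results}
        assert by_key[(victim.sample_id, "CYP2C19")].status is ResultStatus.INCOMPLETE_NO_CALL
        assert by_key[(victim.sample_id, "CYP2D6")].resulted
        others = [r for r in results if r.sample_id != victim.sample_id]
        assert all(r.resulted for r in others)

    def test_abnormal_flag_copied_from_table(self, toy_config, toy_tables):
        export, _ = simulate_plate(toy_config)
        index = toy_tables.phenotype_index()
        for r in process_batch(export, toy_tables):
            assert r.abnormal == index[(r.gene, r.diplotype)].abnormal

    def test_deterministic_result_order(self, toy_config, toy_tables):
        export, _ = simulate_plate(toy_config)
        assert process_batch(export, toy_tables) == process_batch(export, toy_tables)
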