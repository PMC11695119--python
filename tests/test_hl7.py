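"""HL7 message model: parse/serialize round trips, order matching and the
LRR/VAR observation builders."""

import pytest
from hypothesis import given, strategies as st

from pgxbridge import (
    MessageMode,
    assemble_result_message,
    extract_order_context,
    match_order,
    parse_hl7,
    process_batch,
    simulate_order_feed,
    simulate_plate,
)
from pgxbridge.engine import ContractError, SampleGeneResult
from pgxbridge.hl7 import (
    HL7FormatError,
    MappingError,
    MatchError,
    build_lrr_obx_set,
    build_var_obx_set,
    default_mapping,
    distinct_obx3_codes,
    escape_text,
    obx_set_ids,
    unescape_text,
)


def make_result(gene="CYP2C19", score=None, abnormal=True, comment="note", sample="S-0001"):
    return SampleGeneResult(
        sample_id=sample,
        gene=gene,
        diplotype="*1/*2",
        phenotype="Intermediate Metabolizer",
        activity_score=score,
        comment=comment,
        abnormal=abnormal,
        var_display="Intermediate Metabolizer",
        lrr_display="Intermediate Metabolizer",
    )


class TestParseSerialize:
    def test_order_messages_round_trip(self, toy_config):
        export, _ = simulate_plate(toy_config)
        for msg in simulate_order_feed(export):
            text = msg.serialize()
            assert parse_hl7(text).serialize() == text
            assert parse_hl7(text) == msg

    def test_field_addressing(self):
        msg = parse_hl7("MSH|^~\\&|APP\rOBX|1|ST|CODE\r")
        obx = msg.segments_of("OBX")[0]
        assert obx.segment_type == "OBX"
        assert obx.get(1) == "1"
        assert obx.get(3) == "CODE"
        assert msg.segments[0].get(1) == "|"
        assert msg.segments[0].get(2) == "^~\\&"

    def test_first_segment_must_be_msh(self):
        with pytest.raises(HL7FormatError, match="MSH"):
            parse_hl7("PID|1||P1\r")

    def test_empty_input_is_format_error(self):
        with pytest.raises(HL7FormatError):
            parse_hl7("")

    @given(st.text(min_size=0, max_size=60))
    def test_escape_unescape_round_trips_any_text(self, value):
        escaped = escape_text(value)
        for delim in "|^&~":
            assert delim not in escaped
        assert unescape_text(escaped) == value


class TestOrderContext:
    def test_planted_values_extracted(self, toy_config):
        export, _ = simulate_plate(toy_config)
        contexts = [extract_order_context(m) for m in simulate_order_feed(export)]
        assert contexts[0].patient_id == "P0001"
        assert contexts[0].specimen_id == "S-0001"
        assert contexts[0].test_code == "GATORPGX"
        assert len({c.specimen_id for c in contexts}) == len(contexts)

    def test_missing_obr_is_format_error(self, toy_config):
        export, _ = simulate_plate(toy_config)
        msg = simulate_order_feed(export)[0]
        msg.segments = [s for s in msg.segments if s.segment_type != "OBR"]
        with pytest.raises(HL7FormatError, match="OBR"):
            extract_order_context(msg)

    def test_match_order_unique_unmatched_ambiguous(self, toy_config):
        export, _ = simulate_plate(toy_config)
        orders = [extract_order_context(m) for m in simulate_order_feed(export)]
        assert match_order("S-0001", orders).specimen_id == "S-0001"
        with pytest.raises(MatchError, match="unmatched"):
            match_order("S-9999", orders)
        with pytest.raises(MatchError, match="ambiguous"):
            match_order("S-0001", orders + [orders[0]])


class TestObxBuilders:
    def test_lrr_component_count_follows_activity_score(self, toy_mapping):
        with_score = build_lrr_obx_set(make_result(gene="CYP2D6", score=1.5), toy_mapping)
        without = build_lrr_obx_set(make_result(gene="CYP2D6"), toy_mapping)
        assert sum(len(b.obx_segments) for b in with_score) == 3
        assert sum(len(b.obx_segments) for b in without) == 2

    def test_set_ids_sequential_from_start(self, toy_mapping):
        blocks = build_lrr_obx_set(make_result(gene="CYP2D6", score=1.5), toy_mapping, start_set_id=4)
        assert [b.obx_segments[0].get(1) for b in blocks] == ["4", "5", "6"]

    def test_abnormal_flag_passthrough(self, toy_mapping):
        flagged = build_lrr_obx_set(make_result(abnormal=True), toy_mapping)
        clean = build_lrr_obx_set(make_result(abnormal=False), toy_mapping)
        assert {b.obx_segments[0].get(7) for b in flagged} == {"A"}
        assert {b.obx_segments[0].get(7) for b in clean} == {""}

    def test_comment_becomes_nte_after_phenotype_obx(self, toy_mapping):
        blocks = build_lrr_obx_set(make_result(comment="lab comment"), toy_mapping)
        pheno = [b for b in blocks if b.component_kind.value == "Phenotype"][0]
        assert len(pheno.nte_segments) == 1
        assert pheno.nte_segments[0].get(3) == "lab comment"
        geno = [b for b in blocks if b.component_kind.value == "Genotype"][0]
        assert geno.nte_segments == []

    def test_var_codes_shared_across_genes_but_sub_ids_differ(self, toy_mapping):
        c19 = build_var_obx_set(make_result(gene="CYP2C19"), toy_mapping)
        d6 = build_var_obx_set(make_result(gene="CYP2D6"), toy_mapping)
        assert c19[0].obx_segments[0].get(3) == d6[0].obx_segments[0].get(3)
        assert c19[0].obx_segments[0].get(4) != d6[0].obx_segments[0].get(4)

    def test_missing_lrr_code_is_mapping_error(self, toy_mapping):
        with pytest.raises(MappingError, match="GENEX"):
            build_lrr_obx_set(make_result(gene="GENEX"), toy_mapping)

    def test_nonresulted_rejected(self, toy_mapping):
        from pgxbridge import ResultStatus

        bad = SampleGeneResult("S-1", "CYP2C19", status=ResultStatus.INCOMPLETE_NO_CALL)
        with pytest.raises(ContractError):
            build_lrr_obx_set(bad, toy_mapping)

    def test_pipe_in_value_escaped_and_round_trips(self, toy_mapping, toy_config, fixed_clock):
        result = make_result(comment="flag | check ^ this & that")
        export, _ = simulate_plate(toy_config)
        order = extract_order_context(simulate_order_feed(export)[0])
        msg = assemble_result_message(order, [result], toy_mapping, MessageMode.LRR_ONLY, clock=fixed_clock)
        text = msg.serialize()
        reparsed = parse_hl7(text)
        assert reparsed.serialize() == text
        ntes = reparsed.segments_of("NTE")
        assert unescape_text(ntes[0].get(3)) == "flag | check ^ this & that"


class TestAssemble:
    @pytest.fixture()
    def eight_gene_setup(self, fixed_clock):
        from pgxbridge import default_config, generate_toy_panel_tables

        config = default_config(n_genes=8, n_samples=2, seed=11)
        tables = generate_toy_panel_tables(config)
        export, _ = simulate_plate(config)
        results = process_batch(export, tables)
        orders = [extract_order_context(m) for m in simulate_order_feed(export)]
        mapping = default_mapping(tables.panel_genes)
        return config, results, orders, mapping

    @staticmethod
    def expected_obx_count(results, mode):
        """Independent tally: per result 2 components + 1 if an activity
        score is present, doubled in dual mode."""
        per_result = sum(2 + (r.activity_score is not None) for r in results)
        return per_result * (2 if mode is MessageMode.DUAL else 1)

    @pytest.mark.parametrize("mode", list(MessageMode))
    def test_obx_count_matches_independent_tally(self, eight_gene_setup, mode, fixed_clock):
        _, results, orders, mapping = eight_gene_setup
        sample = [r for r in results if r.sample_id == "S-0001"]
        msg = assemble_result_message(match_order("S-0001", orders), sample, mapping, mode, clock=fixed_clock)
        assert len(msg.segments_of("OBX")) == self.expected_obx_count(sample, mode)
        assert obx_set_ids(msg) == list(range(1, len(msg.segments_of("OBX")) + 1))

    def test_dual_mode_eight_gene_panel_has_36_obx(self, eight_gene_setup, fixed_clock):
        """Eight genes with genotype+phenotype each and two activity-score
        genes give 2 x (8 x 2 + 2) = 36 OBX segments in dual mode."""
        _, results, orders, mapping = eight_gene_setup
        sample = [r for r in results if r.sample_id == "S-0001"]
        assert sum(1 for r in sample if r.activity_score is not None) == 2
        msg = assemble_result_message(match_order("S-0001", orders), sample, mapping, MessageMode.DUAL, clock=fixed_clock)
        assert len(msg.segments_of("OBX")) == 36

    def test_var_only_code_count_independent_of_gene_count(self, eight_gene_setup, fixed_clock):
        _, results, orders, mapping = eight_gene_setup
        sample = [r for r in results if r.sample_id == "S-0001"]
        msg = assemble_result_message(match_order("S-0001", orders), sample, mapping, MessageMode.VAR_ONLY, clock=fixed_clock)
        assert len(distinct_obx3_codes(msg)) <= 3

    def test_segment_order_and_round_trip(self, eight_gene_setup, fixed_clock):
        _, results, orders, mapping = eight_gene_setup
        sample = [r for r in results if r.sample_id == "S-0001"]
        msg = assemble_result_message(match_order("S-0001", orders), sample, mapping, MessageMode.DUAL, clock=fixed_clock)
        types = [s.segment_type for s in msg.segments]
        assert types[:4] == ["MSH", "PID", "ORC", "OBR"]
        assert set(types[4:]) <= {"OBX", "NTE"}
        for i, t in enumerate(types):
            if t == "NTE":
                assert types[i - 1] in ("OBX", "NTE")
        assert parse_hl7(msg.serialize()) == msg

    def test_empty_or_mixed_results_rejected(self, eight_gene_setup, fixed_clock):
        _, results, orders, mapping = eight_gene_setup
        order = match_order("S-0001", orders)
        with pytest.raises(ContractError):
            assemble_result_message(order, [], mapping, clock=fixed_clock)
        mixed = [r for r in results if r.sample_id in ("S-0001", "S-0002")]
        with pytest.raises(ContractError, match="mixed"):
            assemble_result_message(order, mixed, mapping, clock=fixed_clock)


def test_lrr_var_code_scaling_across_panels(fixed_clock):
    """The discrete-record (LRR) code book grows with genes x components
    while the variant-style (VAR) code book stays at <= 3 codes."""
    from pgxbridge import default_config, generate_toy_panel_tables

    lrr_counts = []
    for n_genes in (2, 4, 8):
        config = default_config(n_genes=n_genes, n_samples=1, seed=5)
        tables = generate_toy_panel_tables(config)
        export, _ = simulate_plate(config)
        results = process_batch(export, tables)
        order = extract_order_context(simulate_order_feed(export)[0])
        mapping = default_mapping(tables.panel_genes)
        lrr = assemble_result_message(order, results, mapping, MessageMode.LRR_ONLY, clock=fixed_clock)
        var = assemble_result_message(order, results, mapping, MessageMode.VAR_ONLY, clock=fixed_clock)
        expected = sum(2 + (r.activity_score is not None) for r in results)
        assert len(distinct_obx3_codes(lrr)) == expected
        assert len(distinct_obx3_codes(var)) <= 3
        lrr_counts.append(len(distinct_obx3_codes(lrr)))
    assert lrr_counts == sorted(lrr_counts) and lrr_counts[0] < lrr_counts[-1]
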