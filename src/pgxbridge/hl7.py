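"""Pipe-delimited HL7 v2 messaging: parse orders, match results, build ORU-style
result messages carrying both LRR and VAR observation sets.

The dialect is HL7 v2.5.1-shaped: segments terminated by carriage return,
fields separated by ``|``, encoding characters ``^~\\&`` declared in MSH-2,
and the standard escape sequences (``\\F\\ \\S\\ \\T\\ \\R\\ \\E\\``) for
delimiter characters inside values. Messages this package emits use only the
MSH, PID, ORC, OBR, OBX and NTE segments, and ``parse`` / ``serialize`` are
exact inverses on that dialect.

Two observation record styles coexist in one result message:

* **LRR** (Long Read Report, Epic's discrete clinical-pathology storage):
  the OBX-3 observation identifier is specific to each gene × component
  (e.g. a dedicated code for the CYP2D6 genotype), so the code count grows
  linearly with the panel;
* **VAR** (Epic's variant database): a single OBX-3 code per component kind
  is reused across genes, with the gene carried in the OBX-4 sub-ID — no new
  record is needed per gene/result combination.

Both are built from the same phenotype-table content; the abnormal flag
(OBX-7) and observation values (OBX-5) come straight from that table.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from datetime import datetime
from typing import Callable, Iterable, Sequence

from .engine import ContractError, SampleGeneResult

SEGMENT_SEP = "\r"
FIELD_SEP = "|"
ENCODING_CHARS = "^~\\&"

#: Where each order-context field lives in the ancillary order message.
#: Segment, field index (1-based), component index (1-based; 0 keeps the
#: whole field verbatim, encoding intact — used for structured names).
FIELD_MAP = {
    "patient_id": ("PID", 3, 1),
    "patient_name": ("PID", 5, 0),
    "placer_order_number": ("ORC", 2, 1),
    "filler_order_number": ("ORC", 3, 1),
    "specimen_id": ("OBR", 3, 1),
    "test_code": ("OBR", 4, 1),
    "order_timestamp": ("OBR", 6, 1),
}


class HL7FormatError(ValueError):
    """Raw text does not parse as a message of this dialect."""


class MatchError(LookupError):
    """A result could not be paired with exactly one ancillary order."""


class MappingError(KeyError):
    """The observation-code mapping lacks an entry a result needs."""


class ComponentKind(str, enum.Enum):
    GENOTYPE = "Genotype"
    PHENOTYPE = "Phenotype"
    ACTIVITY_SCORE = "ActivityScore"


class RecordStyle(str, enum.Enum):
    LRR = "LRR"
    VAR = "VAR"


class MessageMode(str, enum.Enum):
    LRR_ONLY = "LRR_only"
    VAR_ONLY = "VAR_only"
    DUAL = "dual"


def escape_text(value: str) -> str:
    """Escape HL7 delimiter characters for use inside one field."""
    return (
        value.replace("\\", "\\E\\")
        .replace("|", "\\F\\")
        .replace("^", "\\S\\")
        .replace("&", "\\T\\")
        .replace("~", "\\R\\")
    )


def unescape_text(value: str) -> str:
    out: list[str] = []
    i = 0
    repl = {"F": "|", "S": "^", "T": "&", "R": "~", "E": "\\"}
    while i < len(value):
        ch = value[i]
        if ch == "\\" and i + 2 < len(value) and value[i + 2] == "\\" and value[i + 1] in repl:
            out.append(repl[value[i + 1]])
            i += 3
        else:
            out.append(ch)
            i += 1
    return "".join(out)


@dataclass
class Segment:
    """One HL7 segment: a 3-letter type and its pipe-delimited fields.

    Fields are addressed 1-based, HL7-style. For MSH, field 1 is the field
    separator character itself and field 2 the encoding characters.
    """

    segment_type: str
    fields: list[str] = field(default_factory=list)

    def get(self, index: int) -> str:
        if self.segment_type == "MSH":
            if index == 1:
                return FIELD_SEP
            index -= 1
        return self.fields[index - 1] if 0 < index <= len(self.fields) else ""

    def set(self, index: int, value: str) -> None:
        if self.segment_type == "MSH":
            if index == 1:
                raise ContractError("MSH-1 is the field separator itself")
            index -= 1
        while len(self.fields) < index:
            self.fields.append("")
        self.fields[index - 1] = value

    def component(self, index: int, comp: int) -> str:
        parts = self.get(index).split("^")
        return parts[comp - 1] if 0 < comp <= len(parts) else ""

    def serialize(self) -> str:
        return self.segment_type + FIELD_SEP + FIELD_SEP.join(self.fields)


@dataclass
class HL7Message:
    segments: list[Segment]

    def serialize(self) -> str:
        return SEGMENT_SEP.join(s.serialize() for s in self.segments) + SEGMENT_SEP

    def segments_of(self, segment_type: str) -> list[Segment]:
        return [s for s in self.segments if s.segment_type == segment_type]

    def first(self, segment_type: str) -> Segment | None:
        for s in self.segments:
            if s.segment_type == segment_type:
                return s
        return None


def parse_hl7(text: str) -> HL7Message:
    """Parse pipe-delimited message text; the first segment must be MSH."""
    if not text or not text.strip():
        raise HL7FormatError("empty message")
    lines = [ln for ln in text.replace("\r\n", "\r").replace("\n", "\r").split("\r") if ln]
    segments: list[Segment] = []
    for ln in lines:
        if len(ln) < 4 or ln[3] != FIELD_SEP:
            raise HL7FormatError(f"malformed segment: {ln[:20]!r}")
        segments.append(Segment(segment_type=ln[:3], fields=ln[4:].split(FIELD_SEP)))
    if segments[0].segment_type != "MSH":
        raise HL7FormatError(f"first segment must be MSH, got {segments[0].segment_type}")
    return HL7Message(segments=segments)


@dataclass(frozen=True)
class OrderContext:
    """Patient and order identifiers lifted from one ancillary order message."""

    patient_id: str
    patient_name: str
    placer_order_number: str
    filler_order_number: str
    specimen_id: str
    test_code: str
    order_timestamp: str


def extract_order_context(order: HL7Message) -> OrderContext:
    """Pull the context fields from PID/ORC/OBR at the FIELD_MAP positions."""
    for required in ("PID", "ORC", "OBR"):
        if order.first(required) is None:
            raise HL7FormatError(f"missing {required} segment in order message")
    values: dict[str, str] = {}
    for name, (seg_type, idx, comp) in FIELD_MAP.items():
        seg = order.first(seg_type)
        assert seg is not None
        values[name] = seg.get(idx) if comp == 0 else unescape_text(seg.component(idx, comp))
    ctx = OrderContext(**values)
    if not ctx.filler_order_number or not ctx.specimen_id:
        raise HL7FormatError("order lacks filler order number or specimen id")
    return ctx


def match_order(
    sample_id: str,
    orders: Iterable[OrderContext],
    key: str = "specimen_id",
) -> OrderContext:
    """Find the unique ancillary order whose key field equals the sample id.

    Results that cannot be matched must be quarantined, never dropped — both
    zero and multiple matches raise.
    """
    hits = [o for o in orders if getattr(o, key) == sample_id]
    if not hits:
        raise MatchError(f"unmatched result: no order with {key}='{sample_id}'")
    if len(hits) > 1:
        raise MatchError(f"ambiguous order: {len(hits)} orders with {key}='{sample_id}'")
    return hits[0]


@dataclass
class ObservationMapping:
    """OBX-3 code books for the two record styles plus per-gene sub-IDs.

    ``lrr_codes`` needs one entry per gene × component in the panel;
    ``var_codes`` has exactly one entry per component kind, panel-wide.
    """

    lrr_codes: dict[tuple[str, ComponentKind], str]
    var_codes: dict[ComponentKind, str]
    sub_id_by_gene: dict[str, str]


@dataclass
class ObservationBlock:
    obx_segments: list[Segment]
    nte_segments: list[Segment]
    gene: str
    component_kind: ComponentKind
    record_style: RecordStyle

    def serialize_segments(self) -> list[Segment]:
        return list(self.obx_segments) + list(self.nte_segments)


def _components_for(result: SampleGeneResult) -> list[tuple[ComponentKind, str]]:
    comps = [(ComponentKind.GENOTYPE, result.diplotype or "")]
    comps.append((ComponentKind.PHENOTYPE, result.phenotype or ""))
    if result.activity_score is not None:
        comps.append((ComponentKind.ACTIVITY_SCORE, f"{result.activity_score:g}"))
    return comps


def _build_obx_set(
    result: SampleGeneResult,
    mapping: ObservationMapping,
    start_set_id: int,
    style: RecordStyle,
    timestamp: str = "",
) -> list[ObservationBlock]:
    if not result.resulted:
        raise ContractError(f"cannot build OBX set for non-Resulted result ({result.sample_id}, {result.gene})")
    gene = result.gene
    sub_id = mapping.sub_id_by_gene.get(gene, "")
    blocks: list[ObservationBlock] = []
    set_id = start_set_id
    for kind, value in _components_for(result):
        if style is RecordStyle.LRR:
            code = mapping.lrr_codes.get((gene, kind))
            if code is None:
                raise MappingError(f"no LRR code for ({gene}, {kind.value})")
            if kind is ComponentKind.PHENOTYPE and result.lrr_display:
                value = result.lrr_display
        else:
            code = mapping.var_codes.get(kind)
            if code is None:
                raise MappingError(f"no VAR code for {kind.value}")
            if kind is ComponentKind.PHENOTYPE and result.var_display:
                value = result.var_display
        obx = Segment("OBX")
        obx.set(1, str(set_id))
        obx.set(2, "ST")
        obx.set(3, escape_text(code))
        obx.set(4, escape_text(sub_id))
        obx.set(5, escape_text(value))
        obx.set(7, "A" if result.abnormal else "")
        obx.set(11, "F")
        if timestamp:
            obx.set(14, timestamp)
        ntes: list[Segment] = []
        if kind is ComponentKind.PHENOTYPE and result.comment:
            nte = Segment("NTE")
            nte.set(1, "1")
            nte.set(3, escape_text(result.comment))
            ntes.append(nte)
        blocks.append(
            ObservationBlock(
                obx_segments=[obx], nte_segments=ntes, gene=gene, component_kind=kind, record_style=style
            )
        )
        set_id += 1
    return blocks


def build_lrr_obx_set(
    result: SampleGeneResult,
    mapping: ObservationMapping,
    start_set_id: int = 1,
    timestamp: str = "",
) -> list[ObservationBlock]:
    """Gene-specific discrete records: one OBX per available component
    (genotype, phenotype, activity score when present), codes from
    ``lrr_codes[(gene, component)]``, lab comment as an NTE after the
    phenotype OBX."""
    return _build_obx_set(result, mapping, start_set_id, RecordStyle.LRR, timestamp)


def build_var_obx_set(
    result: SampleGeneResult,
    mapping: ObservationMapping,
    start_set_id: int = 1,
    timestamp: str = "",
) -> list[ObservationBlock]:
    """Variant-database records: same component set as LRR but one shared
    OBX-3 code per component kind; the gene identity rides in OBX-4."""
    return _build_obx_set(result, mapping, start_set_id, RecordStyle.VAR, timestamp)


def format_hl7_timestamp(dt: datetime) -> str:
    return dt.strftime("%Y%m%d%H%M%S")


def assemble_result_message(
    order: OrderContext,
    results: Sequence[SampleGeneResult],
    mapping: ObservationMapping,
    mode: MessageMode = MessageMode.DUAL,
    clock: Callable[[], datetime] | None = None,
    control_id: str = "1",
    sending_app: str = "PGXBRIDGE",
    receiving_app: str = "EHR",
) -> HL7Message:
    """Build the complete result message for one matched ancillary order.

    Segment order is MSH, PID, ORC, OBR, then per gene the LRR and/or VAR
    observation blocks (per ``mode``); OBX-1 set IDs are renumbered 1..N
    across the whole message so every OBX is uniquely identified.
    """
    if not results:
        raise ContractError("assemble_result_message requires at least one result")
    sample_ids = {r.sample_id for r in results}
    if len(sample_ids) != 1:
        raise ContractError(f"mixed sample_ids in one message: {sorted(sample_ids)}")
    if any(not r.resulted for r in results):
        raise ContractError("all results in a message must have status Resulted")

    now = clock() if clock is not None else datetime.now()
    ts = format_hl7_timestamp(now)

    msh = Segment("MSH")
    msh.set(2, ENCODING_CHARS)
    msh.set(3, sending_app)
    msh.set(5, receiving_app)
    msh.set(7, ts)
    msh.set(9, "ORU^R01")
    msh.set(10, control_id)
    msh.set(11, "P")
    msh.set(12, "2.5.1")

    pid = Segment("PID")
    pid.set(1, "1")
    pid.set(3, escape_text(order.patient_id))
    pid.set(5, order.patient_name)  # whole PID-5 field, already HL7-encoded

    orc = Segment("ORC")
    orc.set(1, "RE")
    orc.set(2, escape_text(order.placer_order_number))
    orc.set(3, escape_text(order.filler_order_number))

    obr = Segment("OBR")
    obr.set(1, "1")
    obr.set(2, escape_text(order.placer_order_number))
    obr.set(3, escape_text(order.specimen_id))
    obr.set(4, escape_text(order.test_code))
    obr.set(6, order.order_timestamp)
    obr.set(7, ts)

    blocks: list[ObservationBlock] = []
    for result in results:
        if mode in (MessageMode.LRR_ONLY, MessageMode.DUAL):
            blocks.extend(build_lrr_obx_set(result, mapping, 1, timestamp=ts))
        if mode in (MessageMode.VAR_ONLY, MessageMode.DUAL):
            blocks.extend(build_var_obx_set(result, mapping, 1, timestamp=ts))

    segments = [msh, pid, orc, obr]
    set_id = 1
    for block in blocks:
        for obx in block.obx_segments:
            obx.set(1, str(set_id))
            set_id += 1
            segments.append(obx)
        segments.extend(block.nte_segments)
    return HL7Message(segments=segments)


def obx_set_ids(message: HL7Message) -> list[int]:
    return [int(s.get(1)) for s in message.segments_of("OBX")]


def distinct_obx3_codes(message: HL7Message) -> set[str]:
    return {s.get(3) for s in message.segments_of("OBX")}


def default_mapping(panel_genes: Sequence[str], activity_genes: Sequence[str] = ()) -> ObservationMapping:
    """Deterministic local code book for a panel (codes are configuration in
    production; these synthetic codes follow an EAP/LRR-style numbering)."""
    lrr_codes: dict[tuple[str, ComponentKind], str] = {}
    sub_ids: dict[str, str] = {}
    for gi, gene in enumerate(panel_genes):
        sub_ids[gene] = f"EAP{1000 + gi}"
        for ci, kind in enumerate(ComponentKind):
            lrr_codes[(gene, kind)] = f"LRR{2000 + gi * 10 + ci}"
    var_codes = {kind: f"VAR{300 + ci}" for ci, kind in enumerate(ComponentKind)}
    return ObservationMapping(lrr_codes=lrr_codes, var_codes=var_codes, sub_id_by_gene=sub_ids)
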