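# Methods

## Translation model

The interpretation pipeline is deliberately *table-total*: every decision
from raw instrument string to reportable result is an exact lookup in one
of three operator-maintained CSV tables, so the clinical content lives in
reviewable data, not code.

* **Probe table** (`assay_id, gene, marker_id, ref_call, het_call,
  var_call, notes`). Each TaqMan assay interrogates one variant site; the
  three call strings are the literal instrument outputs for homozygous
  reference, heterozygous and homozygous variant (nucleotide order
  included — "G/A" and "A/G" are different strings, and an export that
  reports the unexpected order simply falls through to NoCall rather than
  being reinterpreted).
* **Genotype table** (`gene, <one column per assay_id>, diplotype`). Wide
  format: each row is one fully enumerated combination of per-assay calls
  (Normal / Heterozygous / Mutant) and the star-allele diplotype it
  translates to. Because combinations are enumerated exhaustively there is
  no phasing inference and no wildcard matching; a combination missing
  from the table yields status `UnmappedCombination`.
* **Phenotype table** (`gene, diplotype, phenotype, activity_score,
  comment, abnormal, var_display, lrr_display`). One record per (gene,
  diplotype). Phenotype wording is unconstrained text so metabolizer genes
  (Ultrarapid / Normal / Intermediate / Poor Metabolizer), transporter
  genes (function wording) and sensitivity genes can coexist on one panel.
  The abnormal flag is *copied* into results and HL7 OBX-7, never
  computed.

`validate_tables` checks all intra- and cross-table invariants (unique
assays, distinct call strings, rules referencing known assays of the same
gene, unique patterns, every reachable diplotype having exactly one
phenotype record) and returns an ordered findings list; the batch pipeline
refuses to start on any error finding.

A fourth call state, **NoCall**, covers "Undetermined", empty cells and any
unrecognised raw value. Any NoCall within a gene blocks that gene's result
(`IncompleteNoCall`): questionable data is routed to human review, never
guessed. Failure is isolated per gene — one blocked gene never suppresses a
sample's other results. `apply_gene_symbol_replacements` normalises
assay-side gene labels (e.g. "2D6" → "CYP2D6") before lookup and is total.

## HL7 dialect

Messages are HL7 v2.5.1-shaped pipe-delimited text: carriage-return
segment terminators, `|` field separator, `^~\&` encoding characters, and
the standard escape sequences (`\F\ \S\ \T\ \R\ \E\`) for delimiters
inside values. Only MSH, PID, ORC, OBR, OBX and NTE segments are emitted,
and `parse`/`serialize` are exact inverses on this dialect (property-tested
on arbitrary text for the escaping layer and on all simulator-generated
messages for whole messages). OBX fields not needed by the result model
(6, 8–10, 12–13) are left empty by decision. OBX-2 is always "ST": star
alleles and phenotype words are free text. OBX-1 set IDs are renumbered
1..N across each assembled message.

The "AIK8"/"AIK7" ancillary interface roles are treated as order-out /
result-in over ORM/ORU-like payloads. Order matching uses the specimen id
(OBR-3 of the order; the key field is an argument), and both zero and
multiple matches raise — unmatched results are quarantined with a reason,
never silently dropped. The positions of all order-context fields are
collected in the single `FIELD_MAP` configuration block in `pgxbridge.hl7`.

Observation codes (OBX-3) are configuration, not content:
`ObservationMapping` carries an LRR code per gene × component, a VAR code
per component kind, and an OBX-4 sub-ID per gene. `default_mapping`
fabricates a deterministic synthetic code book for simulated panels. The
testable consequence of the two storage styles is a scaling contrast: the
distinct-code count in LRR-only messages equals genes × components, while
in VAR-only messages it is ≤ 3 regardless of panel size.

Timestamps come from an injected clock (`YYYYMMDDHHMMSS`), and message
control IDs from a run-scoped counter, so whole pipeline runs are
byte-reproducible.

## Indicators and CDS

Indicator rules match `(gene, phenotype)` exactly after case- and
whitespace-normalisation; each match mints an indicator carrying provider
and patient interpretation text and a `sample:gene` reference to the
originating result. Indicators are minted for normal-function phenotypes
too, with `actionable=False` gating CDS. Drug–gene rules are single-gene
by design: a drug affected by two genes (e.g. a thiopurine with TPMT and
NUDT15) is expressed as two independent rules, and composite multi-gene
logic is a documented non-goal, as is phenoconversion. Activity-score
thresholds are likewise expressed through the table-resolved phenotype
text rather than numeric score conditions. The retroactive utility reuses
the same evaluation on legacy results and subtracts indicators already on
the chart, making re-runs no-ops; unmatched legacy phenotype text goes to
an exceptions report.

`alert_impact_summary` is exact integer arithmetic:
`round(100·(after−before)/before)` with half-away-from-zero rounding and a
positive-baseline precondition.

## Simulator

The generator emulates the inputs the pipeline would meet in production,
not population genetics:

* Each toy gene has `k` biallelic assays; assay `i` defines star allele
  `*(i+1)`. Assays are sampled independently under Hardy–Weinberg from
  per-assay variant allele frequencies (defaults 0.15 for the first assay
  of a gene, 0.08 thereafter — common-variant territory, chosen so a
  96-well plate reliably contains heterozygous and variant genotypes).
  There is **no linkage** between sites, which keeps truth assignment
  unambiguous but means combinations with more than two total variant
  copies are reachable; the enumerated genotype table resolves those by
  keeping the two highest-numbered alleles. This is a toy convention: a
  production table would route such combinations to manual review.
* The default panel mirrors an eight-gene pharmacogene panel (CYP2C19,
  CYP2D6, CYP2C9, CYP3A5, CYP4F2, the CYP2C cluster, SLCO1B1, VKORC1) at
  96 samples per plate. CYP2D6 and CYP2C9 carry allele activity values
  (\*1 = 1.0, \*2 = 0.5, \*3 = 0) with score-to-phenotype cut-points 0 →
  Poor, < 1.25 → Intermediate, ≤ 2.25 → Normal, > 2.25 → Ultrarapid —
  the activity-score framework used for these genes in clinical
  guidelines. Non-metabolizer genes use function/sensitivity wording.
* No-calls are injected per assay at rate `r` after truth is recorded, so
  the expected fraction of blocked gene results is 1−(1−r)^k per k-assay
  gene; the test suite checks this within three binomial standard errors
  over 20 seeded plates.
* Order feeds plant `specimen_id = sample_id` with deterministic synthetic
  demographics.

What passing tests on these inputs do **not** show: robustness to real
instrument-export quirks (encoding, extra metadata rows), real linkage
between star-allele-defining sites, CYP2D6 structural variation (copy
number is handled only insofar as a genotype-table row enumerates it), or
the behaviour of production EHR interfaces. The simulator validates the
*plumbing and the table contract*, not assay chemistry.

## Numerical and formatting choices

Activity scores are rendered with `%g` (2.0 → "2", 1.5 → "1.5") in CSV and
OBX-5 values. The review document's plain-text rendering is the canonical
artifact — column widths derived from content, byte-deterministic given
(results, export, clock) — and the PDF is a pagination of that text.
CSV headers are matched case-insensitively after trimming; unknown columns
are ignored rather than rejected, since institution-specific extension of
the tables is the expected mode of adaptation.

## Problem sizes

The default test and acceptance workloads use 96-sample plates (one
physical plate) on 2–8-gene panels, 1,000 messages for round-trip checks,
exhaustive call-combination enumeration up to 4 assays per gene (4⁴
combinations), and 20 seeded plates for no-call statistics. These sizes
exercise every code path at plate scale; nothing in the design caps larger
batches.

## Known limitations

* Diplotype calling is strictly enumerative — panels whose diplotypes
  cannot be enumerated per-combination (CYP2D6 hybrids, duplications with
  allele-specific copy number) need upstream resolution.
* Single-gene CDS rules only; no composite triggers, no dosing
  calculators, no phenoconversion adjustment.
* Transport is file-drop: no MLLP networking or acknowledgment handling.
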