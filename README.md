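# pgxbridge

Laboratory-to-EHR middleware for clinical pharmacogenomics (PGx). Hospital
laboratories that genotype pharmacogenes on TaqMan panels face a tedious
post-analytical step: raw instrument allele calls must be converted to
star-allele diplotypes and CPIC-style predicted phenotypes, filed as
discrete results in the electronic health record, and wired into
prescribing-time decision support. `pgxbridge` automates that path for the
laboratory informaticists and clinical pharmacists who run it.

## What it does

1. **Table-driven translation.** Three coupled CSV translator tables define
   the whole interpretation: a *probe table* (assay → gene and the raw call
   strings meaning homozygous reference / heterozygous / homozygous
   variant), a *genotype table* enumerating every per-gene assay-call
   combination and its star-allele diplotype *d* = \*x/\*y, and a
   *phenotype table* mapping each (gene, *d*) to phenotype, optional
   activity score (the sum of the two allele activity values, e.g.
   AS(\*1/\*4) = 1.0 + 0 = 1.0 for CYP2D6), lab comment and EHR abnormal
   flag. Calling is pure lookup — no phasing or inference — and any
   unrecognised raw value ("Undetermined", unexpected allele order) blocks
   the gene's result rather than guessing.
2. **HL7 v2 result messaging.** Results are matched to ancillary order
   messages by specimen id and packaged as pipe-delimited ORU-style
   messages (MSH/PID/ORC/OBR then OBX/NTE observation blocks). Each gene is
   emitted in one or both of two record styles: **LRR** (discrete storage,
   one OBX-3 observation code per gene × component) and **VAR**
   (variant-database storage, one code per component kind reused across
   genes, the gene carried in the OBX-4 sub-ID). Unmatched results are
   quarantined, never dropped.
3. **Review document.** A deterministic plain-text + PDF summary of every
   sample's calls with the generation date and raw export file names, for
   technologist sign-off.
4. **Indicators and CDS.** Resulted phenotypes map to genomic indicators
   (provider/patient interpretation text, link to the source result) which
   trigger drug–gene alerts at ordering — e.g. clopidogrel ordered for a
   CYP2C19 poor metabolizer defaults to removing the order, overridable by
   keeping it or dismissing the alert. A retroactive utility applies the
   same rules to legacy results idempotently, and
   `alert_impact_summary(before, after)` gives the percent change
   `round(100·(after−before)/before)` in alert volume.
5. **Simulator.** All inputs — tables, Hardy–Weinberg plate exports with
   known ground truth, order feeds — can be generated synthetically, so
   every stage is testable offline.

## Worked example

```bash
python examples/01_translate_plate.py
```

```
panel: ['CYP2C19', 'CYP2D6'], 4 assays, 18 genotype rules, validation findings: []
S-0001  CYP2C19   *1/*2    Intermediate Metabolizer  [abnormal]
S-0001  CYP2D6    *2/*3    Intermediate Metabolizer  AS=0.5  [abnormal]
S-0002  CYP2C19   *1/*1    Normal Metabolizer
...
recovered 192/192 diplotypes against simulator ground truth
```

Each line is one reportable gene result: sample, gene, star-allele
diplotype, the phenotype it translates to, the CYP2D6 activity score, and
whether the EHR will flag it abnormal. With no no-calls, all 96 × 2 results
match the simulator's ground truth. `examples/02_result_messages.py` prints
a complete dual-mode HL7 message and shows the LRR/VAR contrast (an
8-gene message: LRR uses 18 distinct OBX-3 codes, VAR only 3);
`examples/03_indicators_and_cds.py` fires the clopidogrel alert and prints
the +112% alert-volume statistic for 1,518 → 3,218; and
`examples/04_full_pipeline.py` runs the whole batch workflow.

A thin CLI wraps the same library calls:

```bash
pgxbridge simulate --genes 2 --samples 96 --seed 7 --out simulated
pgxbridge validate-tables simulated/qs_translator.csv simulated/pgx_translator.csv simulated/gt_pt_translator.csv
pgxbridge run --config run.yaml --mode dual
```

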