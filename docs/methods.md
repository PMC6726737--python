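# Methods

## Problem and model

Disorders/differences of sex development (DSD) span a wide phenotypic range
— hypospadias, cryptorchidism, micropenis, gonadal dysgenesis, primary
ovarian insufficiency — that monogenic explanations often fail to cover.
For carriers of *MAMLD1* variants specifically, functional evidence argues
against single-gene sufficiency, motivating an oligogenic reading: each
patient carries, alongside the index *MAMLD1* variation, several rare
variants in other sex-development genes whose joint burden shapes the
phenotype. The package operationalizes that reading as a prioritization
problem: from a patient's annotated exome, retain the small set of rare,
well-supported variants in disease-relevant genes, classify their evidence,
and ask how the implicated genes relate to MAMLD1 in the protein-interaction
network.

The pipeline is deliberately deterministic and auditable rather than
statistical: no burden test or enrichment p-value is computed (sample sizes
of single-digit cohorts do not support one); the output is a filtered,
classified, cross-referenced candidate table plus network membership.

## Filter cascade

Rules run in a fixed order per variant; the first failure decides exclusion
and every evaluated rule is recorded in the trace.

| step | rule | default |
|------|------|---------|
| A  | gene on the disease-tailored panel (alias-aware) | — |
| B  | reference MAF ≤ `maf_keep_threshold` or never observed, and consequence in the retained set | 0.015 |
| D1 | identical variant (gene, HGVSc) in ≤ `max_patient_recurrence` patients | 2 |
| D2 | not flagged as repeat-region | — |
| D3 | not flagged as high-variability gene/region | — |
| D4 | depth ≥ `min_depth` and quality ≥ `min_quality` | 10 / 20 |
| D5 | het alt-fraction within `het_allele_balance` (hemi/hom exempt) | [0.25, 0.75] |
| H  | local-control cohort MAF lookup (informational) | — |
| I  | every observed MAF (reference and local cohort) < `maf_reject_threshold` | 0.01 |

Notes on choices that were genuinely open:

- **Both frequency bounds are applied as stated** even though the looser
  keep-stage bound is redundant against the reject-stage bound for the
  reference population: the keep stage consults only the reference MAF, the
  reject stage consults every observed source, so a variant common only in
  the local control cohort is caught at I, not B. Step I treats the sources
  symmetrically (either-source rejection).
- **Synonymous variants are never rejected on consequence** — they can
  affect splicing — and plain deep-intronic calls are not in the default
  retained set; near-splice-site intronic calls are typed
  `splicing_intronic` and retained. Which regulatory regions qualify is
  configurable, not guessed.
- **Visual alignment review is not automatable**; its role is covered by
  the D4/D5 QC rules plus a pass-through `confirmed` flag recording
  orthogonal (Sanger) confirmation. The flag never excludes.
- **D4/D5 thresholds** (depth ≥ 10, quality ≥ 20, balance [0.25, 0.75]) are
  common-practice defaults for the named criteria; all are configurable.
  A heterozygous call whose allelic depths sum to zero has undefined
  balance: it fails D4 (evidence unavailable) and D5 is skipped.
- **Recurrence is keyed on identical variants**, not genes: the same gene
  hit by different variants in several patients is biologically the
  interesting signal and is retained; only the identical call recurring in
  more than two patients is treated as a likely artifact or common
  polymorphism.

Candidate sets are order-independent (recurrence is computed cohort-wide
before per-variant rules), monotone in the reject threshold, and
anti-monotone in panel shrinkage; the tests check these properties against
a straight-line re-implementation of the rule predicate.

## Predictor consensus

Thirty predictors in four batteries: functional impact (SIFT, PolyPhen-2
HumDiv/HumVar, PROVEAN, MutationAssessor, MutationTaster, LRT, FATHMM,
FATHMM-MKL, VEST3, MetaSVM, MetaLR, M-CAP, DANN, fitCons — 15 tools),
conservation (GERP++, phyloP and phastCons vertebrate/mammalian, SiPhy — 6),
splicing databases (dbscSNV ADA/RF, SPIDEX ΔPSI — 3) and splicing assay
channels (SSF, MaxEntScan, NNSPLICE, GeneSplicer, ExSkip — 5, expressed as
reference-vs-variant relative change). Each tool is binarized with a
direction-aware cutoff at its published recommendation (e.g. SIFT ≤ 0.05,
PROVEAN ≤ −2.5, GERP++ ≥ 2.0, dbscSNV ≥ 0.6, |ΔPSI| ≥ 5, assay-channel
relative change ≥ 10 %); categorical tools are binarized by damaging-label
membership. A battery with no available score reports NA, distinct from 0
(all tools scored benign). CADD is carried raw — a PHRED-scaled score is
more informative unbinned. Consensus counts annotate; they never filter.
The packaged cohort fixture carries pre-computed counts, so no cutoff
default affects the reproduced numbers.

## ACMG/AMP classification

Evidence codes are inputs (assigned upstream by interpretation tools and
curation); the engine implements only the 2015 combining rules, evaluated
in a fixed order with the first satisfied rule recorded as rationale.
Two policy points the rule text leaves open:

- **Benign evidence below the Likely-benign bar does not veto** a
  pathogenic-side class: a set like {PS1, PP2, PP5, BP4} classifies Likely
  pathogenic. Only when both a pathogenic-side and a benign-side class are
  simultaneously satisfied does the result collapse to VUS
  (`conflict_VUS`). This matches the recorded classes in the cohort fixture
  and common interpreter behavior; the stricter reading (any BP forces VUS)
  would contradict the fixture.
- **Strength modifiers are not modeled**; codes are taken at face-value
  strength, as printed.

A printed class prefix in an evidence cell (`"VUS: PM2, PP3"`) is parsed
for concordance testing but never trusted as input. Cells that are a bare
dash carry no printed class and are counted unparseable rather than
guessed. The engine is verified against an independent literal restatement
of the rules, exhaustively over all code sets of size ≤ 4 from a 9-code
alphabet and on random sets from the full inventory.

## Cohort summaries

Cross-patient variant identity is (gene, HGVSc); coordinate agreement is
asserted when present. Phenotype tallies are **gene-level**: counting at
variant level over-counts multi-variant genes and cannot reproduce the
published per-phenotype figures consistently, so a gene carried by several
patients counts once per tag. Tags cover hypospadias, cryptorchidism,
micropenis, female gonadal development, reported sex/gonadal-development
involvement (`other_dsd`), and syndromic genitourinary phenotypes.
Diagnostic-panel overlap partitions the unique genes by a per-gene flag
recording membership in existing commercial DSD panels.

## Interaction network

An undirected graph with combined confidence scores in [0, 1] and evidence
channels, default pruning at 0.4 (conventional medium confidence) for
user-supplied exports. The packaged edge fixture transcribes exactly the
reported connectivity for the cohort genes — the MAMLD1–MAML1/2/3 hub, the
NOTCH1/2 hub (WNT9A/B, GLI2/3, FGF10, RET, PROP1, NRP1), the GLI3 and RIPK4
hubs, the RET–PIK3R3–PTPN11 chain, NRP1–FLNA, EYA1–FRAS1/FREM2, and the two
isolated couples CYP1A1–HSD3B2 and MYO7A–CDH23 — with placeholder scores of
0.9 and channel `curated`, since per-edge scores are not published and only
connectivity (not weights) feeds any computed number. MAMLD1–NOTCH1/2 edges
are included: the reported per-patient networks place NOTCH1 on a direct
path from MAMLD1, and the anchored component only reaches its reported size
with them. "Genes interacting with MAMLD1" is read as connected-component
membership (not direct neighborhood); only that reading is consistent with
the enumerated edges, and the identity 27 connected = 23 (component) + 2 +
2 (couples) is asserted in the tests.

## Synthetic cohorts

The generator emulates the statistical structure the cascade assumes —
panel membership, a background allele-frequency mixture (default weights
0.25 never-observed, 0.35 rare on (0, 0.015], 0.40 common on [0.01, 0.5]),
clean-QC planted candidates (MAF ≤ 0.005 or unobserved), recurrent variants
planted identically in ≥ 3 patients, and QC artifacts each violating
exactly one rule. Default scale is 8 patients × 200 variants against a
606-gene panel (the 41 cohort genes plus MAMLD1 are always included;
synthetic fill uses a reserved `SYNG` prefix to avoid symbol collisions);
tests run smaller configurations (2–4 patients, 25–80 variants) chosen to
exercise every rule while keeping the suite fast. Truth labels are fixed at
construction from the designed category via threshold arithmetic — the
cascade is never consulted — so recovery tests are a genuine two-route
check. Background variants are constructed to be excluded (off-panel, or
on-panel with a common frequency), which makes planted-candidate counts
exact.

One deterministic stream per seed with fixed per-patient offsets gives
byte-identical output files for a fixed configuration.

What passing synthetic tests does **not** show: robustness to ambiguous QC
(every artifact violates its rule decisively), realistic linkage or
site-frequency spectra, annotation noise, or caller disagreement. The
generator validates rule wiring and bookkeeping, not performance on real
exomes.

## Fixtures and their limits

The packaged cohort fixture transcribes the published candidate tables:
8 patients, 57 records, 55 unique variants in 41 genes, with frequencies
("ND" = never observed, distinct from an observed 0.0), predictor consensus
counts, evidence-code cells and per-gene annotations. Coordinates are
1-based on hg19/GRCh37. Fields the source tables do not print — ref/alt
alleles for two complex indels, read depths, qualities, allelic depths —
are filled with synthetic clean-QC placeholders (depth 100, quality 60,
balanced depths; an `N`-run reference for the one delins whose reference
bases are unprinted), marked as such here because the cascade's QC rules
need concrete values and the fixture records are, by construction, already
past QC. A SHA-256 manifest guards the transcription; the loader refuses a
tampered fixture. Raw exomes and the pre-filter per-patient variant counts
are not reproducible from published material and are out of scope.

## Numerical and degenerate-input conventions

- Frequencies compare with ≤ / ≥ exactly as stated (keep at ≤ 0.015, reject
  at ≥ 0.01); no epsilon is applied to printed thresholds.
- Empty panels, empty cohorts, header-only tables and edgeless graphs are
  valid inputs returning empty results, not errors; absence of a gene from
  a panel is a value, not an error.
- The allele-balance interval is closed on both ends.
- Unknown tokens (consequence, predictor, evidence code, channel) raise
  errors naming the token and, for files, the line number.
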