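# Methods

## The scoring model

`cnvscore` implements the quantitative evidence framework of the 2019
ACMG/ClinGen technical standards for constitutional copy-number variants.
A CNV (a genomic deletion, "loss", or duplication, "gain") accumulates
signed points across five evidence sections; the total maps onto a
five-tier clinical classification:

| total *S* | classification |
|---|---|
| *S* ≥ 0.99 | pathogenic |
| 0.90 ≤ *S* ≤ 0.98 | likely pathogenic |
| −0.89 ≤ *S* ≤ 0.89 | uncertain significance |
| −0.98 ≤ *S* ≤ −0.90 | likely benign |
| *S* ≤ −0.99 | benign |

The published bands are stated at 0.01 resolution; we realise them as the
threshold mapping *S* ≥ 0.99 → P, *S* ≥ 0.90 → LP, *S* > −0.90 → VUS,
*S* > −0.99 → LB, else B, which reproduces every printed band and is total
over the reals. Totals are accumulated in integer hundredths of a point,
so band boundaries are compared exactly and `auto_total` is bit-for-bit
reproducible — there is no randomness anywhere in the engine.

The metric defines 40 categories per dosage direction (80 total). The
engine scores 18 loss and 16 gain categories automatically from local
annotation databases; the remainder (case evidence 4A–4N, family history
5A–5H, and the phenotype-dependent gain breakpoint categories 2J/2K) take
curator-entered points, validated against each category's configured range
and, by default, against a 0.05 adjustment grid around the default. The
whole table ships as data (`cnvscore/data/metric_config.yaml`). Defaults
for the automated categories are fixed by the metric; defaults for
manual-only categories are transcribed from the standards' tables and are
deliberately overridable, since they are curation policy rather than code.

## Annotation

Coordinates are 1-based and fully closed everywhere internally (the
convention of clinical CNV reports and the ClinGen dosage map); a BED
reader converts 0-based half-open tracks on load. Overlap means "shares
at least one base" and is applied uniformly to every collection — the
standards state this rule explicitly only for gene counting, so uniform
application is a design choice, surfaced here rather than buried.
Chromosome labels are normalised (`22` ≡ `chr22`).

Six tab-delimited databases drive annotation: gene models with exon/CDS
structure and constraint metrics (pLI, o/e upper bound, haploinsufficiency
percentile), the curated dosage-sensitivity map (HI/TS genes and regions
with scores 0–3/30/40), established-benign loss and gain tracks,
population CNVs with frequencies and cohort sizes, known small variants
with clinical significance, and an optional curated critical-region table.
Interval queries run on per-chromosome interval trees and are verified in
the test suite against a brute-force linear scan.

Gene overlap is classified strand-aware on the *selected transcript* of
each locus (canonical flag, then longest CDS, then longest span, then
lexicographic id — the autoPVS1 convention): a partial overlap covering
the transcription start is a 5′ overlap, one covering the transcription
end a 3′ overlap, with exon ordinals counted in transcription order so
"last exon" is well defined on both strands. "Functionally important
element" means any dosage-map element with a curation score of 1, 2 or 3.
Benign-region comparisons are on protein-coding gene content, not
coordinates: a CNV whose coding-gene set equals the benign element's is
"identical" even if the breakpoints differ.

A population variant is *common* when its frequency is ≥ 1 % and its
cohort is ≥ 1,000 samples (sample-counted, DGV-style) or ≥ 2,000 alleles
(allele-counted, gnomAD-style); only common variants of the same dosage
enter category 4O.

## Intragenic loss-of-function calls

For a CNV fully inside an established HI gene, a graded PVS1 call drives
categories 2E (loss) and 2I (gain):

- **Reading frame.** The affected coding length is the exact intersection
  of the CNV with the coding parts of the selected transcript's exons;
  the frame is disrupted iff that length is not a multiple of 3.
- **NMD.** No nucleotide sequence is available at CNV scale, so the
  premature termination codon is approximated at the CNV junction: for a
  deletion, the spliced position where the removed sequence joins; for a
  tandem duplication, the junction between the duplicated copy and the
  downstream original. NMD is predicted iff that position lies ≥ 50 nt
  upstream of the last exon–exon junction of the (post-event) transcript;
  single-exon genes never trigger NMD. The test suite checks this
  arithmetic against an independent base-by-base transcript
  reconstruction on seeded random gene models.
- **Strength mapping (deletion).** Frameshift + NMD on a biologically
  relevant transcript → PVS1 (0.9 points); otherwise a curated
  critical-region hit → PVS1_Strong (0.45); otherwise, if LoF variants in
  the region are not frequent (no known pathogenic variant at allele
  frequency ≥ 0.001, configurable), removal of > 10 % of the protein →
  PVS1_Strong, ≤ 10 % → PVS1_Moderate (0.3). "Critical to protein
  function" is never inferred — it is true only when a curated record
  says so.
- **Strength mapping (duplication).** Frameshift + NMD with tandem status
  *proven* → PVS1 (0.9); *assumed* → PVS1_Strong (0.45); *unknown* → no
  automated strength (0, deferred to manual review). Tandem status is a
  per-query input (`--tandem`), not something the engine can infer.

## Decision trees and aggregation

Sections are walked in ascending order. Section 1 gives 0 (1A) when the
CNV holds protein-coding genes or functionally important elements, −0.60
(1B) otherwise. Section 2 runs the dosage-specific tree (established
HI/TS first, then benign, then predictors/fallbacks); when several
2-series categories apply, **all candidates stay in the report but only
the highest-scoring one contributes points**. Section 3 scores gene count
(loss: 25–34 → 0.45, ≥ 35 → 0.9; gain: 35–49 → 0.45, ≥ 50 → 0.9 — the
closed printed 3B ranges force these boundaries). Section 4's automated
part (4O) gives −1.0 for containment in a common same-dosage variant, or
for ≥ 50 % coverage with no additional coding genes.

A benign containment hit is *terminal*: loss 2F (and, mirroring it, gain
2C/2D — the standards do not state finality for gains, so this is a
configurable design choice) fixes the automated total at exactly −1.0 and
skips later sections. If positive Section-2 evidence fired first, the
benign hit is recorded but suppressed, and a conflict flag asks for
review; the same flagging applies when 4O co-fires with positive
Section-2 evidence or when a manual entry overrides an automated winner.

An automated total at or beyond ±0.99, or a terminal benign hit, marks
the interpretation as sufficient without manual evidence.

## Synthetic data

The fixture generator builds a complete annotation database and a ~40-CNV
suite covering every automated branch of both dosage trees, plus replicas
of three published worked examples: a 1.5-Mb chr22 deletion that spans a
score-3 HI region and 32 protein-coding genes (expected total 1.45,
pathogenic), a 49-gene chr11 deletion (Section 3 → 0.9, likely
pathogenic), and a chr1 deletion inside a 12.45 %-frequency population
loss (4O → −1.0, benign). Expected scorecards are derived constructively
from the geometry during generation — never by running the engine — so
the suite is an independent oracle; the engine must reproduce every
expectation exactly.

The generator emulates gene structure (multi-exon models on both strands
with UTRs), curation tracks and population variants, but not sequence
content, overlapping transcript complexity, segmental duplications, or
the long-tailed size distribution of real CNV callsets. Passing the suite
therefore demonstrates the correctness of the decision logic and
arithmetic under the metric, not calibration against real curated CNVs.
Only cosmetic attributes (constraint metrics of genes that must not trip
any predictor) are drawn from the seed; all category-deciding geometry is
fixed, so the suite and its expectations are identical across seeds and a
given seed reproduces the database byte for byte.

## Numerical and degenerate-input choices

- Point totals use integer hundredths; every metric value is a multiple
  of 0.01, so no tolerance is needed at band boundaries.
- A record with `start == end` has length 1; a query abutting a record
  (query end + 1 = record start) does not overlap it.
- Queries on unknown chromosomes return empty results (logged once), not
  errors — batch ergonomics for mixed references.
- Transcript-selection ties break by longest span then lexicographic id,
  so batch output is deterministic across platforms.
- Deletions touching no coding base (intronic/UTR-only) get no PVS1
  strength regardless of frame arithmetic.
- At exactly 10 % protein removed, the weaker PVS1_Moderate applies (the
  strong branch requires strictly more than 10 %).
- Batch rows fail independently: a malformed row yields a `parse_error`
  status column, never an aborted batch.

## Problem sizes in the test suite

Oracle-equivalence checks run 1,000 random interval queries against a
200-record database and 200 random intragenic deletions against the
brute-force NMD reconstruction; the branch-coverage suite scores ~40
CNVs. The full suite and the acceptance script each complete in a few
seconds.

## Known limitations

- No sequence-level consequence prediction: splice effects, regulatory
  disruption and position effects are out of scope; the PTC-at-junction
  NMD approximation is conservative and documented above.
- Manual-only category defaults are transcribed curation policy; sites
  should review `metric_config.yaml` against their own standard operating
  procedure.
- Phenotype matching (gain 2J/2K, Section 4 case evidence) is not
  automated; the engine solicits those points explicitly.
- Single genome build per database directory; the build tag is echoed in
  reports but never validated against coordinates.
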