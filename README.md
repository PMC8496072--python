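# cnvscore

Semiautomatic interpretation of constitutional copy-number variants (CNVs)
under the 2019 ACMG/ClinGen technical standards.

Clinical laboratories classify a deletion or duplication by walking a
quantitative scoring metric: 40 evidence categories per dosage direction,
each contributing signed points, summed and mapped onto the five-tier
scale (pathogenic / likely pathogenic / uncertain significance / likely
benign / benign). Doing this by hand means querying half a dozen
databases per variant. `cnvscore` automates the automatable part: it
annotates a CNV against local tab-delimited databases (gene models,
ClinGen-style dosage-sensitivity map, established-benign regions,
population CNVs, known variants), scores 18 of the 40 loss criteria and
16 of the 40 gain criteria automatically, validates and merges
curator-entered points for the rest, and emits a per-category evidence
report with the point total and classification.

The total *S* classifies as: *S* ≥ 0.99 pathogenic; 0.90–0.98 likely
pathogenic; −0.89–0.89 uncertain; −0.90–−0.98 likely benign; ≤ −0.99
benign. Highlights of the automated logic:

- **Section 1** — genomic content: −0.60 when the CNV contains no
  protein-coding gene and no functionally important element (dosage
  score 1–3), else 0.
- **Section 2** — established dosage sensitivity: full containment of a
  haploinsufficient (loss) or triplosensitive (gain) gene/region scores
  1.0; partial overlaps of HI genes are resolved strand-aware (5′ vs 3′
  end, last-exon logic, documented pathogenic variants); CNVs inside an
  HI gene get a graded PVS1 call from reading-frame arithmetic and the
  50-nt NMD rule (0.9 / 0.45 / 0.3); benign containment is terminal at
  −1.0. When several categories apply, all are reported but only the
  highest contributes.
- **Section 3** — gene count: 0.45 / 0.9 above dosage-specific cuts
  (loss 25 and 35; gain 35 and 50).
- **Section 4O** — containment in (or ≥ 50 % coverage by) a common
  population variant of the same dosage (frequency ≥ 1 %, cohort ≥ 1,000
  samples or ≥ 2,000 alleles) scores −1.0.

See `docs/methods.md` for the full model, parameter defaults and design
choices.

## Worked example

Generate the synthetic annotation database (no downloads needed — it
includes a replica of a published 1.5-Mb chr22 deletion spanning an
established HI region with 32 protein-coding genes) and score that
deletion:

```sh
cnvscore make-fixtures --out fixtures --seed 1
cnvscore score --cnv chr22:18,761,827-20,307,561 --type loss \
    --db fixtures --format text
```

Output:

```
CNV: chr22:18761827-20307561 (loss)
Genome build: GRCh37

Evidence (sections 1-5):
  * 1A    +0.00 [0..0] (automated) contains 32 protein-coding gene(s); overlaps functionally important element (dosage score 1-3)
  * 2A    +1.00 [1..1] (automated) completely spans established HI element HIR0001
  * 3B    +0.45 [0.45..0.45] (automated) 32 protein-coding gene(s)
  (* = contributes to the total)

Automated total: 1.45 -> pathogenic
Final total:     1.45 -> pathogenic
Classification reached without manual evidence.
```

Reading it: the deletion contains protein-coding genes (1A, 0 points),
completely spans an established haploinsufficient region (2A, +1.0), and
holds 32 genes, inside the 25–34 band (3B, +0.45). The 1.45 total is at
or above 0.99, so the CNV is pathogenic before any manual evidence —
the report says so explicitly.

Manual evidence merges from a JSON or TSV file and is validated against
each category's allowed range and the 0.05 adjustment grid:

```sh
cnvscore score --cnv chr1:1000000-1200000 --type gain \
    --db fixtures --manual evidence.json
```

Batch mode scores one CNV per row and isolates per-row failures:

```sh
cnvscore batch --in fixtures/suite.tsv --db fixtures --out results.tsv
```

The same functionality is available as a library
(`cnvscore.interpret(query, db, cfg, ...)` returns a `ScoreCard`).

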