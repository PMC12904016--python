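# ncsplice

Prioritization and protein-level consequence analysis of **non-canonical
splicing variants** (NCSVs) — variants outside the ±2 canonical splice
dinucleotides that nonetheless disrupt mRNA splicing. Such variants are
routinely annotated as missense, synonymous or intronic and filtered out of
rare-disease exome pipelines, although a substantial fraction of them cause
exon skipping, partial exon deletion through cryptic splice sites, or intron
retention. `ncsplice` implements the full in-silico side of an NCSV study
for recessive disease cohorts (the motivating application is idiopathic male
infertility): candidate prioritization from splicing scores, the protein
consequence of an observed aberrant splicing event, clinical strength
assignment, biallelic/X-linked inheritance screening, and the catalog
statistics — plus a synthetic-data generator so every stage is testable
without any downloads.

## What it computes

**Prioritization.** A variant is a *potential splicing variant* when at
least 9 of 18 integrated splicing predictors call it splice-altering
(SPCards count ≥ 9) **or** its SpliceAI delta score is ≥ 0.5. Canonical ±2
variants and stop-gains are established loss-of-function classes and are
excluded from the NCSV candidate set.

**Consequence engine.** Given a transcript model and an observed splicing
outcome, the engine edits the mRNA, re-derives the CDS from the original
start codon, and names the protein change in HGVS p. notation by trimming
the maximal common prefix and then suffix between the reference and the
alternate translation (the 3'-most representation). The *disrupted-protein
fraction* follows the conventions of curated clinical tables:

| consequence | disrupted residues |
|---|---|
| in-frame deletion / delins of residues *s…e* | *e − s + 1* |
| in-frame insertion of *m* residues | *m* |
| frameshift / premature stop at residue *f* of an *L*-residue protein | *L − f* |

A LoF-type consequence (frameshift or premature stop) disrupting **more than
10 %** of the protein is assigned **PVS1_Strong**; everything else is
`not_met`. Each validated NCSV is also placed into one of six classes,
region × outcome: exonic/intronic × {exon skipping, partial exon deletion,
intron retention} (labels A–F).

**Cohort screen.** Variants with any population allele frequency > 0.01 are
excluded; missense variants need ≥ 3 of 4 damaging calls (SIFT, PolyPhen-2,
MutationTaster, CADD > 20; a variant with all four missing is retained).
Candidates are emitted per patient as homozygous NCSVs, hemizygous NCSVs on
X in males, or compound heterozygotes pairing a het NCSV with a trans
partner from {canonical splicing, stop-gain, stop-loss, frameshift,
deleterious missense, another NCSV}; pairs without phase evidence are
flagged `unknown` rather than silently assumed trans.

**Statistics.** Percentages are printed half-up at two decimals; the 2×2
exact test uses the probability-mass two-sided p, a conditional-MLE odds
ratio and an exact conditional CI (cross-checked against R's
`fisher.test`); Pearson correlation of the two splicing scores is computed
pairwise-complete.

## Worked example

A 79-bp intron retention that shifts the reading frame from residue 480 of
a 4471-residue axonemal dynein:

```python
from ncsplice import apply_event, protein_consequence, pvs1_call, rate
from ncsplice.simulate import reconstruct_printed_event

genome, tx, events = reconstruct_printed_event(
    4471, "Intron 10 79bp retention", "p.V480Ifs*17", seed=0
)
edited = apply_event(tx, events)
cons = protein_consequence(tx.protein, edited.alt_cds,
                           frame_shifted=edited.net_cds_indel % 3 != 0)
print("alteration :", cons.hgvs_p)
print("disrupted  :", f"{cons.disrupted_count}/{tx.protein_length} "
                      f"({rate(cons.disrupted_count, tx.protein_length)}%)")
print("PVS1       :", pvs1_call(cons).strength)
```

prints

```
alteration : p.V480Ifs*17
disrupted  : 3991/4471 (89.26%)
PVS1       : PVS1_Strong
```

i.e. the retention diverges the protein at V480, reaches a new stop 17
codons later, removes the 3991 residues downstream of the first altered one
(89.26 % of the protein), and therefore meets the PVS1_Strong bar.

`reconstruct_printed_event` engineers a toy transcript whose *true* spliced
product has exactly the requested geometry; it is how the packaged
curated-table rows (in `ncsplice/data/curated_catalog.tsv`) are turned into
executable golden tests.

## Command line

```sh
ncsplice simulate --seed 1 --outdir run/          # synthetic FASTA/GTF/TSV dataset
ncsplice annotate --genome run/genome.fa --gtf run/transcripts.gtf \
         --variants run/variants.tsv --out run/variants.annotated.tsv
ncsplice prioritize --variants run/variants.annotated.tsv --out run/prioritized.tsv
ncsplice consequence --genome run/genome.fa --gtf run/transcripts.gtf \
         --events run/events.tsv --variants run/variants.annotated.tsv \
         --out run/consequences.tsv
ncsplice cohort-screen --variants run/variants_with_cohort.tsv \
         --cohort run/cohort.tsv --out run/candidates.tsv
ncsplice report --out run/catalog_report.json
ncsplice run-all --seed 1 --outdir run/           # all of the above
```

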