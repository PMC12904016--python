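# Methods

## Transcript model and coordinates

A transcript is an ordered list of 1-based inclusive exon intervals on one
contig, 5'→3' in transcript orientation, with a CDS span whose first base is
the A of the start codon and whose last base is the final base of the stop
codon. Building a transcript derives the spliced mRNA (reverse-complemented
for minus-strand models), the CDS and the protein, and enforces the ORF
invariants: length divisible by 3, ATG start, terminal stop, no internal
stop, no N inside the CDS. Validation failures raise a structured error
naming the violated invariant.

Coordinate mapping follows HGVS c. conventions: exonic positions are CDS
offsets; intronic positions anchor to the nearer exon, the first half of an
intron as `c.N+k` off the upstream exon and the second half as `c.N−k` off
the downstream exon (the midpoint of an odd-length intron anchors
upstream — HGVS leaves this open and a deterministic tie-break is needed).
Positions outside the CDS on the mRNA are flagged as 5'/3' UTR without
fine-grained UTR numbering; UTR-aware HGVS is out of scope. The mapping and
its inverse are fuzz-tested to be mutually inverse over the full
exonic+intronic domain.

The distance-to-junction convention is signed along the transcript
direction relative to the nearest junction: intronic past a donor positive,
intronic ahead of an acceptor negative, the exonic base immediately 5' of a
donor −1, the exonic base k past an acceptor +k. This is the convention
that makes all distance columns of the packaged curated tables internally
consistent; equidistant exonic ties break toward the junction implied by
the variant's HGVS c. anchor, else toward the donor. Splicing consensus
windows are donor −3…+8 and acceptor −12…+2 (inclusive).

## Prioritization and classification

Classification assigns exactly one class per variant: canonical splicing
iff the intron offset is within ±2; other intronic positions are intronic;
exonic SNVs are classified by re-translating the affected codon
(synonymous / missense / stop-gain / stop-loss / start-loss); exonic indels
by length difference mod 3. Prioritization is the inclusive union
SPCards ≥ 9 **or** SpliceAI ≥ 0.5 — a union rather than a conjunction
because variants supported by a single arm are still informative, and the
decision records which arms fired. A missing score never blocks the other
arm; a variant with both scores missing is simply not prioritized, never
dropped with an error.

## Consequence engine

Events are applied as edits in transcript (mRNA) space: exon skipping
deletes the exon's nucleotides, a partial exon deletion removes a
sub-interval (a cryptic-splice-site product), intron retention inserts the
retained (sub-)intron at its junction. Retained sub-intervals must stay
anchored to one end of the intron, which is what a cryptic donor/acceptor
within the intron produces. Compound outcomes of one allele are applied
together, 3'→5' so reference coordinates stay valid. The CDS is re-derived
from the original start codon and extends to the mRNA 3' end, so a
frameshift is free to find its new stop downstream of the old one; an event
that removes the start codon yields consequence `none` with a note, and an
alternate frame that never reaches a stop is flagged `no-stop-found` rather
than invented.

Naming trims the maximal common prefix first, then the maximal common
suffix of the remainders. Prefix-first trimming places ambiguous deletions
in repeated context at their 3'-most (highest-numbered) representation,
matching HGVS practice; remaining ties therefore resolve toward larger
start positions deterministically. Frame disruption is decided from the
event arithmetic (net inserted−deleted nucleotides inside the CDS, mod 3),
not guessed from the translation, so a frameshift that coincidentally
shares a C-terminal residue with the reference is still a frameshift. A
translation that stops exactly at the divergence point is reported as a
premature stop (`p.X123*`), which the PVS1 logic treats identically to a
frameshift; frame-preserving events that truncate without recovering the
C-terminus are likewise reported in frameshift notation, since their effect
is loss of the downstream protein.

Disrupted-residue counting is inclusive for in-frame deletions/delins
(end − start + 1), the insert length for in-frame insertions, and
`protein_length − first_altered` for frameshifts and premature stops
(exclusive of the first altered residue). These conventions are fixed by
majority evidence across the packaged curated tables — they reproduce every
internally consistent row exactly — and rows that contradict them are
shipped with `golden = 0` and a note instead of being forced to agree
(e.g. an in-frame deletion printed with a count one below its inclusive
span, and one fraction printed truncated rather than half-up rounded).
The PVS1_Strong rule uses a strict inequality (> 10 % of the protein) and
applies only to LoF-type consequences; a 14.74 % in-frame deletion does not
qualify.

## Cohort screen

The frequency filter drops a variant when any configured population
frequency exceeds 0.01 (strict); missing frequencies keep the variant. For
compound heterozygotes the filter is applied per arm: the NCSV allele at
the strict 0.01, the trans partner at a configurable lenient 0.05 — the
packaged cohort table itself contains a retained partner at 0.043, which
fixes the lenient default. Missense deleteriousness is ≥ 3 damaging calls
of four tools, counting PolyPhen-2 "possibly damaging" as a call and
CADD > 20; "more than three" is read as ≥ 3 because retained three-call
rows exist in the packaged table and a literal > 3 would be incoherent with
the all-missing-retained rule. Unphased pairs are emitted with
`phase_status = unknown` for downstream confirmation (the real-world step
is Sanger of the parents or a long amplicon), cis-asserted pairs are
rejected, and hemizygous calls off the X chromosome raise a data error
because the screen is defined for all-male cohorts. Screening output is
sorted (patient, gene, key) and therefore independent of input order.

## Exact 2×2 inference

The two-sided p is the probability-mass definition: the sum of
fixed-margin tables whose hypergeometric probability does not exceed the
observed one (with a 1+1e−9 slack factor against floating-point ties),
matching full enumeration to 1e−12 on all tables tried up to total 60. The
odds ratio defaults to the conditional MLE (root of E[X|ψ] = a under
Fisher's noncentral hypergeometric), with the sample cross-product as an
option; the 95 % CI inverts the exact conditional tails. Degenerate margins
return p = 1 with an undefined OR. Boundary tables give OR 0/∞ with the
corresponding one-sided CI. Implementation cross-checked against R's
`fisher.test` on representative tables, including a zero cell.

## Synthetic data

`gen_transcriptome` draws 3–7 exons of 60–240 nt and introns of 80–300 nt
per transcript (one transcript per contig, ~25 % minus-strand, the last on
an X contig), back-translating a random protein so the ORF is valid by
construction, with GT…AG intron ends. The defaults are toy-scale on
purpose: large enough for every event geometry, small enough that the whole
suite runs in seconds.

`spike_events` rotates through the six region × outcome classes, places a
junction-proximal SNV consistent with each event (70 % inside the consensus
windows by default, echoing the observed share of validated NCSVs), and
records the true consequence computed by an *independent oracle*: direct
string surgery on the exon/intron sequence lists followed by a plain
codon-loop translation and index-loop prefix/suffix diff. The engine is
required to agree with this oracle on 100 % of spiked events.

`gen_scores` draws (SPCards, SpliceAI) from a Gaussian copula —
`spcards = round(18·Φ(z₁))`, `spliceai = Φ(z₂)` — with a common +1.2 latent
shift for spiked variants. Discretisation and the mixture shift attenuate
or inflate the product-moment correlation relative to the latent one, so
the latent correlation is solved once by bisection on a fixed,
seed-independent Monte-Carlo draw so that the *emitted* scores hit the
configured target (default 0.83, the empirically observed correlation
between the two scores) within the generator's ±0.05 contract at n ≥ 2000.
A `separated_scores` mode draws the two groups on disjoint sides of both
thresholds for sensitivity/specificity-by-construction checks.

`gen_cohort` plants 7 homozygous, 9 compound-heterozygous (trans) and 1
hemizygous configuration into a 34-patient all-male cohort by default and
fills the remainder with decoys the screen must reject: a lone het NCSV, a
cis pair, a common-frequency homozygote, and a het NCSV with a benign
missense partner. Synthesized trans partners are placed in the contig
padding upstream of the transcript so their keys cannot collide with
catalog variants.

What the generator does *not* emulate: sequencing noise and genotyping
error, linkage structure and realistic allele-frequency spectra,
NMD and expression effects, multiple isoforms per gene, and any dependence
of the scores on actual sequence context (scores are annotations by
construction). Passing tests therefore demonstrate the correctness of the
bookkeeping, coordinate arithmetic and decision rules — not the accuracy of
splicing prediction on real data.

## Curated-table reconstruction

`reconstruct_printed_event` turns a printed row (protein length, outcome
descriptor, HGVS p. alteration) into an executable fixture: a toy
transcript whose true spliced product has exactly the printed consequence.
In-frame deletions become codon-aligned skipped exons with the printed
boundary residues pinned and the flanking residues chosen to block trim
shifts; the single-residue delins searches codon pairs whose hybrid codon
encodes the junction residue; frameshifts weave the post-junction
nucleotides so the shifted frame spells the printed first altered residue
and stop offset while the reference frame stays stop-free (greedy per-codon
rejection with deterministic retries). Every reconstruction is verified
against the independent oracle before being returned. Skipped-exon lengths
that the source does not print are chosen as 100 nt (any non-multiple of 3
works for a frameshift; the fraction depends only on the first altered
residue). Exon/intron ordinals in the fixtures are toy ordinals, not the
real gene's exon numbers — the consequence depends only on geometry.

## Problem sizes

Default test and acceptance runs use 6–30 transcripts, 200–5000 variants
and 34 patients; the full suite completes in well under a minute on one
core. The correlation check uses n = 5000 variant pairs; oracle-agreement
checks use ≥ 1000 spiked events; the exact-test oracle enumerates tables up
to total 60.

## Known limitations

One transcript per gene (no isoform selection); no UTR-aware HGVS; no
insertion/deletion splicing variants in the spike generator (SNVs only, as
scores for indels are typically absent from the score sources emulated); the
six-class taxonomy treats a compound outcome as a set of labels and reports
the worst (largest) fraction when a single number is required; fs*1 events
are unrepresentable by construction (an immediate stop is `p.X*`), matching
HGVS rather than occasional nonstandard printed forms.
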