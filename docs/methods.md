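# Methods

## Scope and data model

The package starts from assembled transcript models, not reads: alignment
and assembly (the TopHat/Cufflinks/Scripture layer of a classic bulk
RNA-seq workflow) are upstream and out of scope, as are PhyloCSF itself,
conservation scoring, and figure rendering.  All coordinates are 0-based
half-open internally; GTF I/O is 1-based closed, BED I/O 0-based
half-open, matching each format's native dialect.  A transcript is an
ordered set of non-overlapping exons on one chromosome strand; a locus is
the gene-level grouping (`gene_id`), and gene-level footprints are the
union span of a locus's isoforms.

Distances between transcripts are **span gaps**: 0 when spans overlap or
abut, and an infinite "unreachable" sentinel across chromosomes, so
threshold tests like `distance <= window` need no special cases.  Span gap
was chosen over TSS-to-TSS distance because it is the most conservative
reading of "genomic distance" and makes overlap imply distance zero; the
choice matters only for loci comparable in size to the cis window and is
isolated in `genomic_distance` for sensitivity analysis.

## lncRNA catalog

Filtering runs five stages in order, each logged in an attrition table:

| stage | rule | default |
|---|---|---|
| length | spliced length ≥ min_length | 200 nt (the lncRNA size definition) |
| exons | ≥ min_exons_novel unless the model matches the reference lncRNA annotation | 2 |
| expression | max FPKM across samples ≥ min_fpkm | 0.5 |
| coding overlap | no same-strand exonic overlap with any coding model | — |
| coding potential | provided score ≤ coding_score_max, else longest ORF < orf_max_codons when a sequence is supplied, else pass with warning | 0 (PhyloCSF convention); 100 codons |

The exon-count and FPKM thresholds are the standard desk values for lncRNA
catalogs; they are not derivable from first principles and are fully
configurable, with the attrition log making each stage's effect auditable.
Known transcripts are exempt from the exon filter because reference
catalogs contain many single-exon lncRNAs.  The longest-ORF surrogate
scans the three forward frames of the spliced sense sequence (ATG to stop,
stop not counted); it stands in only when no coding-potential score is
provided.

Novelty: a spliced candidate is *known* iff its intron chain (chromosome,
strand, ordered intron coordinates) is identical to a reference transcript
— exon termini are deliberately ignored, as assembly rarely recovers exact
ends; a single-exon candidate is known iff it has same-strand exonic
overlap ≥ 50 % of the shorter model with a single-exon reference
transcript.  Alternatives (any-overlap, class-code matching) would be more
permissive; the intron-chain rule is the stricter and more reproducible
choice.

Positional classes use a fixed precedence: **antisense** (≥ 1 bp exonic
overlap with a coding exon on the opposite strand) before **intronic**
(every exon inside introns of one coding transcript — for contiguous exons
this is equivalent to each exon lying in a single intron; either strand,
since host strand is no evidence about a contained, non-exon-touching
transcript) before **lincRNA** (everything else, including span-only
overlaps that satisfy neither rule).  Exon contact is ranked above
containment because it is the stronger structural evidence.  The
classifier is validated against a per-base set-membership oracle on
hundreds of random toy topologies.

## Expression and differential testing

FPKM is `fragments × 10⁹ / (length × total mapped fragments)`; the
implementation checks the conservation identity (FPKM inverts back to the
fragment totals) in tests.  Differential expression per pairwise
comparison is a two-sided pooled-variance Student's *t*-test on
log₂(FPKM + 1), BH step-up adjustment across all transcripts of that
comparison (lncRNA and mRNA jointly), and a significance call at adjusted
*P* < alpha (0.05).  A variance floor of 1e-8 on the pooled estimate keeps
perfectly separated constant groups finite and makes two identical
constant groups return *P* = 1 without special-casing.  Fold changes are
pseudocounted group-mean ratios on raw FPKM (pseudocount 1 FPKM) reported
with the signed convention (ratios < 1 print as −1/ratio) used in
expression tables.

Correlation analyses (clustering, cis/trans PCC, neighbor classes) operate
on log₁₀(FPKM + 1) over all samples jointly.  The transform choice is a
design decision — raw FPKM is heavily right-skewed and a single
high-expression sample would dominate the product-moment statistic;
callers can correlate raw values through the lower-level API.
Zero-variance rows/samples are excluded with a warning rather than
poisoning a whole run, but a fully degenerate input is an error.

Sample clustering is agglomerative with average linkage on 1 − PCC between
sample profiles; `cut(k)` uses the maxclust criterion, and trees serialize
to Newick for inspection.

At *n* = 3 per group the *t*/BH rule has limited power: for a shift of 4
within-group standard deviations, the per-test noncentral-*t* power at the
Bonferroni and unadjusted thresholds brackets what BH can recover, and the
expected recovery over a few hundred tests is well below 100 %.  The test
suite therefore asserts recovery inside that power-derived band (plus
direction correctness and FDR control) rather than near-complete recovery;
the synthetic defaults use a 3 log₂-unit effect with 0.4 log₂ within-group
noise, where power is effectively complete.

## Target prediction and enrichment

*cis* pairs are (lncRNA transcript, coding locus) pairs with span gap ≤
100 kb (inclusive, per the usual "within 100 kb" reading) on the same
chromosome; *trans* pairs require |PCC| strictly > 0.95 **and** (gap >
100 kb or different chromosomes), so the two sets partition any pair.
Coding-side expression is the locus-level sum of isoform FPKM.  The
neighbor-correlation analysis compares three PCC classes —
lncRNA:cis-mRNA, mRNA:cis-mRNA (coding-locus pairs within the window) and
random coding pairs, count-matched to the lncRNA class and sampled without
replacement under a seed — reporting class means and pooled-variance
*t*-test *P*-values for each class-vs-random and the lnc-vs-mRNA contrast,
without interpreting them.

Gene-set over-representation is the upper-tail hypergeometric probability
P(X ≥ k) for k foreground hits out of a term's K background genes, BH
across terms, rich factor k/K, significance at *q* < 0.05.  The background
defaults to the expressed coding loci of the run rather than a whole
genome — the conservative standard for expression data.  Terms are flat
GMT sets; ontology structure is not modeled.

## Synthetic study generator

The generator emulates a 3 + 3 + 3 three-group design (eosinophilic-like,
noneosinophilic-like, control).  Defaults: 60 coding loci (5–9 exons,
~30 % with a second exon-skipping isoform, giving ~1.3 isoforms/locus) and
48 lncRNA loci — 26 lincRNA, 10 intronic, 12 antisense, with 12 of the 48
"known" — interleaved on two chromosomes with intergenic gaps drawn half
from 10–90 kb (inside the cis window) and half from 150–250 kb (outside).
Placement is constructive: intronic models are laid inside a single intron
of their host, antisense models overlap an internal host exon by 100 bp on
the opposite strand, and known models are copied into the reference
annotation with jittered termini but identical intron chains, so planted
class and novelty labels are geometrically guaranteed rather than
rejection-sampled.

Expression: per-transcript log₂-FPKM baselines are normal with mean 4
(mRNA) or 2 (lncRNA) and SD 1.5 — encoding the empirical fact that
lncRNAs are expressed below coding genes — with within-sample noise SD
0.4.  A 12 % DE fraction receives a ±3 log₂ shift in the eosinophilic
group, the noneosinophilic group, or both ("common" DE).  Two neighbor
pairs are planted adjacent to coding loci at 20–80 kb: a **headline pair**
(noise correlation ρ = 0.9 *and* a +6 log₂ eosinophilic shift in both
members, mimicking a disease-specific lncRNA–chemokine pair) and a
**quiet pair** (ρ = 0.9 only), whose observed PCC estimates ρ without
group-structure inflation and is checked against the Fisher-z sampling
interval at n = 9.  Expected fragment counts invert the FPKM formula at
~2 × 10⁷ mapped fragments per sample and are Poisson-sampled; the
log-normal/Poisson hierarchy was preferred to a negative binomial for
transparency at this sample size, since the validation surface is
recovery, not count-model realism.  Gene sets are random draws over coding
loci with three terms over-sampling true-DE loci at 60 %.

What the generator does **not** model: read-level artifacts, isoform
quantification ambiguity, batch effects, library-size composition bias,
and realistic (heavier-than-Poisson) biological dispersion.  Passing
recovery tests therefore demonstrates the correctness of the analysis
logic under its stated assumptions, not performance on real tissue data.

A single integer seed fixes every random stream (annotation, DE
assignment, expression noise, gene sets, random pairs) through independent
child generators, and the pipeline manifest hashes every output file, so
end-to-end reruns are bit-identical.

## Problem sizes and numerical choices

Validation runs use the default study (≈ 118 transcripts, 9 samples), 200
random interval topologies for the geometry oracles, 500 random vectors
(m ≤ 100) for the BH oracle, backgrounds of N ≤ 12 for exhaustive
hypergeometric enumeration, and 100–200 replicate null studies for
false-positive calibration — sizes at which exact oracles are feasible and
the whole suite runs in seconds.  Ties in BH are handled by stable
sorting; correlations are clipped to [−1, 1] against floating-point
drift; hierarchical clustering symmetrizes the distance matrix before
linkage.  Known limitations: the intron-chain novelty rule cannot credit
partially assembled known transcripts; Cuffdiff-style dispersion modeling
is intentionally not implemented (the *t*/BH rule is the stated
significance criterion); and the cis window uses span gap, not promoter
distance.
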