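# Methods

Definitions and conventions used throughout `hydroxymap`. Coordinates:
interval tracks (BED-like, gene models) are half-open 0-based; per-base
cytosine records are 1-based, one row per strand-cytosine.

## Assay model

BS-Seq leaves both mC and hmC unconverted, measuring total modification
modC = mC + hmC. TAB-Seq (glucosylation of hmC followed by Tet
oxidation of mC) leaves only hmC protected. Per cytosine with true
fractions (f_hmC, f_mC), a read reports "C" (unconverted) with
probability

```
TAB:  p = f_hmC · protection + f_mC · ncr_mC + (1 − f_hmC − f_mC) · ncr_C
BS:   p = (f_hmC + f_mC) · (1 − bs_failure) + (1 − f_hmC − f_mC) · ncr_C
```

Coverage is Poisson; unconverted counts are binomial. Defaults:
ncr_C = 0.0036, ncr_mC = 0.0118, hmC protection = 0.976.

## Spike-in calibration

Two control contigs ride along with every simulated library: a fully
CpG-methylated lambda fragment and a fully hydroxymethylated pUC19
fragment. Pooled ratios Σ unconverted / Σ total give

* `ncr_c` — lambda non-CpG sites (unmodified-C non-conversion),
* `ncr_mc` — lambda CpG sites (mC non-conversion under TAB),
* `ncr_hmc` — all pUC19 cytosines (hmC protection),
* `protection_normalized` — TAB pUC19 rate / BS pUC19 rate, clipped at 1
  (removes incomplete-conversion effects shared by both assays).

## hmC calling

Each covered cytosine gets an exact binomial upper tail
P(X ≥ k | n, p₀) against the background p₀ = max(ncr_c, ncr_mc)
(residual mC is the dominant TAB error). Benjamini–Hochberg FDR < 0.01
is applied independently within each (chromosome, context CG/CHG/CHH)
stratum. Zero-coverage sites and spike-in contigs are excluded.

## CpG deconvolution and categories

Per strand-CpG covered in both assays: modC from BS, hmC from TAB,
mC = clip(modC − hmC, 0, 1) (sampling noise can push the difference
negative). Categories:

* modC_no: modC < 0.10; modC_low: 0.10 ≤ modC < 0.50;
  modC_high: modC ≥ 0.50.
* Within modC_high: hmC_no when there is no significant hmC call (or
  hmC = 0 in threshold-only mode); otherwise hmC_high when hmC > mC
  (strict; ties go to hmC_low), else hmC_low. mC_high denotes
  hmC_low ∪ hmC_no.

Subclass fractions are reported against all captured CpGs, so the three
hmC subclasses sum to the modC_high fraction. Differential hmC between
samples requires coverage ≥ 10 in both and a frequency difference
≥ 0.3.

## Elements and enrichment

Enhancers are H3K4me1 peaks distal to every TSS (beyond ± 2.5 kb);
distal peaks overlapping an H3K27ac peak are active, the rest poised.
Exclusive element assignment follows the precedence promoter →
enhancer_active → enhancer_poised → exon → intron → intergenic. Fold
enrichment of a CpG category at an element is its observed fraction
there divided by the fraction of all captured CpGs there. Element-level
modification is pooled (read-weighted: Σ unconverted / Σ coverage) by
default. The in-silico MspI digest cuts at C^CGG and retains fragments
of 40–220 bp.

## Splice-site boundary convention

Transcript orientation throughout. At the 5′ splice site the last
exonic base is −1 and the first intronic base (+1) is the G of the
invariant GT; at the 3′ splice site −1 is the G of the invariant AG and
+1 the first exonic base. A CpG "at position p" has its C at p; the −1
CpG spans the boundary (C at −1 pairing the +1 G). 5′ss CpGs are
detected at −2/−1 (exon side) and +4/+5 (intron side) of internal
exons; the exon inherits the four-way class (hmC_high, mC_high,
modC_low, modC_no) of its splice-site CpG after a coverage-weighted
merge of the dyad's two strands.

## Exon inclusion

For every ordered exon pair the junction library joins the last
`arm_len` bases of the upstream exon to the first `arm_len` of the
downstream exon. A read supports a junction when it matches the
junction sequence with ≥ 8 nt on each side, does not match the
unspliced genomic sequence contiguously, and matches only one junction.
For a focal exon A with nearest neighbours C1, C2:

```
inclusion = (ΣCiA + ΣACj) / (ΣCiA + ΣACj + 2 · skip)
```

Two accountings of the shared C1→C2 junction, which appears in both
printed skip sums (ΣCiC2 and ΣC1Cj), are provided: `literal` keeps the
double count exactly as the formula is printed, biasing the estimate
toward ψ/(2 − ψ); `count_once` (default) counts each skip read once,
which matches read-level enumeration and is the unbiased estimator of
the true inclusion fraction. An exon is alternatively spliced when
inclusion < 0.8; comparisons require ≥ 10 supporting reads and an AG
3′ss. Group comparisons use a two-sided Mann–Whitney–Wilcoxon test,
enumerated exactly over the permutation distribution (tie-correct) when
both groups have ≤ 20 members.

The junction-read simulator samples fragments from the mRNA pool:
isoforms are enumerated over the variable exons and each read draws its
isoform with weight abundance × number of valid start positions, so
per-position coverage is proportional to abundance and junction counts
estimate isoform fractions without length bias.

## Strand bias

The sense strand is the strand a gene is transcribed from. Per gene,
CpG counts between TSS and TTS are pooled separately per genomic strand
and mapped to sense/antisense. Bias conventions: hmC bias =
sense − antisense, mC bias = antisense − sense (both positive in
transcribed genes). The default test is a paired two-tailed Student's t
across genes; expression groups are RPKM tertiles/deciles over genes
with RPKM > 0.1. SAS regions are the genomic intersections of expressed
(RPKM ≥ 1) plus-strand and minus-strand gene bodies; within them each
strand is sense for one gene, so the strand bias collapses relative to
non-SAS gene bodies.

## Chromatin profiles

Midpoint profiles slide 50-bp windows in 25-bp steps across ± 5 kb
around interval midpoints; a CpG contributes to every window covering
it. Region profiles rescale each region into 100 equal bins plus
fixed-width flank windows. Window levels are pooled; the hmC/mC ratio
is computed from the pooled window levels and reported missing when the
pooled mC is zero. Category fractions (hmC_high, mC_high, modC_low) are
relative to all CpGs in the window.

## Simulation design

The toy genome interleaves gene clusters with intergenic blocks hosting
enhancer peaks (H3K4me1 ± H3K27ac, placed beyond the TSS ± 2.5 kb
distal filter, including deliberately TSS-proximal decoy peaks) and one
repressive H3K9me3-like domain per chromosome. The truth methylome
starts from uniform (base_hmc, base_mc), then applies CpG-island
hypomethylation at a subset of promoters, sense-strand gene-body hmC
excess scaled with the gene's expression group, the splice-site CpG
delta at −2/−1/+4/+5 of internal exons, enhancer and repressive hmC
deltas, and the spike-in truths (lambda CpG f_mC = 1; pUC19 f_hmC = 1).
All signals are additive with clipping so that f_hmC + f_mC ≤ 1.
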