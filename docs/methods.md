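# Methods

## Scientific setting

Acetaldehyde (AA), the first metabolite of ethanol, damages guanine bases.
In a *cdc13-1* telomere-uncapping reporter strain of *Saccharomyces
cerevisiae*, shifting to the non-permissive temperature triggers 5'→3'
resection from chromosome ends, exposing ~30 kb single-stranded DNA (ssDNA)
tracts.  Lesions accrued in these tracts escape excision repair and are
fixed as mutations during second-strand resynthesis, concentrating the
mutagen's intrinsic signature in a known genomic window with a known strand
geometry: the bottom strand is exposed on left chromosome arms and the top
strand on right arms, so a guanine-specific mutagen produces C→A changes
(top-strand notation) on left arms and G→T changes on right arms.

This package implements the downstream computational analysis of such an
experiment: building substitution catalogs from VCF calls, classifying
mutations by telomere distance and resected-strand consistency, quantifying
motif enrichment with the TriMS statistic, visualizing flanking-base
preferences as binomial logos, and screening independent cohorts (e.g.
tumor catalogs) for the same signature, including transcriptional strand
bias and CC→AA doublet correlation.

## Catalog construction

Input VCFs are filtered to biallelic single-base substitutions with variant
allele fraction (VAF) ≥ 0.9 by default, reflecting clonally fixed reporter
mutations; records without a VAF annotation fail loudly when a threshold is
requested, because silently keeping sub-clonal calls would corrupt every
downstream count.  Matched-normal subtraction removes exact
(chrom, pos, alt) triples seen in the untreated parent, and cross-isolate
de-duplication removes variants recurring in ≥ 2 sibling isolates
(configurable), treating them as inherited rather than induced.  All
analyses work in pyrimidine orientation: a substitution with a purine
reference base is re-expressed as its reverse complement, with the strand
recorded, so C→A and G→T form one event class.  Records at chromosome
termini, or with N in the ±1 context, are excluded from context-dependent
statistics and tallied.

## The TriMS statistic

For a motif such as gCn→gAn (a C→A change with a 5' guanine; equivalently
nGc→nTc on the opposite strand), four counts are assembled:

* m_motif — substitutions matching the motif (both strands),
* m_total — substitutions of the base change regardless of flanks,
* c_motif — motif context occurrences in ±20 nt windows centered on each
  counted mutation,
* c_base — occurrences of the mutated base in the same windows,

and the fold enrichment is

    E = (m_motif × c_base) / (m_total × c_motif).

Windows include the mutated position, truncate at chromosome ends, and are
counted per-window without merging when they overlap.  A motif occurrence is
counted when its central base lies inside the window; its flanks are read
from the genome and may extend past the window edge but never past the
chromosome.  Significance uses a one-sided (greater) Fisher's exact test on
[[m_motif, m_total − m_motif], [c_motif, c_base − c_motif]], exact
hypergeometric tail, with Benjamini–Hochberg (default) or Bonferroni
adjustment across the sample family.  The mutation load attributes the
excess over baseline to the motif process:

    load = m_motif × (E − 1) / E,   gated on E > 1 and corrected p ≤ α.

Cohort screening flags a sample when E ≥ 1 (inclusive, unlike the strict
gate in the load formula — both thresholds are explicit parameters) at
corrected p ≤ 0.05, and reports flagged/total plus the mean load among
flagged samples.

### Finite-window expectation

Because context windows are centered *on mutations* and include the mutated
position, the window composition is not genome-representative at the
center: a motif mutation guarantees a motif context there, and — for a
dinucleotide-defined motif like gC — also at its reverse-complement partner
one base away.  Consequently the estimator's large-sample limit is below
the naive φ·f_base/f_motif (φ = fraction of mutations at motif sites,
f_· = genome-wide frequencies); on an i.i.d. GC = 0.38 genome the maximum
attainable pooled estimate at φ = 1 is ≈ 3.5.  The package therefore ships
two oracles: `expected_enrichment` (the asymptotic ratio φ·f_base/f_motif)
and `planted_enrichment_expectation`, which averages realized window
motif/base counts over the exact placement strata — (region, arm, strand,
motif-ness) pools on the realized genome — and returns the value the pooled
estimator converges to.  Parameter-recovery tests compare against the
latter; `motif_fraction_for_enrichment` numerically inverts it.  This bias
is a property of the windowed estimator itself, not of the simulation, and
is shared by any analysis using the same window convention.

## Telomere geometry and strand consistency

Telomere distance is min(pos − 1, L − pos); positions within 30 000 bp of
either end (inclusive) are sub-telomeric.  Arms are assigned by the nearer
end, ties (exact midpoint) to the left arm — a measure-zero convention.  A
mutation is ssDNA-consistent when the purine partner of its
pyrimidine-normalized change lies on the arm's resected strand: on a left
arm the pyrimidine must sit on the top strand, on a right arm on the
bottom.  Mutation density is reported per isolate (primary) and per mutable
base (reference C plus G positions in the region, secondary).

## Flanking-base logos

For offsets −2..+2 (excluding 0) around the mutated base, in pyrimidine
orientation, the height of base b at offset o is the exact binomial tail
log-probability of the foreground count k out of n given the background
frequency q: −log10 P(X ≥ k) when k/n ≥ q (over-representation, the
boundary counted as over), +log10 P(X ≤ k) otherwise.  The default
background is the flank composition of mutations of the same reference base
with any other alternate allele; genome composition is available as an
option.  Background frequencies carry a 0.5 pseudocount per (offset, base)
so q stays inside (0,1).  The significance line is −log10(α / (4 × number
of offsets)), α = 0.05.  Two caveats: the statistic conditions on the
background as fixed, so with a small estimated background (tens to a few
hundred mutations) it is anti-conservative — the result carries a
`low_background` flag below 10 background mutations, and calibration is
exact only for a known background such as genome composition; and heights
are comparable to the original web-tool output directionally, not
numerically, since that tool's exact background normalization is not
recoverable.

## Transcriptional strand bias, doublets, correlation

Within genes of a single unambiguous strand, the damaged purine of a
motif-matching mutation is assigned to the coding (non-transcribed) strand
when it lies on the gene's strand, else to the template (transcribed)
strand; intergenic mutations and overlaps of opposite-strand genes are
excluded.  The 50:50 null is tested by chi-square goodness of fit (df 1)
when both expected counts are ≥ 5, else by the exact two-sided binomial
test; the plain (non-Yates) chi-square is used, which agrees with the exact
test closely in absolute p at moderate counts and within ~10% relatively
only at large counts.  By default only motif-matching mutations enter the
counts (a parameter, since an all-G→T variant is equally defensible).

CC→AA doublets are adjacent same-sample SNV pairs whose top-strand
dinucleotides match CC→AA or GG→TT; each pair is emitted once and its
constituents are marked so combined reports do not double-count them as two
independent substitutions.  DBS counts and motif loads across samples are
related by ordinary least squares with Pearson's r, a t-distribution
p-value (n − 2 df), and a 95% slope confidence interval.

## Synthetic data

The generator emulates the reporter experiment's statistical structure, not
its biochemistry.  Genomes are i.i.d. bases at a configurable GC fraction
(default 0.38, yeast-like) over 8 chromosomes × 200 kb — scaled down from a
real genome; no dinucleotide correlation, repeats, or composition gradients
are modeled.  Per isolate, a Poisson number of substitutions (default mean
17, matching ~500 mutations over ~30 isolates) is placed by drawing, per
mutation: region (sub-telomeric with probability 0.9, reflecting the
observed ~90% telomere-proximal clustering), arm (uniform), strand (purine
on the arm's resected strand with probability 0.9 for sub-telomeric draws,
uniform mid-chromosome), and motif-ness (probability φ, default 0.8), then
sampling uniformly among unused eligible sites of that class.  VAF is 1.0
for all records (clonally fixed reporter mutations).  Gene annotations are
non-overlapping random-strand intervals; when a non-transcribed fraction β
is set, genic motif mutations are re-stranded within their gene so a
fraction β carry the purine on the coding strand.  CC→AA / GG→TT doublets
are added at an expected `dbs_rate` per isolate; the default is 0 because
the yeast data showed too few doublets to analyze — doublet-bearing cohort
scenarios (as in the DBS–load correlation) set it explicitly.  Everything
derives from one integer seed; identical (config, seed) pairs give
byte-identical FASTA/VCF/BED output.

What passing recovery tests show: the estimators correctly invert the
generative model under ideal conditions (uniform placement within strata,
exact reference match, no sequencing error).  They do not show robustness
to alignment artifacts, sub-clonal contamination, germline leakage, or
compositional heterogeneity of real genomes.

## Numerical and design choices

* Fisher table orientation and "greater" alternative are fixed as above so
  p-values are bit-reproducible; degenerate tables (any zero margin) return
  p = 1 and loads 0.
* Enrichment with a zero denominator but non-zero numerator is reported as
  missing (None/NaN), never as 0; m_motif = 0 gives E = 0.
* The corrected-significance gate in the load uses p ≤ α; α = 0.05
  throughout, exposed as a parameter.
* The sub-telomeric boundary is inclusive at exactly 30 000 bp.
* p-value adjustment is delegated to statsmodels (Bonferroni / BH step-up),
  order-preserving with the input.
* Binomial logo tails use scipy's log-survival/log-CDF directly in log
  space; no normal approximation anywhere.
* The acceptance script scales cohorts to 20 isolates × 500 mutations
  (recovery), 100 × 50 (null screening), 10 × 200 (strand bias), 15
  heterogeneous samples (correlation) — sizes chosen to make the planted
  parameters recoverable with comfortable sampling error on a desk-scale
  genome.

## Known limitations

* The i.i.d. genome makes motif-context frequencies nearly uniform along
  chromosomes; real sub-telomeres are compositionally atypical, so absolute
  enrichment values on real data are not directly comparable.
* Per-window context counting double-counts shared context in mutation
  clusters (deliberately, matching the established convention); extremely
  clustered catalogs inflate context totals relative to a merged-window
  convention.
* The estimated-background logo is anti-conservative for small backgrounds
  (see above).
* Strand-bias testing assumes a 50:50 null with no correction for base
  composition differences between strands of real genes.
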