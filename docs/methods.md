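# Methods

This note records the models, conventions and numerical choices behind
`teacr`, in the spirit of the methods documentation of the established
genomics toolkits.

## Coordinates and formats

All internal coordinates are 0-based half-open; GFF3 and CGmap (1-based)
are converted on ingest, BED-family formats pass through unchanged. Genes
must be stranded (promoter/downstream windows depend on orientation);
peaks and TEs may be unstranded. narrowPeak column 10 supplies the peak
summit offset; an absent summit (−1) falls back to the interval midpoint,
so every peak has a profiling anchor. VCF parsing keeps biallelic SNPs
only; multi-allelic records are skipped with a logged count, and
half-missing diploid genotypes (`./1`) are treated as fully missing —
a conservative choice for diversity estimation.

## TE overlap classification

A peak is TE-derived iff the union of TE spans covers **strictly more
than 50%** of its length, so a peak exactly half covered is *not*
TE-derived. Overlapping TE annotations are never double-counted (union
coverage). For class roll-up (DNA vs retrotransposon) the class with more
covered bp wins; ties go to the DNA class, since DNA transposons dominate
peak overlap in TE-rich cereal genomes and the published summaries report
disjoint class percentages without stating a rule. A summit covered by
nested TEs is attributed once, to the innermost (shortest) element.
Nearest-TE distances are edge-to-edge gaps (0 on ≥1 bp overlap) binned as
0 / 1–170 / 171–500 / 501–1000 / >1000 bp.

## Positional classification

Promoter windows are `[TSS−2000, TSS)` and downstream windows
`(TTS, TTS+2000]` in the gene's orientation; any ≥1 bp overlap counts.
Precedence for peaks touching several windows is
pACR > gACR > dnACR > dACR: gene-body overlap beats the downstream flank
because it is the more specific location, and the distal class is
definitionally exclusive (reserved for peaks more than 2 kb from every
gene body, measured edge-to-edge to the body, not the extended span).
One boundary case needs a rule of its own: a peak whose nearest gene edge
sits at exactly 2000 bp overlaps no half-open flank window yet is not
"more than 2 kb" away; it is assigned the flank class of the nearest gene
side. Classification uses any-overlap rather than summit position; the
summit-based variant would only reassign peaks that straddle window
borders.

Accessibility tertiles split peaks at the empirical 1/3 and 2/3 RPKM
quantiles with sizes differing by at most one; boundary ties break by
peak id so the split is deterministic, and the labels are invariant under
any strictly monotone transform of the values.

## Tissue specificity

Counts are normalized to RPM with per-tissue mapped-read totals (the
down-sampled totals when equal-depth down-sampling is applied; the
down-sampler draws a multivariate hypergeometric subsample, preserving
the total exactly and never inflating a zero). Shannon entropy is
computed on the row-normalized RPM shares with 0·log 0 = 0; rows with
zero total are excluded before ranking, so the 15% rule counts only
quantifiable peaks and flags exactly ⌊0.15·N⌋ of them. Entropy ties break
by higher maximal RPM (the more sharply accessible peak ranks as more
specific), then by id. RPM rows are not quantile-normalized before
entropy; that switch is deliberately left out of the default path.
Fold change uses (max + ε)/(mean of others + ε) with ε = 0.01 to keep
zero-background rows finite. Superfamily enrichment is the upper-tail
hypergeometric P(X ≥ k) with the genome-wide TE catalogue as population;
BH q-values are reported alongside raw p.

## Methylation

Region levels are read-weighted (Σ methylated / Σ total over in-region
sites of the context) rather than means of per-site ratios — the bulk
convention, stated here because the two differ at uneven coverage. Sites
with fewer than 5 reads are removed first. Symmetric CG sites are not
collapsed across strands; CGmap rows are used as-is. A region with no
covered site of a context reports NaN, never 0. Metaprofiles over TE
bodies use per-site ratio tracks (NaN where no site) so that unscored
positions are skipped, not counted as unmethylated.

## Diversity and sweeps

Per-site π is the proportion of differing haplotype pairs,
2k(n−k)/(n(n−1)), with n the non-missing haplotypes at that site
(pairwise-complete). Windows tile each chromosome from position 0 without
overlap; the window denominator is the full span (invariant sites
contribute zero), matching the convention of the standard windowed-π
tools, and the terminal truncated window uses its actual span. Sweep
eligibility requires cultivated π > 0 and at least one variant per panel
per window; with fewer than 20 eligible windows the scan refuses to run
(the 95th percentile would be unstable). The threshold is the k-th
largest ratio with k = ⌊0.05·n⌋, windows at or above it are flagged, and
adjacent flagged windows merge into sweep regions. The printed ratio
cutoff is always data-derived.

## NG86 Ka/Ks

Per-codon synonymous site fractions count, at each position, the share of
the three single-nucleotide changes that preserve the amino acid; changes
creating a stop codon count as nonsynonymous, and S + N = 3 × codons per
sequence. Site totals are averaged over the two sequences. Differences
between codons are classified by averaging over all minimal substitution
pathways; pathways passing through a stop codon are excluded unless every
pathway is blocked. Proportions are corrected with Jukes–Cantor,
d = −(3/4)·ln(1 − 4p/3), undefined at p ≥ 3/4 (saturation); ω = Ka/Ks is
undefined when Ks is 0 or undefined. The estimator is deliberately the
fully specifiable NG86 rather than a γ- or ML-corrected variant, so its
difference counting can be pinned to an exhaustive pathway-enumeration
oracle in the tests. The significance filter uses a two-sided Fisher
exact test on the 2×2 table of (synonymous, nonsynonymous) differences vs
remaining sites, rounded to integers (NG86 counts are fractional; at very
small S the rounded remainder is clamped at zero). Pairs with Ks > 5.0
(saturated synonymous sites) or p > 0.05 are excluded from downstream
comparisons; both cutoffs are inclusive on the retained side. Raw CDS
input is codon-aligned by exact Needleman–Wunsch protein alignment
(BLOSUM62, affine gaps, open −10 / extend −0.5) with codons back-threaded
and gapped columns dropped; the Ka/Ks core itself requires pre-aligned
input.

Duplicate-pair subgroups are defined by the joint TSS ±500 bp
accessibility status (the window is closed at exactly 500 bp): both
copies TE-derived (1); one TE-derived, the other a regular peak (2); one
TE-derived, the other without any peak (3); pairs with no TE-derived copy
stay unassigned. A TE-derived peak in the window dominates a co-occurring
regular one. Duplicate origin modes (WGD/tandem/proximal/transposed/
dispersed) are consumed as input labels; detecting them is out of scope.

## Synthetic data generator

The generator emulates the structural features the analysis assumes, at
desk scale. Defaults and rationale:

* **Genome**: 4 chromosomes × 1.5 Mb of i.i.d. sequence at 44% GC —
  large enough for 60 non-overlapping 100-kb windows (so a top-5% sweep
  scan is meaningful) while keeping a full run near ten seconds.
* **Features**: 600 genes (1–3 kb, slot-placed with ≥1 kb gaps), 1200 TEs
  from ten superfamilies with copy-number weights and length ranges that
  make DNA transposons numerous and short and LTR retrotransposons long
  (≈40% genome coverage, rice-like), 1000 peaks of 200–600 bp.
* **TE-derived peaks**: 8% of peaks (the fraction reported for rice),
  placed with coverage drawn from (0.55, 1.0] so the strict >50% boundary
  is exercised; regular peaks are kept below 45% coverage, one clear step
  under the threshold. Six tissues (young leaf, flag leaf, root,
  stamen & pistil, lemma & palea, young panicle).
* **Counts**: negative binomial (dispersion 10); common peaks mean 60 in
  every tissue, tissue-specific peaks (15% of the catalogue) mean 240 in
  their tissue and 6 elsewhere; TE-derived peaks are damped by 0.7,
  encoding their lower accessibility. Mapped totals are 5× the in-peak
  sum, standing in for reads outside peaks.
* **Methylation**: CGmap sites are sampled at 5% of cytosines (uniform
  thinning leaves read-weighted region levels unbiased while keeping the
  file desk-scale), sequence-derived contexts, depth Poisson(10),
  per-context means 0.80/0.60/0.15 (TE bodies), 0.05/0.03/0.02 (peaks,
  also inside TEs — the embedded-hypomethylation structure) and
  0.40/0.20/0.05 (background), typical of a methylation-dense cereal
  genome.
* **Panels**: wild = 5 diploids (the five wild accessions the study
  design rests on), cultivated = 10 diploids; SNPs at 0.004/bp with
  allele frequencies uniform on (0.05, 0.95), giving per-bp π ≈ 0.0015.
  Inside the 3 designated sweep windows the cultivated variant density is
  thinned by the configured fold (default 10), which reduces expected π
  by exactly that factor; with the fold set to 1 the two panels are
  statistically indistinguishable window-by-window.
* **CDS pairs**: 60 pairs of 400 codons; substitution targets are
  *events*: Ks·S synonymous and ω·Ks·N nonsynonymous single-nucleotide
  changes (Ks uniform on 0.05–1.0, ω on 0.1–0.5) applied sequentially,
  each classified in its current codon context and never creating a stop.
  Truth rates are events per site, the quantity the JC-corrected NG86
  estimate recovers. Subgroup designations follow the published
  29:532:509 mix, scaled to the pair count; TSS peaks (and, for
  TE-derived ones, a dedicated host TE) are placed by construction, and
  expression/accessibility divergence is drawn correlated
  (Δaccess = 0.6·Δexpr + noise) so the rank-sum association is real.

One global seed drives per-component child generators at fixed offsets;
identical seeds give byte-identical bundles. Ground truth (TE coverage,
positional class, specific tissue, sweep windows, applied substitution
counts, divergence draws) is written alongside the data.

What the generator does **not** emulate: read-level noise and mapping
artefacts, realistic TE sequence models (TEs are coordinate annotations
over random sequence), linkage disequilibrium and realistic site
frequency spectra, indels in CDS evolution, and chromatin-state spatial
autocorrelation beyond the designed peak/TE structure. Passing recovery
tests therefore demonstrates the correctness of the statistical
machinery under the stated generative assumptions, not robustness to the
full noise structure of real sequencing data.

## Problem sizes in the test and acceptance runs

The shared test bundle uses the default configuration above; structural
and determinism tests run a 2 × 300 kb configuration, and the
neutral-panel comparison a 2 × 10 Mb configuration (200 windows) with all
other components minimized. These sizes were chosen so the whole suite
and the acceptance script each finish in well under a minute on one CPU
while every recovery check retains comfortable statistical margin.

## Known limitations

* NG86 with equal-weight pathway averaging underestimates rates at high
  divergence; the saturation filter (Ks ≤ 5) bounds the damage but the
  estimator is not intended for deep paralogs.
* The entropy caller's 15% rule fixes the *number* of calls, not an
  error rate; with fewer truly specific peaks than 15% the tail of calls
  is necessarily noise.
* The sweep scan's top-5% rule likewise flags a fixed share of windows;
  under neutrality those flags are false positives by construction.
* Distance binning and window conventions follow the published analysis;
  alternative conventions (callable-bp denominators, sliding windows)
  exist behind flags or are documented as deliberate non-defaults.
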