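# Methods

## Coordinate model and functional-effect calling

All positions are 1-based against a circular mitochondrial reference;
variants are substitutions `m.POS REF>ALT` (indels are out of scope). The
locus map types every interval as CDS, tRNA, rRNA or regulatory; the control
region spans the circular origin and is modelled with an explicit
wraps-origin flag (`start > end`) rather than negative coordinates. When
annotations overlap (e.g. MT-ATP8/MT-ATP6), the primary annotation is chosen
deterministically — locus-type priority CDS > tRNA > rRNA > regulatory, then
lower start coordinate — and all containing loci remain available as
secondary contexts via `LocusMap.all_loci_at`.

CDS effects are called by translating the affected codon before and after
the change under the vertebrate mitochondrial genetic code (NCBI table 2,
via Biopython): synonymous, non-synonymous, stop-gain or stop-loss.
Minus-strand genes are read in reverse complement from their reading-frame
origin (the highest genomic coordinate of the frame). A codon extending past
the annotated gene end is padded with `A`, modelling the poly-A completion
of the incomplete stop codons typical of mitochondrial transcripts.
Non-coding loci return their locus type as the functional class. BED input
is converted to 1-based inclusive coordinates exactly once at the boundary;
VCF output converts back symmetrically.

## Enumeration

Every site contributes its three non-reference alleles, so exhaustive
enumeration of an L-base genome yields exactly 3L substitutions (49,707 for
L = 16,569), intergenic positions included. Sites whose reference base is
`N` still contribute three alleles so the 3L arithmetic is preserved; the
bundled references contain none. Disease scores attach only where the
scoring schemes apply (non-synonymous CDS and tRNA variants); synonymous,
rRNA, regulatory and intergenic entries are enumerated as annotation-only
records. A variant is *observed* when its cohort allele frequency exceeds
zero, *potential* otherwise; absent variants have frequency 0 by definition.

## Allele frequencies and site variability

Cohort genomes are haploid consensus sequences, so an allele frequency is a
fraction of genomes: carriers of the alternative allele over genomes with a
called base (A/C/G/T) at the position, within the requested stratum (all,
healthy, pathologic). Gap and ambiguous symbols leave both numerator and
denominator. An empty denominator raises rather than returning a spurious
zero. With full call coverage the stratum frequencies recombine exactly:
`N_total·af_total = N_healthy·af_healthy + N_pathologic·af_pathologic`.

Site variability is a pluggable column statistic. The default is normalized
Shannon entropy — `H(column)/log k` with k = 4 for nucleotide columns and
k = 21 (20 amino acids + stop) for translated residue columns — which is 0
for monomorphic sites, 1 for equiprobable columns, bounded in [0, 1], and
invariant under allele relabelling. This is a deliberately simple,
well-characterized statistic exposing the same contract as the dedicated
site-variability estimators used in large mtDNA databases; a different
formulation can be passed as the `statistic` argument without touching the
callers. Residue columns drop genomes whose codon is not fully called and
require at least two remaining observations.

## tRNA disease score

Nine boolean criteria in fixed order — multiple pathogenic reports,
PhastCons conservation, PhyloP conservation, heteroplasmy evidence, disease
segregation, histochemical evidence, OXPHOS biochemical defect,
cybrid/steady-state evidence, single-fiber segregation — carry raw weights
(2, 1, 1, 2, 2, 2, 2, 5, 3). The normalized weights are computed as
raw/sum(raw) rather than stored, so an alternative raw weighting (a config
option) stays automatically consistent; with the defaults they are
0.1, 0.05, 0.05, 0.1, 0.1, 0.1, 0.1, 0.25, 0.15. DS is the sum over
satisfied criteria, hence confined to the 512 subset sums of those weights,
with extremes 0 and 1.

Each criterion is tri-state: satisfied, not satisfied, or unknown. Unknown
criteria contribute nothing, making DS a monotone lower bound under
incomplete evidence. The VUS flag is driven purely by the *availability* of
functional-study evidence: a variant with no functional study in the
literature is VUS even when conservation criteria alone give DS > 0, and a
fully investigated variant with all-negative results is not VUS (it
classifies through the thresholds with DS = 0). When evidence is
unavailable the five functional-study criteria must remain unknown, a
constraint enforced at profile construction and in the evidence-table
format (cells are `yes`/`no`/`unknown` with strict header validation).
Additional tRNA attributes sometimes proposed for future scoring
(cloverleaf disruption, post-transcriptional modification sites, 3D folding
contacts, frequency-ratio rules, macrohaplogroup markers) are carried as
annotations only and never enter the score.

## Non-synonymous disease score

The non-synonymous DS is a consensus over external predictor probabilities.
The default aggregation is the weighted mean with weights renormalized over
the non-missing predictors (uniform weights unless configured); it is
bounded by the minimum and maximum available probability and invariant
under splitting a predictor's weight across duplicates. An all-missing
panel leaves DS unassigned, and the variant Unclassified.

This is the package's single largest fidelity gap: the published consensus
schemes in this area have specific predictor sets and weightings (sometimes
including a site-variability term) that are not reproduced here. The panel
composition and weights are therefore exposed in `PredictorPanel` so a
specific published scheme can be configured; results obtained with the
uniform-mean default should be reported as such.

## Thresholds and tiers

Classification uses the threshold pairs DS_T/AF_T given in the README,
shipped as frozen defaults in `ThresholdConfig` so tier assignment is
reproducible without access to any genome corpus. Both comparisons are
inclusive on the pathogenic side (DS ≥ DS_T, AF ≤ AF_T), including at the
exact boundary, and the same inclusive filter is used when selecting
high-scoring variants for AF_T re-estimation. `estimate_af_threshold`
implements the empirical-quantile estimator with the inverted-CDF
convention (the smallest observed value whose empirical CDF reaches the
quantile); the quantile defaults to 0.95 and is a config parameter, since
the convention behind the shipped constants is not recoverable. The four
quadrants partition the unit square, so every scored, non-VUS variant
receives exactly one tier, and assignment is monotone in DS. Potential
variants (AF = 0) with DS ≥ DS_T are always Pathogenic, never Likely
Pathogenic.

## Summaries

Percentages are computed from integer counts with decimal half-up rounding
(never banker's rounding) at one decimal by default; the rendered string
drops a zero decimal (7.0 → `7%`), and a whole-percent rendering
(`decimals=0`) is available where integer reporting is conventional
(9/70 → `13%`). The tier breakdown additionally reports, among
Pathogenic-tier variants, the fraction never observed in healthy genomes
(af_healthy = 0), or N/A when no variant is Pathogenic or strata are
missing. Summaries are permutation-invariant and idempotent under
re-summarization of their own counts.

## Synthetic studies

The generator emulates the production inputs: an aligned cohort of complete
genomes stratified healthy/pathologic, a tRNA criterion table and a
predictor table. Defaults: a 600 bp toy genome with one regulatory (1–60),
one tRNA (61–130), one rRNA (131–260) and one CDS locus (300–560, an ATG…
TAA open reading frame of sense codons), plus intergenic spacers, so all
annotation regimes are exercised; 400 healthy and 100 pathologic genomes, a
healthy-majority composition mirroring real mtDNA corpora at desk scale.
Target allele frequencies are realized exactly as round(AF × N) carriers per
stratum, drawn without replacement with the spec seed, so the expected tier
of each planted variant is deterministic arithmetic recorded in a truth
table; changing the seed moves carriers between genomes but cannot change
the truth table. The truth tier is computed by inline threshold comparisons,
independent of the tier-assignment module it is later checked against. The
default 22-variant scenario covers all four quadrant tiers for both scored
kinds (including exact DS = DS_T boundaries), VUS with and without evidence
rows, an unassigned-DS non-synonymous variant, and the stop-gain and
synonymous withheld classes.

What the generator does not emulate: phylogenetic (haplogroup) structure,
recurrent mutation, heteroplasmy fractions, sequencing error and missing
data patterns of real consensus genomes. Passing end-to-end tests therefore
demonstrate correctness of the bookkeeping and decision rules under clean
inputs, not robustness to real-data artefacts. Likewise, database-scale
tier counts depend on the underlying genome corpus and literature evidence
and are not reproducible from synthetic data.

## Bundled reference data

The package bundles the standard 38-interval human mitochondrial locus
table (13 CDS, 22 tRNA, 2 rRNA genes and the origin-spanning control
region, NC_012920.1 coordinates). The full-length reference sequence is a
deterministic synthetic sequence of the correct length (16,569 bp), clearly
labelled synthetic: every quantity used from it depends only on length and
the locus map (catalogue size 3L = 49,707, per-locus-type partitions), not
on base identities. Analyses that need real rCRS bases should load the real
FASTA via `ReferenceModel.from_fasta`.

## Numerical and interchange conventions

Normalized weights sum to 1 within 1e-12; degenerate (all-zero) weights are
an error rather than a silent fallback. VCF output declares every `HV_*`
INFO key with type and description, writes explicit zeros for AF = 0
potential variants, and encodes spaced tier labels with underscores (VCF
INFO values cannot contain whitespace); readers restore the canonical
labels. JSON variant cards serialize absent values as explicit nulls (never
NaN) and keep a fixed block layout (variant, main info, variability,
pathogenicity, provenance), with the pathogenicity block null for
annotation-only records. Problem sizes in the test suite (600 bp toy
genome, 500-genome cohorts, one full-length enumeration) keep the entire
suite in a few seconds on one CPU.
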