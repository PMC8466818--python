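# Methods

`cansynth` implements the analytical machinery used to characterize the
cannabinoid synthase gene family of *Cannabis sativa* — THCAS, CBDAS and
CBCAS, near-identical single-exon paralogs (roughly 84–96% pairwise identity
between classes, >99% within a class) — together with seeded synthetic-data
generators that stand in for plant material and cloned sequences.  This note
records the models, the defaults and why, the numerical choices, and what the
synthetic data does and does not show.

## Sequence model and coordinates

All cds-relative coordinates are 1-based and end-inclusive, counted from the A
of the start codon; a substitution "at position 13" sits in codon 5.  A cds is
*complete* when it starts with ATG, ends with an in-frame stop, has length
divisible by 3 and no internal stop; an internal stop or a frameshift-length
marks a *pseudogene*; a missing start or terminal stop marks a *fragment*.
Ambiguity codes are tolerated in the body (translated to `X` with a warning)
but rejected inside the first or last codon, where start/stop identity cannot
be established.  ORF scanning reports, per reading frame and strand, the
maximal ORF for each stop codon (first ATG after the previous in-frame stop);
minus-strand ORFs are mirrored into plus-strand coordinates.

## Variant annotation

Equal-length sequences are compared positionally — the synthase cds are
co-linear amplicons of one family, so no alignment is needed and the SNP list
is exact.  Unequal lengths go through a global pairwise alignment (match +1,
mismatch −1, gap −2, end gaps penalized); indel columns are counted separately
and excluded from the SNP list, because the family's reported SNP counts are
substitution-only.  Percent identity is rounded half-up to two decimals, the
precision at which such identities are conventionally printed (99.94, 99.82,
…).  Substitution effects are classified by mutating the affected codon and
translating both versions; the codon index is `floor((pos−1)/3)+1`.  Note that
applying this standard arithmetic, a substitution at nucleotide 986 falls in
codon 329; literature occasionally numbers the same event 328, which suggests
a different residue-numbering convention — the package uses the standard
formula and does not special-case.

The critical-residue check covers the catalytically required stretch
Arg110–His114 plus Cys176 (Met of the start codon is residue 1): 110, 114 and
176 have fixed expectations (R, H, C); 111–113 are compared against the
supplied reference protein.

## Clade typing

Diagnostic positions are defined strictly: a position qualifies when every
sequence of one clade carries one allele and every sequence of the other clade
a different allele (a minor-allele tolerance knob exists, default 0; ambiguity
codes never count as a fixed allele).  Classification assigns a query to a
clade iff *all* diagnostic alleles match exactly and identity to the clade
reference is at least the threshold, default 97.0% — chosen because observed
CBCAS-vs-THCAS identities span roughly 95.7–96.0% while within-clade
identities exceed 99.5%, so 97% cleanly separates the two regimes.  Ties break
by highest identity, then registration order (logged).

The default diagnostic set — positions 13, 18 and 1628 with alleles A/C/G for
CBCAS versus G/T/A for THCAS — is read directly off the published full-cds
primer sequences, whose footprints cover cds 1–18 (forward) and 1628–1638
(reverse-complement), i.e. the primers discriminate the classes at exactly
these positions through their 3′ ends.

## In-silico PCR

Wet-lab primer specificity is replaced by the standard dry-lab proxy: a primer
binds where it has at most 2 total mismatches and a perfect 3′-terminal clamp
of 3 bases (both knobs exposed).  IUPAC codes in the template match any
compatible base.  Products form between a forward-priming site and a
downstream reverse-priming site on the opposite strand; length runs from 5′
footprint end to 5′ footprint end inclusive, which makes a full-cds amplicon
with primers on start and stop exactly the cds length.  The B-locus marker
reads multiplex band sizes with ±5 bp tolerance, treating 1080 and 1081 bp as
one band class (both figures appear in print for the same band): 1192 bp marks
a functional THCAS (B_T), 1080/1081 bp a functional CBDAS (B_D);
B_T/B_T ⇒ chemotype I, B_T/B_D ⇒ II, B_D/B_D ⇒ III/IV/V indistinctly.
The specificity validator passes a pair iff it predicts at least one product
on every positive template and none on any negative; the melting-curve step of
the wet protocol is represented only by a report-only Tm note (Wallace rule
below 14 nt, `64.9 + 41(GC−16.4)/N` otherwise) — never a filter.

## Phylogenetics

Pairwise distances use pairwise deletion (columns with a gap or ambiguity in
either member of the pair are dropped for that pair) under p-distance, JC69 or
TN93; TN93 uses the empirical base frequencies of each pair's retained sites
and is the default.  TN93 stands in for the Maximum Composite Likelihood
distance of desktop phylogenetics suites: the published 202-taxon tree (branch
length sum 0.49420587, 1906 positions) depends on repository sequences this
package deliberately does not download, so the requirement here is algorithmic
soundness at desk scale, not replication of that figure.  Codon-position
filtering is not implemented; all positions are used.

Neighbor joining follows Saitou–Nei with the standard Q criterion,
deterministic tie-breaking by the lowest index pair, and negative branch
estimates clamped to zero (counted and logged).  NJ is exact on additive
matrices — the suite verifies path-length recovery below 1e−9 over 100 random
6-taxon additive matrices, and cross-checks topology-free path distances
against an independent NJ implementation.

Bootstrap resamples alignment columns with replacement, rebuilds the NJ tree
per replicate and scores each internal edge of the base tree by the fraction
of replicates containing its bipartition; edges below the collapse threshold
(default 50%) become polytomies.  Zero-length internal edges are treated as
unresolved and collapsed outright rather than scored: with all-identical
sequences every replicate would otherwise "resolve" the same arbitrary
tie-broken topology at 100% support, which would be support for nothing — the
chosen rule returns the star tree instead and leaves separated data
untouched.  Newick output carries branch lengths at 6 significant digits and
supports as internal node labels, and round-trips through the bundled parser.

## qPCR quantification

Standard curves are ordinary least squares of Cq on log10(quantity) over a
dilution series (the emulated design: 5 points of 1:4 dilutions);
amplification efficiency is `E = 10^(−1/slope) − 1`, so the canonical slope
−3.3219 gives E = 1.000.  Technical replicates are averaged on the Cq scale
before interpolation (quantities are exponential in Cq, and averaging before
the transform matches how instruments report replicate Cq).  Per biological
replicate, the target quantity is normalized to the geometric mean of the
reference-gene quantities; the genotype-level RQ is the mean over biological
replicates with SEM = SD/√n computed over biological replicates only.  A
genotype×gene with all Cq undetermined is reported "n.d." and excluded from
testing; a replicate whose reference is undetected is dropped with a warning.

Reference-gene stability replaces the four-tool RefFinder web consensus with a
fully specified two-score scheme: a geNorm-style M value (mean over partner
genes of the SD of the pairwise log2 expression ratio) and a comparative
ΔCt score (mean over partners of the SD of the raw Cq difference), combined by
the geometric mean of the two ranks; ties break by ΔCt SD, then name.  Both
scores are pairwise, which bounds their resolving power: distinguishing noise
SDs of 0.05 and 0.2 cycles next to a 0.8-cycle partner is dominated by the
shared partner variance — the sampling variance of the variance difference is
`2(σ₁⁴ + σ₂⁴ − 2σ₁₂²)/(n−1)`, which requires on the order of 200 samples for
95% correct ordering.  The recovery test therefore runs on an 80-genotype ×
3-replicate screening panel; at the study's own scale (13 genotypes) only
clearly separated candidates are reliably ordered, which is worth knowing
before trusting any pairwise stability ranking on a small panel.

Group comparisons are two-sided pooled-variance Student's t-tests on
natural-log-transformed per-replicate RQ versus a baseline genotype, starred
at p < 0.05 / 0.01 / 0.001.

## Synthetic data

The family generator draws a random ancestor cds (default 1638 nt = 545
codons + stop, the THCAS/CBCAS length implied by a 1635-bp amplicon whose stop
codon sits just past the reverse primer), applies each clade's diagnostic
alleles, then adds per-sequence private substitutions (k ~ Uniform(3, 8) by
default, matching the observed 3–8 SNPs per clone) placed uniformly outside
diagnostic positions, the protected codons 110–114 and 176, and the start/stop
codons, never creating an in-frame stop.  A configurable fraction of sequences
instead receives one internal stop (pseudogenes).  Transition/transversion
bias is not modeled — no downstream stage depends on it.  Every output is
paired with a truth table (clade, injected SNPs, cds status) and all
generators are byte-deterministic per seed.

The template panel embeds the published primer footprints into synthetic
genomic templates: a CBCAS-like and THCAS-like gene from one ancestor with
~60 clade differences, and a CBDAS-like gene at ~16% body divergence and 1635
nt (one codon shorter).  A synthetic three-primer multiplex marker (bands
1080/1192 bp; the published marker's primer sequences are not public) is
derived from the panel with 3′-anchor bases forced pairwise distinct across
genes, and per-genotype template sets follow the 13 study genotypes'
chemotypes.

The plate generator produces Cq values under the exponential-phase
idealization `Cq = intercept − log10(q)/log10(1+E) + N(0, σ)` with per-gene
efficiencies (defaults from the published assay: CBDAS 1.04, THCAS 0.80,
CBCAS 1.01) and Cq noise SD 0.15 cycles by default — a typical SYBR
technical-replicate spread.  What the generators do *not* emulate: sequencing
error, chimeric clones, indels/CNV at the locus, inhibitor-driven efficiency
shifts between standards and unknowns, and inter-run calibration drift.
Passing tests therefore demonstrate correctness of the algorithms under the
stated noise model, not robustness to those real-data artifacts.

## Numerical choices and degenerate inputs

Round-half-up (decimal) for identities; saturated distances (log argument ≤ 0)
and empty pairwise-deletion intersections raise errors naming the pair; NJ on
fewer than 3 taxa, curves with fewer than 3 points or a single quantity, and
zero-replicate bootstraps are rejected; zero/negative RQ replicates are
dropped from the log transform with a warning.  All randomized commands
require an explicit seed, and every CLI run writes a manifest (inputs,
parameters, seed, version) sufficient to reproduce it.

## Known limitations

No multiple-alignment construction (inputs are assumed co-linear; a stacking
check enforces equal lengths); no thermodynamic duplex model behind the
mismatch proxy; the identity floor separating "same class" from "different
class" before diagnostic inspection is exposed rather than asserted, since no
canonical value exists; the stability ranking is a documented stand-in, not a
reimplementation of RefFinder's consensus.
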