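# Methods

## The measurement model

All analyses start from a per-site nucleotide count table: for every
candidate position on a shared circular reference and every isolate, the
number of reads showing A, C, G and T.  No consensus sequence is ever
formed.  The statistical premise is that an isolate is a pool of genotypes
and reads sample genomes from that pool, so at a SNP carried by a subset of
the genotypes the alternative read count is approximately
Binomial(depth, p) with p the summed proportion of carrier genotypes.
The alternative frequency ƒ_alt therefore estimates genotype proportions
directly, which is what makes mixtures quantifiable without deconvolution
machinery: a marker set of n positions gives n nearly independent binomial
estimates of one proportion, summarised by their median and 5th/95th
percentiles.

Assumptions worth keeping in mind: reads are taken as correctly mapped
(mapping and pileup generation are upstream of this package); each SNP is
biallelic after first-alternative reduction; genotype proportions are
constant along the genome (violated by recombinants and by genuinely
heterogeneous isolates, whose wide percentile ranges are the diagnostic).

## Filtering and the first alternative

A site/isolate pair is *variable* iff (strict bounds)
depth > `min_total_depth` (default 100), first-alternative count >
`min_alt_count` (default 10), and max(ƒ_ref, ƒ_alt) > `min_freq`
(default 0.05).  The frequency rule is deliberately applied to the larger of
the two focal-allele frequencies: with deep coverage, a genotype present at
2–7% of an isolate clears the absolute-count bound and is real variability;
requiring ƒ_alt > 0.05 would erase exactly the minority components the
method exists to measure.  The alternative-only reading is available as
`FilterConfig(freq_applies="alt")`.  The practical effect of the frequency
bound is to discard site/isolate pairs where a *third* base dominates, i.e.
where the globally chosen first alternative is not this isolate's signal.

The first alternative is chosen once per site as the non-reference base with
the highest count summed over all isolates (ties broken A<C<G<T).  A per-
isolate choice would make "the same SNP" mean different bases in different
isolates and break cross-isolate labels.  Sites with no variable isolate are
dropped; the retained-set definition is order-independent (filter-then-drop
equals drop-then-filter, asserted by test).

## Specificity labels and marker sets

The label of a position is the exact set of isolates in which it is
variable.  Labels are computed over the *field* isolates; commercial and
laboratory-selected preparations are then quantified on the resulting marker
sets.  This choice is forced by internal consistency: a selection derived
from the reference strain quantifies at 100% on the reference-identity set,
so it cannot itself be variable there, yet the set must keep its label.
Positions variable in no field isolate receive a label over the remaining
isolates (commercial-only markers).

The reference strain is a special case: its own genotype never shows
alternative reads against itself, so the set identifying it has the
complement label (variable in everyone else) and is quantified by the
*reference* frequency.  `specificity.reference_marker_set` constructs it.

## Composition arithmetic

`composition.quantify` reports median (default; the arithmetic mean is
exposed as an option) and 5/95 percentiles of the allele frequency over each
marker set, per isolate, as percentages; percentiles use linear
interpolation and rounding to integers happens only at report time.
`collapse_groups` implements the combined-label arithmetic: members of a
combined lineage set whose own specific sets quantify below
`absence_threshold` (default 1%) are removed from the label; when a
collapsed superset and a subset differ by one member, that member's
proportion is the difference of the medians, clamped to [0, 100].  A direct
single-member quantification obtained by collapsing a combined set (e.g.
E from DEFG when D, F, G are absent) outranks remainder arithmetic; a
subset median exceeding its superset median by more than `tolerance`
(default 5 points) emits a heterogeneity note instead of failing.

## ORF statistics

SNPs are classified wrap-aware on the circular genome: membership, in-frame
codon position (reverse-complemented for minus-strand ORFs) and synonymy by
translating the reference and mutated codons with the standard genetic code.
A SNP inside overlapping ORFs is classified per ORF; genome-wide tallies
count it once under the lexicographically lowest ORF id, and as
nonsynonymous if any frame changes the protein (the conservative call).
Per-ORF density is SNPs per kbp.  For class comparisons the pooled densities
are transformed with a Tukey ladder of powers — λ on a −2…2 grid in steps of
0.05, chosen to maximise the Shapiro–Wilk W; λ ≤ 0 requires positive values,
so a small offset is added when conserved (zero-SNP) ORFs are present — and
compared by one-way ANOVA, Tukey-HSD pairwise tests and a pooled
known-vs-unknown-function t test.

## Repeat-locus genotyping

The copy number of a short tandem repeat (canonical case: the 12-bp motif
GACACAGTGGAT in *pe38*, flanked by a unique 12-nt upstream and 10-nt
downstream sequence) is read off single reads: a read is informative iff
both flanks occur exactly once, in order, on one strand (the reverse
complement is scanned too).  Copy number = flank distance / motif length;
non-multiple distances and spans that are not verbatim tandem copies are
tallied as *irregular*, reads with duplicated flanks as *ambiguous*.
Matching is exact by default (`max_mismatch=0`); a mismatch tolerance exists
for noisy data.  Flanks shorter than 6 nt are rejected as ambiguity guards.

## HCPC

The isolates × positions ƒ_alt matrix (zeros where an isolate shows no
alternative reads — informative absence, not missing data) is centered and,
by default, scaled to unit column variance; zero-variance columns are
dropped with a warning.  PCA uses a full SVD with a deterministic sign
convention (largest-magnitude loading positive).  Ward agglomeration (the
squared-Euclidean Ward.D2 convention) runs on the first `n_components`
score columns (default 7).  The within-inertia increase of each merge,
read from k−1 to k clusters, is the *inertia gain*; the suggested cluster
number maximises the ratio of successive gains over the conventional
small-k window (k ≤ 10).  The tree is cut at k (default 6, one cluster per
lineage) and consolidated by a single k-means run initialised at the cut
clusters' centroids — deterministic, seed-free, and guaranteed not to
increase within-cluster inertia.

## The synthetic-data generator

`synth` draws a uniform-random circular reference, genotypes defined by
(position, alternative-base) sets, and count matrices via per-site
multinomial draws with success probabilities
p_alt = q(1−ε) + (1−q)ε/3, p_ref = (1−q)(1−ε) + qε/3 and ε/3 for the two
other bases, where q is the carrier proportion and ε the uniform base-miscall
rate (default 0.001, within the plausible post-filtering Illumina range).
Depths are truncated-normal per isolate (minimum 1), mirroring how panels
report mean ± SD read depth.  Repeat-locus reads are placed uniformly (or
forced to span the locus) over padded synthetic loci, with random strand.
Ground truth is emitted alongside every simulation; tests never re-derive
truth from outputs.

The default `study_panel` encodes the population structure the package is
organised around, as fixed design constants: a 123,529 bp reference; twenty
isolates (twelve field, eight commercial/selected) with the reported
per-isolate depths (540–4,345 mean); lineage marker sets of sizes
58 (reference-identity), 68, 24, 30, 89, 21, 22, 75 and 45; 290
low-frequency background positions spread over 24 assorted field labels at
5–7% carrier proportion; 30 commercial-only positions; and one
reference-anomaly site at position 105,178 carried by every genotype.  In
total 753 variable positions, 544 of them transitions, 665 inside ORFs and
88 intergenic, over a tiled annotation of ~86 ORFs including one spanning
the origin.  Mixture proportions follow the published composition medians
wherever a single consistent mixture exists (e.g. KS1 = 69% A + 31% E,
V15 = 9/42/49% A/B/E, V34 = 33/39/28% A/B/E); genuinely heterogeneous
isolates (the "wave"-patterned B-lineage material, the group-F mixtures)
cannot be represented by any exact finite mixture, so their designs are
self-consistent approximations and their cells are not regression targets.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: mapping and alignment artefacts, strand and GC
bias, position-correlated error, within-isolate recombination, and
genuinely continuous genotype heterogeneity.  The binomial model makes the
synthetic panel cleaner than real pileups; thresholds that are comfortable
here may sit closer to the noise floor in practice.

### Statistical resolution of the design

One designed margin is deliberately tight: the minority group-G component of
isolate JQ sits at 2%, so at JQ's depth (950 ± 184) a marker site of the
22-position {ALE, JQ} set has a 5.2% chance of drawing ≤ 10 alternative
reads and flipping its label to {ALE}.  The two set sizes therefore wobble
(within ±6 at 99.9% probability) while their sum stays fixed at 43; all
other set sizes are recovered exactly (weakest remaining margin: a 6%
component at depth ~1,076, ≈ 65 expected alternative reads).  Totals of
753/723/30 are stable to ±1 (a single-member background site can in rare
draws undershoot the read-count bound).

## Problem sizes

The worked analysis simulates 753 SNP + 400 invariant sites × 20 isolates
(≈ 23k multinomial draws), three repeat read sets of 400–3,000 reads, and
clusters 20 isolates on 7 components; the full pipeline runs in about two
seconds on one CPU.  Property tests use 100 replicate matrices (5 isolates ×
25–40 sites), 20–100 composition replicates at depth 2,000 and 200-SNP
translation oracles on 6 kb toy genomes.

## Known limitations

- Quantification assumes each marker set tags one genotype; for highly
  heterogeneous isolates the medians remain defined but the percentile
  ranges, not the medians, carry the information.
- The suggested-cluster-number rule (inertia-gain ratio) is a heuristic; on
  smoothly decaying gain sequences it can sit at the search-window edge, and
  the lineage count is the scientifically meaningful choice of k.
- The ƒ > 0.05 bound is nearly inactive under the ref-or-alt reading; the
  operative stringency comes from the absolute count and depth bounds.
- Real supplementary count tables vary in layout; the reduced ref/alt TSV
  dialect implemented here is one defined convention, sniffed by header.
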