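# Methods

This note records the models, conventions and numerical choices behind the
package, and what the synthetic generators do and do not emulate.

## Coordinates and formats

RepeatMasker `.out` records are read and written 1-based inclusive, with
the strand column's `C` mapped to `-`; internal `LtrElement` coordinates
are 0-based half-open; BED export is 0-based half-open. Conversion happens
only at the I/O boundary. Element sequences and both flanks are stored
strand-oriented (the element's own 5′→3′), so downstream code never
branches on strand.

Filtering to a working catalog keeps one repeat subtype, drops hits below
330 nt (a full LTR is ~337 nt; shorter hits are fragments) and drops
non-chromosomal placements. "Non-chromosomal" is a user-supplied allow
list when given, otherwise a name heuristic (`random`, `Un`, `hap`); the
removal counts are reported per criterion with precedence
subtype → short → unmapped so each record is counted once.

LTR pairing is greedy left-to-right with nearest-neighbour preference: two
same-strand, same-chromosome elements whose inner gap lies in
[3000, 8000] nt form one insertion (the window spans the ~5.4 kb truncated
and ~7.2 kb full-length IAP bodies); on the minus strand the left genomic
copy is the 3′ LTR. Everything unpaired is a solo LTR.

A naive consensus scanner (iterated best-infix edit-distance search via
edlib, masking each hit) exists solely so synthetic genomes can be scanned
without RepeatMasker; real annotations enter through the `.out` parser.

## Alignment and distances

Pairwise alignments use a Geneious-style parameterisation: match +5,
mismatch −4 (a standard realisation of a 65%-similarity target matrix),
gap open 12, gap extend 3, end gaps free. Pairwise identity is matches
over aligned columns excluding terminal-gap columns, i.e. identity over
the length of shared sequence.

The multiple alignment is a consensus-anchored star alignment: each
element is aligned pairwise to the consensus and columns are merged on
consensus positions, with insertion columns padded in all other rows. It
is deterministic and adequate for intra-family LTR alignment, where
indels are rare; it does not attempt progressive MSA refinement.
Unalignable elements are excluded by a normalised-score criterion
(alignment score over the perfect-match score of the shorter sequence,
threshold 0.50). An identity threshold cannot do this job: with affine
gaps, uniform random DNA reaches ~0.53 gapped identity against any
consensus, while its normalised score stays near 0.1 and a genuine family
member at 13% divergence scores ~0.77.

Distances: *p* is the observed proportion of differing sites, skipping
columns with a gap or N in either row (a pair with no comparable columns
is an error); the Jukes–Cantor correction d = −(3/4)·ln(1 − (4/3)·p) is
undefined at p ≥ 0.75 and raises, unless a cap is requested (the
bootstrap uses a cap so a saturated resample cannot abort a replicate).

## Tree building and clades

Neighbor joining is the Saitou–Nei algorithm: join the pair minimising
Q(i,j) = (n−2)·d(i,j) − Σ_k d(i,k) − Σ_k d(j,k), with branch lengths
l_i = d(i,j)/2 + (r_i − r_j)/(2(n−2)), negative lengths clamped to zero,
and ties broken by the lexicographically smallest active index pair so
output is deterministic. On any additive matrix the result reproduces the
input path-length matrix exactly (tested to 1e-9 up to n = 8 against a
brute-force least-squares oracle).

Bootstrap support resamples alignment columns with replacement, rebuilds
the tree per replicate, and reports the fraction of replicates containing
each internal bipartition. Internal edges of length ≤ 1e-12 are collapsed
before bipartitions are extracted, so an alignment of identical sequences
yields no (spuriously perfect) supports.

Clade partitioning cuts the k−1 longest internal edges whose removal
leaves every component with at least `min_clade_size` (default 5) leaves —
the in-code analogue of delineating clades visually on a tree figure.
Components are labelled `clade1..k` by descending mean divergence from
consensus, so the most conserved (oldest, largest) clade receives the
highest label, matching the field convention that "clade 3" is the
conserved background. δ_c is the clade mean of per-element *p*-distance to
the consensus row, in percent; computing it pairwise against the consensus
(rather than over all MSA columns) makes it independent of which other
elements happen to be in the alignment.

## CoBRA assay model

Bisulfite conversion is modelled on one strand: every C becomes T except
CpG cytosines explicitly marked methylated; marking a non-CpG cytosine is
an error because the chemistry converts those unconditionally. Conversion
preserves length and is idempotent on its own output.

The recognition string is the 6-mer `ACGGCG` carrying two CpGs (offsets 1
and 4). The enzyme-catalog 5-mer definition with a downstream cut is
representable through the configurable recognition/cut-offset pair, but
the 6-mer is the default because the two-CpG joint readout is the point of
the assay: the site survives conversion — and therefore cuts — iff *both*
CpGs were methylated (exhaustively tested over the 4 states). Digestion
cuts 12 nt downstream of the recognition 3′ end, a single-strand fragment
model that ignores the 2-nt stagger since only fragment sizes reach the
gel; a cut position falling beyond the amplicon end does not cut.
Fragment lengths always sum to the amplicon length.

Primer design operates on the bisulfite-converted antisense strand of
(unique flank + element), fully-methylated conversion, so CpG cytosines
remain C in the template and are then written as degenerate Y (forward,
template sense) or R (reverse, reverse-complement sense) — priming is
thereby unbiased by the genomic methylation state. On that template the
element occupies the 5′ portion and the unique flank the 3′ portion, so
the forward primer (element-internal, giving locus-homologous priming)
is a direct template window and the reverse primer (flank-internal,
giving locus specificity) a reverse-complement window. Constraints:
primer lengths 18–29 nt, melting temperature inside a configurable window
(Wallace rule 2·AT + 4·GC by default; nearest-neighbor optional), amplicon
150–1300 nt spanning the element/flank junction, and at least one
methylation-dependent site ≥ 30 nt clear of both primers. The search scans
forward-primer end positions from the site outward and reverse-primer
starts from the junction outward, taking the first satisfying pair, so
designs are deterministic; failures name the first unsatisfiable
constraint. Every emitted assay is re-validated from scratch by an
independent constraint checker rather than trusted.

Candidate selection keeps only 5′ LTRs of complete paired insertions (the
3′ copy duplicates the same insertion; solo LTRs lack full proviral
structure) and drops elements with repetitive assay flanks: a shared exact
30-mer with any other candidate's flank, or ≥ 50% of the flank interval
covered by other repeat annotations. The two thresholds operationalise
"repetitive flanking sequence" and are configurable.

## Quantitation

Percent methylation per lane is M = 100·I_cut/(I_cut + I_uncut), with all
cut sub-fragment bands summed (material is conserved), reported rounded to
integers as gel tables are printed while unrounded values feed the
statistics. Zero total intensity is undefined and flags the lane. The LOD
rule applies to the uncut (top) band: lanes below the configured intensity
are masked and excluded from analysis. Each locus's unmethylated control
must quantify ≤ 5% (otherwise incomplete conversion or nonspecific
digestion is suspected) and the methylated control ≥ 90%; a missing
control fails as absent. The assembled matrix distinguishes "lod" masking
from structural absence (a Y-linked locus in female mice) and round-trips
through TSV with `LOD` / blank cells.

## Statistics

Locus summaries use the sample (n−1) standard deviation and exclude masked
cells. The clade comparison uses per-locus means as the unit of analysis
(one value per locus, 7 per clade in the bundled panel): mice are not
independent replicates of a clade effect, and pooling mouse-level values
would pseudo-replicate. One-way ANOVA from the standard sums of squares;
omnibus p from the F distribution; pairwise contrasts use the Tukey HSD
adjustment with q = |Δmean|/√(MS_w/2·(1/n_i + 1/n_j)) (Tukey–Kramer) and
the adjusted p from the studentized range distribution with (k, df_w),
evaluated numerically via scipy's implementation of the closed-form CDF.
Degenerate input with zero within-group variance yields F = 0, p = 1 when
the means are equal. The implementation agrees with statsmodels'
`pairwise_tukeyhsd` to 1e-6 and with a 10^5-draw permutation oracle to
0.01 in the test suite.

On the bundled published matrix this analysis gives black−red p = 0.041
and black−green p = 0.018 — the same significance pattern, and the same
pair of p-values, as published, though the publication attributes 0.017 to
the red contrast and 0.040 to the green one. Since the green mean differs
from black by *more* than the red mean under equal n, that attribution is
not reproducible from the printed matrix under any balanced analysis; the
package reports computed values and does not chase the printed
attribution.

## Synthetic generators

`make_consensus` draws an LTR-sized (337 nt) random sequence with at least
2 CpGs per 100 nt and one recognition site planted on each strand — the
antisense-strand site (written `CGCCGT`) at offset 40–110 so an
element-internal forward primer fits upstream of it on the assay template.

`plant_elements` creates clade structure by founder-then-member mutation:
each clade founder accumulates half the clade's divergence from the
consensus, members diverge independently by the other half. The shared
founder substitutions are genuine synapomorphies, which is what lets NJ
recover the clades; independent star noise around the consensus would
not. Substitutions only (no indels) by default, so realised divergence is
the exact Hamming fraction recorded per copy in the emitted annotations.
Clade defaults follow the published family structure: 40 elements at 1.8%
(most methylated, 79%), 15 at 9.1% (70%), 12 at 12.9% (68%). Paired
insertions (default fraction 0.5) carry two identical LTR copies around a
5–7 kb random body. Background segments between insertions are at least
8.5 kb — above the pairing gap window — so planted paired/solo structure
is recoverable exactly; the default 1.2 Mb genome accommodates this
layout. Two realised-data features are deliberately not emulated: LTR
pairs with post-insertion divergence between the 5′ and 3′ copies, and
nested/fragmented insertions.

`simulate_methylation` draws per-locus true means from
Normal(clade mean, 7) and mouse values from Normal(locus mean, σ_ℓ) with
σ_ℓ ~ U(2, 8), all truncated to [0, 100]; truncated Gaussians (rather than
beta) fit the symmetric mid-range values of real panels. Cells drop out
independently at 2% as LOD; Y-linked loci are masked in females (7 of 17
mice are male). `simulate_gel` inverts quantitation with multiplicative
lognormal noise at CV 5% on each band and a ±20% random lane scale around
a base intensity of 1000 units; LOD threshold 50 units. At that base
intensity a cell above ~95% methylation can legitimately fall below the
uncut-band LOD — the same mechanism that masks high-methylation lanes on
real gels — so exact-mask round-trip tests use tables with moderate means.

What passing the synthetic tests shows — and what it does not: recovery of
planted structure, clades and methylation parameters demonstrates that the
pipeline's inference is correct under its own generating assumptions
(substitution-only divergence, Gaussian noise, independent dropouts). It
does not certify performance on real genomes, where alignment error,
segmental duplication, polymorphic insertions and gel artefacts violate
those assumptions.

A note on statistical power under the default conditions: with 7 locus
means per clade and a between-locus standard deviation of 7 points, the
9-point conserved-vs-diverged contrast carries roughly 40% power for the
Tukey test at α = 0.05 (the observed joint significance rate across 200
replicates is ~37%, and the point-estimate ordering "conserved above both
diverged clades" holds in ~99%). A single 17 × 21 panel reaching
significance on both contrasts is therefore a favourable draw, not the
typical outcome; the acceptance script reports the measured rates.

## Problem sizes and determinism

All generators and the bootstrap take explicit seeds or
`numpy.random.Generator` instances and are fully reproducible; seeded
defaults are used throughout the tests. The test suite and acceptance
script run the phylogeny end-to-end at the published family's scaled-down
shape (67 elements of 337 nt, clades 40/15/12), the methylation
replications at 200 seeded tables of 17 × 21, and the permutation oracle
at 10^5 draws — sizes chosen so every analysis remains a desk-scale
computation while keeping estimator noise well below the tested margins.
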