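# metastable

Phylogeny-guided discovery and CoBRA validation of variably methylated LTR
retrotransposons.

## The problem

Intracisternal A particle (IAP) elements are murine endogenous retroviruses
kept silent by dense CpG methylation. At a handful of loci — *metastable
epialleles* such as A^vy and Cabp^IAP — the 5′ long terminal repeat (LTR) is
*variably* methylated among genetically identical mice, the state is set
stochastically in early development, and it shifts under maternal
environmental exposures. This package implements a pipeline for finding and
validating such loci systematically:

1. **repeats** — parse RepeatMasker `.out` annotations, filter to one LTR
   subtype (e.g. `IAPLTR1_Mm`, minimum 330 nt, chromosomal sequences only),
   extract each element with up to 400 nt of flank, and classify copies as
   5′/3′ of a paired proviral insertion or as solo LTRs.
2. **phylogeny** — align every element to the family consensus
   (Geneious-style pairwise scoring: 65%-similarity matrix, gap open 12,
   extend 3), compute observed *p*-distances and Jukes–Cantor distances
   d = −(3/4)·ln(1 − (4/3)·p), build a Saitou–Nei neighbor-joining tree with
   optional column-bootstrap supports, and cut it into clades whose mean
   divergence from consensus δ_c summarises their age.
3. **assay** — design combined bisulfite restriction analysis (CoBRA)
   assays: in-silico bisulfite conversion (unmethylated C → T, methylated
   CpG C protected), detection of the two-CpG BceAI recognition string
   `ACGGCG` (cut iff *both* CpGs were methylated), junction-spanning primer
   pairs (forward inside the element, reverse in the unique flank, CpGs in
   primers degenerate as Y/R), and predicted digest fragments.
4. **quant** — turn gel band intensities into percent methylation,
   M = 100·I_cut/(I_cut + I_uncut), enforce the digestion controls, mask
   lanes below the limit of detection, and assemble the mice × loci matrix.
5. **stats** — per-locus / per-mouse / per-clade summaries and the clade
   comparison: one-way ANOVA on per-locus means followed by Tukey HSD
   (studentized-range distribution, Tukey–Kramer SE for unequal n).
6. **simulate** — synthetic genomes with planted, clade-structured LTR
   insertions plus matching annotations, and mice × loci methylation
   matrices with clade-dependent means, per-locus noise, gel intensities
   and LOD dropouts — so every stage runs and is testable at desk scale.

The published 17-mouse × 21-locus CoBRA methylation matrix ships with the
package (`metastable.datasets.load_cobra_table()`), along with the
published primer/condition table.

## Worked example

```python
from metastable import datasets
from metastable.stats import clade_statistics, clade_anova, grand_mean

table = datasets.load_cobra_table()          # 17 mice x 21 LTR loci
print(f"grand mean: {grand_mean(table):.1f}%")
print(clade_statistics(table).round(2))
print(clade_anova(table).summary())
```

prints

```
grand mean: 72.5%
       n_loci   mean  mean_range  pooled_sd
clade
black       7  79.32       11.00       3.85
green       7  68.16       16.29       4.56
red         7  69.67       20.86       5.75

One-way ANOVA with Tukey HSD
F(2, 18) = 5.512, p = 0.01358

group means:
  black: 79.317
  green: 68.163
  red: 69.672

group1 group2   diff    se      q   p_adj  reject
 black  green -11.15 2.578  4.327 0.01763    True
 black    red -9.645 2.578  3.742 0.04146    True
 green    red  1.509 2.578 0.5854  0.9103   False
```

Reading: methylation averaged over everything is a steady ~72.5% and each
mouse's own average sits in a narrow 71–74% band — but individual loci
range from a 59% to an 88% mean, and the phylogenetically conserved clade
("black", δ_c ≈ 1.8% from consensus) is significantly more methylated
(79%) than either diverged clade (70% and 68%), while also varying less
between mice (average per-locus range 11 points vs 21 and 16). Variable
methylation tracks phylogeny: the young, diverged subfamilies that escaped
silencing well enough to amplify are exactly the ones that remain
epigenetically labile.

The same analyses run from the shell:

```bash
metastable simulate --seed 17 --out sim/
metastable scan --genome sim/genome.fa --rmout sim/repeats.out --out catalog/
metastable phylo --elements catalog/elements.fa --consensus sim/consensus.fa --out tree/
metastable quantify --lanes sim/lanes.tsv --lod 50 --clades sim/clades.tsv --out methylation.tsv
metastable stats --table methylation.tsv --clades sim/clades.tsv --out stats/
```

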