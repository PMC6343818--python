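# Methods

`hybridgca` implements the statistical pipeline used to dissect the
genetic basis of general combining ability (GCA) in a panel of inbred
parents of hybrid crops: GCA estimation from a North Carolina design II
(NCII) factorial, confidence-interval haplotype-block partitioning of the
parents' SNPs, collapse of blocks into multi-allelic SNPLDB markers,
single-factor ANOVA association of marker alleles with GCA effect values,
and mining of favourable (positive-effect) alleles. A synthetic-data
generator with planted ground truth stands in for raw field and
sequencing data so that every stage can be verified end to end.

## GCA estimation (`hybridgca.gca`)

In an NCII design a set of female lines (CMS lines in hybrid rice) is
crossed to a set of male lines (restorers) in a complete factorial and the
F1 hybrids are evaluated in a randomized complete block design (RCBD).
The GCA effect of parent *i* for a trait is

    g_i = y_i − ȳ

where *y_i* is the mean of every replication-level record of crosses
involving parent *i* and *ȳ* is the mean of all records in the
subpopulation group. Females and males are estimated independently; in a
balanced factorial each role's effects sum to zero by construction, which
the tests assert to 1e−9. ȳ is the grand mean over records (identical to
the mean of cross means when balanced); unbalanced tables fall back to the
same record-level means with a warning.

The hybrids' ANOVA is the standard RCBD decomposition (crosses as
treatments, replications as blocks); its residual mean square feeds the
least-significant-difference (LSD) letter display:

    LSD = t(1 − α/2, df_error) · sqrt(2·MSE / n)

with `n = (crosses per parent) × replications` and α = 0.01 by default.
Letters are assigned by the insert-and-absorb algorithm on
descending-sorted means, ties broken by parent id, so output is
deterministic. The error term for comparing GCA means is not uniquely
defined in the field's practice; the pooled RCBD residual used here is the
standard NCII choice, and published letter groupings computed with a
different error term need not match letter for letter.

Mid-parent heterosis is `100·(F1 − MP)/MP` with `MP = (P1 + P2)/2`; it
requires parental line means and is undefined at MP = 0. Values are
reported signed for every trait (no flipping for traits where smaller is
better).

## LD and SNPLDB construction (`hybridgca.ld`)

The panel is fully homozygous, so two-locus haplotypes are read directly
off the genotype matrix — no phasing or EM step exists, which makes the
haplotype counts exact rather than estimated. Missing calls are imputed
by the site's majority allele (optionally within subpopulation group),
ties to the reference allele; the imputer is deliberately isolated behind
one function so a model-based imputer can be swapped in.

For a site pair with haplotype frequencies `p_AB` etc.,
`D = p_AB − p_A p_B`, `D′ = |D| / D_max`, `r² = D² / (p_A q_A p_B q_B)`.
The D′ confidence interval follows the likelihood approach of
confidence-interval ("Gabriel") block partitioning: the multinomial
likelihood of the four observed haplotype counts is evaluated on a grid of
D′ ∈ [0, 1] (step 0.01, configurable) with allele frequencies held at
their observed values and the sign of D fixed; after normalising the grid
to unit mass, the 5th and 95th cumulative percentiles give the bounds.

Blocks use the published parameterisation: maximum extent 200 kb and
minimum MAF 0.01, with the standard thresholds — a pair is in **strong
LD** when `ci_high ≥ 0.98` and `ci_low ≥ 0.70`, shows **strong
recombination** when `ci_high < 0.90`, and is otherwise uninformative. A
candidate span must have a strong-LD endpoint pair and ≥ 95 % of its
informative pairs in strong LD; candidates are accepted greedily by
physical length (ties to the leftmost start), skipping overlaps. No
span-length-dependent minimum pair counts are imposed beyond the endpoint
pair itself; all five thresholds are exposed as parameters. The
implementation is checked against an exhaustive enumeration oracle on
instances of up to 12 sites.

Each accepted block becomes one multi-allelic **SNPLDB marker** whose
alleles are the concatenated bases of the member sites per parent, named
`{chrom}_BLOCK_{first}_{last}` from the 1-based positions of its first and
last member SNP; polymorphic SNPs outside any block are kept as singleton
biallelic markers `S{chrom}_{pos}`. Marker summaries are the minor allele
frequency (second-largest allele frequency), gene diversity `1 − Σ p_k²`
and polymorphism information content
`PIC = 1 − Σ p_k² − Σ_{k<l} 2 p_k² p_l²`, with `PIC ≤ diversity` always.

## Association and favourable alleles (`hybridgca.association`)

Each marker × trait combination is tested with the one-way ANOVA model
`y_ij = μ + a_i + ε_ij`, alleles as groups and per-parent GCA effect
values as observations, pooled over the whole panel (an optional flag
z-scores g within strata first). The record carries F, the F-distribution
P value, `R² = 100·SS_between/SS_total` (percent of variance explained)
and per-allele effects (allele mean − grand mean of retained parents).
Alleles with fewer than `min_carriers` (default 2) carriers are dropped
from that marker's test because single-carrier groups contribute no
within-group variance. Significance defaults to a per-test α = 0.01 with
no genome-wide correction, mirroring the published analysis; Bonferroni
and Benjamini–Hochberg are available behind a flag. A zero within-group
variance with distinct group means yields the smallest positive double as
P and a `degenerate` flag rather than a silent failure.

Favourable alleles are the positive-effect alleles of significant
records, reported with their carrier parents; the per-parent tally of
favourable alleles per trait is the pipeline's breeding-oriented output.

## SNP annotation (`hybridgca.annotate`)

SNPs are placed in exactly one region class with the precedence
CDS(exon) > UTR > splice > intron > intergenic; the splice region is the
2 intronic bases at each junction (width configurable). Only the first
transcript per gene is considered. Coding SNPs are classified by mutating
the affected codon of the spliced, phase-corrected CDS and translating
with the standard nuclear code (synonymous / missense / nonsense; the
minus strand is handled by complementation), verified against a
whole-CDS translate-and-diff oracle. Substitutions split into transitions
(C/T, G/A) and transversions (C/G, T/A, A/C, G/T). Because class
percentages depend on the annotation source and precedence conventions,
published percentages are not expected to reproduce exactly.

## Synthetic data (`hybridgca.simulate`)

`simulate_parents` plants LD structure directly: each block draws a small
repertoire of distinct binary haplotypes (default 3 per block, redrawn
until every site's frequency clears `maf_floor` = 0.10) and assigns every
parent one haplotype, so within-block D′ is 1 by construction and
between-block sites are independent. Missing calls are injected
independently per (parent, site) at `missing_rate` (default 0.02),
keeping at least one typed parent per site.

`simulate_crosses` builds the full-factorial phenotype records as

    y = grand_mean + g_female + g_male + SCA + rep effect + noise.

Per-parent g values are sums of planted per-allele effects at
`n_causal_blocks` (default 4) randomly chosen blocks, centred within each
role group so the NCII sum-to-zero constraint holds exactly; the SCA
matrix is drawn i.i.d. normal and double-centred, keeping GCA and SCA
orthogonal. With noise, SCA and replication effects all zero the
estimator recovers the planted g exactly (tested to 1e−9; observed at
~1e−14).

The default panel is 21 female × 12 male = 33 parents with three
replications — the published panel size collapsed into a single factorial,
since the generator models one group (the original design crossed two
subspecies sets of 8×6 and 13×6 separately). Default effect scales
(allele effects sd 1.0, SCA sd 0.5, replication sd 0.5, residual sd 1.0,
all in trait units around a grand mean of 100) give causal blocks that
explain on the order of 25 % of GCA variance each, comparable to the
variance explained by significant markers in real panels of this size.

What the generator does *not* emulate: sequencing reads and genotyping
error, population structure beyond a single group label, linkage between
blocks, dominance at the allele-effect level, and trait correlations.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to real-data artefacts
such as structure-induced confounding.

## Numerical choices and degenerate inputs

- Zero-variance ANOVA tables are flagged and reported not-significant
  instead of dividing by zero; zero within-group variance with k ≥ 2
  distinct means reports the smallest positive double as P, flagged.
- The D′ grid resolution is 0.01; the CI search uses cumulative mass with
  `searchsorted`, so bounds are always grid values.
- Sites below the MAF floor are excluded before partitioning; fully
  missing sites are an error naming the site.
- Heterozygous genotypes are rejected at VCF read time (inbred contract)
  rather than silently dropped.
- All coordinates are 1-based inclusive (VCF convention); the BED export
  converts to 0-based half-open and both files label their convention.

## Problem sizes used in the checks

The verification suite runs at desk scale: panels of 14–33 parents,
genomes of 6–18 planted blocks (≈ 60–80 SNPs), 200-replicate power and
500 × 200 null calibration simulations, 1000-instance partition-oracle
sweeps and 200 random toy genes. These sizes were chosen so the full
suite documents the method's calibration properties (type-I error inside
the binomial envelope, power ≥ 0.9 at a 2-residual-SD allele contrast in
33 parents) while remaining quick to run; the statistical properties they
establish are size-generic.

## Known limitations

- The published raw-data results (hundreds of thousands of SNPs, 2612
  SNPLDBs, 99 significant markers) derive from a sequencing dataset that
  is out of scope here; the pipeline reproduces the *procedure*, with the
  synthetic generator providing ground truth instead.
- At n = 33 haplotypes the D′ confidence interval is wide, so blocks with
  3+ haplotypes or modest minor-class counts are often left unconfirmed
  (pairs fall in the uninformative category). This is faithful to the
  confidence-interval method; the exact-recovery guarantee holds in the
  two-haplotype, no-missing-data regime.
- The association model fits no kinship or structure correction, exactly
  like the analysis it implements; on structured panels its P values are
  anti-conservative.
- LSD letters compare means using the pooled RCBD residual; alternative
  error terms change letters but not g values.
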