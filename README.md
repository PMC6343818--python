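# hybridgca

Dissecting the genetic basis of **general combining ability (GCA)** in
panels of inbred parents of hybrid crops.

Hybrid breeding programmes pick parents by how much they improve their
offspring on average — the parent's GCA. `hybridgca` implements, as a
tested Python library and CLI, the full analysis chain that links a
North Carolina design II (NCII) crossing trial to the parents' genomes:

1. **GCA estimation** from replication-level hybrid phenotypes:
   `g_i = y_i − ȳ`, the deviation of the mean of parent *i*'s crosses
   from the group mean, with RCBD ANOVA of the hybrids, LSD letter groups
   at α = 0.01, and mid-parent heterosis.
2. **SNPLDB construction**: pairwise D′ with likelihood-based confidence
   intervals, confidence-interval (Gabriel) haplotype-block partitioning
   (max extent 200 kb, MAF ≥ 0.01), and collapse of each block into one
   multi-allelic marker whose alleles are the block haplotypes, with MAF,
   gene diversity and PIC per marker.
3. **Association**: single-factor ANOVA of marker alleles against
   per-parent GCA effect values (`y_ij = μ + a_i + ε_ij`), reporting F,
   P, and R² (percent of variance explained).
4. **Favourable-allele mining**: positive-effect alleles at significant
   markers, tallied per parent and trait — the shortlist a breeder uses
   to choose and improve parents.
5. **SNP annotation** (optional): region classes from GFF3 + FASTA
   (exon / intron / UTR / splice / intergenic), synonymous–missense–
   nonsense calls, and Ts/Tv classification.

A synthetic-data generator plants LD-block structure and causal GCA
alleles with known ground truth, so every stage is verifiable end to end.
The analytic stages are exposed as sklearn-style estimators
(`GCAEstimator`, `SNPLDBTransformer`, `SNPLDBAssociation`) over plain
functions.

## Worked example

Simulate a 33-parent panel (21 CMS × 12 restorer lines, 3 replications)
and run the whole pipeline:

```bash
hybridgca simulate --seed 1 --out-dir demo
hybridgca run --vcf demo/parents.vcf --phenotypes demo/phenotypes.tsv \
              --output-dir demo/out
cat demo/out/summary.txt
```

```
markers: 33
blocks (multi-site): 16
tests: 99
significant records (alpha=0.01): 6
mean R2 among significant (%): 43.6
favourable alleles: 7
```

Of 77 simulated SNPs, 16 haplotype blocks are confirmed and, with the
singleton SNPs left over, 33 SNPLDB markers are tested against the GCA
values of 3 traits (99 tests). Six marker × trait pairs clear α = 0.01,
explaining on average 43.6 % of the variance in GCA among parents, and 7
positive-effect (favourable) alleles are mined from them —
`demo/out/parent_tally.tsv` lists which parents carry how many of them
per trait, and `demo/out/gca_effects.tsv` holds each parent's g values
with LSD letters:

```
parent  group  role    T1          T1_letters  ...
CMS01   sim    female  -1.022      ef          ...
CMS02   sim    female   0.067      d           ...
```

The same stages are available in the library:

```python
from hybridgca import GCAEstimator, SNPLDBTransformer, SNPLDBAssociation
from hybridgca.simulate import SimConfig, simulate_parents, simulate_crosses

cfg = SimConfig(seed=1)
genotypes, truth = simulate_parents(cfg)
crosses = simulate_crosses(genotypes, truth, cfg)

gca = GCAEstimator().fit(crosses)             # effects_, anova_, letters
markers = SNPLDBTransformer().fit(genotypes)  # blocks_, markers_, stats_
assoc = SNPLDBAssociation(alpha=0.01).fit(
    markers.markers_, gca.gca_matrix().loc[genotypes.parents]
)
print(assoc.summary_)                          # tests, significant, mean R2
```

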