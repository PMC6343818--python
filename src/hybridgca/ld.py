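"""Linkage disequilibrium, haplotype-block partitioning and SNPLDB markers.

The panel consists of inbred (fully homozygous) lines, so two-locus
haplotypes can be read directly off the genotype matrix — no phasing or EM
is needed.  Pairwise LD is summarised by D' with a likelihood-based
confidence interval, chromosomes are partitioned into haplotype blocks by
the confidence-interval (Gabriel) rule, and each block is collapsed into a
single multi-allelic "SNPLDB" marker whose alleles are the haplotype
strings of its member SNPs.  Polymorphic SNPs outside any block are kept as
singleton biallelic markers.

Defaults follow the published analysis: maximum block extent 200 kb and
minimum MAF 0.01, with the standard confidence-interval thresholds
(strong LD when the D' CI is [>=0.70, >=0.98]; strong historical
recombination when the CI upper bound is < 0.90; a block requires >= 95 %
of its informative pairs in strong LD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MISSING, GenotypeMatrix

__all__ = [
    "PairLD",
    "LDBlock",
    "SNPLDBMarker",
    "impute_missing",
    "site_maf",
    "pair_ld",
    "dprime_ci",
    "gabriel_blocks",
    "build_snpldb",
    "marker_stats",
    "SNPLDBTransformer",
]

# Gabriel confidence-interval partitioning thresholds (Haploview defaults)
STRONG_CI_LOW = 0.70
STRONG_CI_HIGH = 0.98
RECOMB_CI_HIGH = 0.90
INFORMATIVE_FRACTION = 0.95


@dataclass
class PairLD:
    """Pairwise LD summary between two sites.

    ``informative`` is False when either site is monomorphic among the
    parents typed at both sites, in which case the statistics are NaN.
    """

    i: int
    j: int
    n_informative: int
    D: float = np.nan
    dprime: float = np.nan
    r2: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    informative: bool = True


@dataclass
class LDBlock:
    """A haplotype block: contiguous run of retained sites on one chromosome.

    ``start``/``end`` are the 1-based positions of the first/last member
    SNP (inclusive), matching the ``{chrom}_BLOCK_{start}_{end}`` naming.
    """

    chrom: str
    start: int
    end: int
    members: list[int]

    @property
    def name(self) -> str:
        return f"{self.chrom}_BLOCK_{self.start}_{self.end}"


@dataclass
class SNPLDBMarker:
    """A multi-allelic marker collapsed from an LD block (or a singleton SNP).

    Alleles are haplotype strings over the member sites; ``parent_alleles``
    maps every parent to its allele string.
    """

    marker_id: str
    chrom: str
    start: int
    end: int
    sites: list[int]
    allele_freqs: dict[str, float]
    parent_alleles: dict[str, str]
    maf: float = 0.0
    gene_diversity: float = 0.0
    pic: float = 0.0

    @property
    def n_alleles(self) -> int:
        return len(self.allele_freqs)

    @property
    def is_monomorphic(self) -> bool:
        return self.n_alleles < 2


def site_maf(genotypes: GenotypeMatrix, site: int) -> float:
    """Minor allele frequency of one site over non-missing parents."""
    return genotypes.site_maf(site)


def impute_missing(genotypes: GenotypeMatrix, by_group: bool = False) -> GenotypeMatrix:
    """Replace missing calls with the site's most frequent allele.

    With ``by_group`` set and group labels available, the majority is taken
    within the parent's subpopulation group, falling back to the overall
    majority when the group is untyped at the site.  Ties go to the
    reference allele.  A site with no typed parent at all raises.
    """
    out = genotypes.copy()
    calls = out.calls
    groups = out.groups if by_group else None
    if by_group and groups is None:
        raise ValueError("by_group imputation requires group labels on the matrix")
    group_of = None
    if groups is not None:
        group_of = np.array([groups[p] for p in out.parents], dtype=object)
    for j in range(out.n_sites):
        col = calls[:, j]
        miss = col == MISSING
        if not miss.any():
            continue
        typed = col[~miss]
        if typed.size == 0:
            raise ValueError(
                f"site {out.chrom[j]}:{out.pos[j]} is missing in every parent; "
                "cannot impute"
            )
        n_alt_all = int((typed == 1).sum())
        # majority with tie -> ref (0)
        fill_all = 1 if n_alt_all * 2 > typed.size else 0
        for i in np.flatnonzero(miss):
            fill = fill_all
            if group_of is not None:
                same = (group_of == group_of[i]) & ~miss
                gt = col[same]
                if gt.size:
                    n_alt = int((gt == 1).sum())
                    fill = 1 if n_alt * 2 > gt.size else 0
            calls[i, j] = fill
    return out


def _haplotype_counts(genotypes: GenotypeMatrix, i: int, j: int) -> tuple[int, int, int, int, int]:
    """Two-locus haplotype counts over parents typed at both sites.

    Returns (n_AB, n_Ab, n_aB, n_ab, n) where A/B denote the alt allele at
    sites i and j.  Exact for inbreds: each parent contributes one
    haplotype.
    """
    ci = genotypes.calls[:, i]
    cj = genotypes.calls[:, j]
    ok = (ci != MISSING) & (cj != MISSING)
    a, b = ci[ok], cj[ok]
    n_ab11 = int(((a == 1) & (b == 1)).sum())
    n_ab10 = int(((a == 1) & (b == 0)).sum())
    n_ab01 = int(((a == 0) & (b == 1)).sum())
    n_ab00 = int(((a == 0) & (b == 0)).sum())
    return n_ab11, n_ab10, n_ab01, n_ab00, int(ok.sum())


def _ld_from_counts(n_AB: int, n_Ab: int, n_aB: int, n_ab: int) -> tuple[float, float, float]:
    """(D, D', r^2) from four haplotype counts."""
    n = n_AB + n_Ab + n_aB + n_ab
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    p_ab = n_AB / n
    d = p_ab - p_a * p_b
    q_a, q_b = 1 - p_a, 1 - p_b
    if d > 0:
        d_max = min(p_a * q_b, q_a * p_b)
    else:
        d_max = min(p_a * p_b, q_a * q_b)
    dprime = 0.0 if d_max == 0 else abs(d) / d_max
    denom = p_a * q_a * p_b * q_b
    r2 = 0.0 if denom == 0 else d * d / denom
    return d, min(dprime, 1.0), min(r2, 1.0)


def dprime_ci(
    haplotype_counts: tuple[int, int, int, int], grid_step: float = 0.01
) -> tuple[float, float]:
    """Likelihood-based confidence bounds on |D'|.

    The multinomial likelihood of the four observed haplotype counts is
    evaluated on a grid of D' in [0, 1] (allele frequencies held at their
    observed values, the sign of D fixed at its observed sign), normalised
    to unit mass; the lower bound is the smallest grid value whose
    cumulative mass reaches 0.05 and the upper bound the smallest reaching
    0.95.
    """
    n_AB, n_Ab, n_aB, n_ab = (int(c) for c in haplotype_counts)
    counts = np.array([n_AB, n_Ab, n_aB, n_ab], dtype=float)
    n = counts.sum()
    if n < 2:
        raise ValueError("need a total haplotype count >= 2")
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    q_a, q_b = 1 - p_a, 1 - p_b
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise ValueError("degenerate allele frequencies; both loci must be polymorphic")
    d_obs = n_AB / n - p_a * p_b
    if d_obs >= 0:
        d_max = min(p_a * q_b, q_a * p_b)
        sign = 1.0
    else:
        d_max = min(p_a * p_b, q_a * q_b)
        sign = -1.0
    grid = np.round(np.arange(0.0, 1.0 + grid_step / 2, grid_step), 10)
    d_vals = sign * grid * d_max
    p11 = p_a * p_b + d_vals
    p10 = p_a * q_b - d_vals
    p01 = q_a * p_b - d_vals
    p00 = q_a * q_b + d_vals
    probs = np.stack([p11, p10, p01, p00], axis=1)
    probs = np.clip(probs, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(counts > 0, np.log(np.where(probs > 0, probs, 1.0)), 0.0)
        impossible = (probs <= 0) & (counts > 0)
        loglik = (counts * logp).sum(axis=1)
        loglik[impossible.any(axis=1)] = -np.inf
    loglik -= loglik.max()
    lik = np.exp(loglik)
    total = lik.sum()
    if total == 0:
        raise ValueError("zero likelihood over the whole D' grid")
    cum = np.cumsum(lik) / total
    ci_low = float(grid[np.searchsorted(cum, 0.05)])
    ci_high = float(grid[np.searchsorted(cum, 0.95)])
    return ci_low, ci_high


def pair_ld(
    genotypes: GenotypeMatrix, i: int, j: int, grid_step: float = 0.01
) -> PairLD:
    """Pairwise LD (D, D', r^2 and D' CI) between sites ``i`` and ``j``.

    Haplotypes are read directly from the homozygous calls of parents
    non-missing at both sites.  A pair where either site is monomorphic
    among those parents is returned flagged non-informative.
    """
    n_AB, n_Ab, n_aB, n_ab, n = _haplotype_counts(genotypes, i, j)
    if n == 0:
        return PairLD(i=i, j=j, n_informative=0, informative=False)
    p_a = (n_AB + n_Ab) / n
    p_b = (n_AB + n_aB) / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        return PairLD(i=i, j=j, n_informative=n, informative=False)
    d, dprime, r2 = _ld_from_counts(n_AB, n_Ab, n_aB, n_ab)
    lo, hi = dprime_ci((n_AB, n_Ab, n_aB, n_ab), grid_step=grid_step)
    return PairLD(
        i=i, j=j, n_informative=n, D=d, dprime=dprime, r2=r2, ci_low=lo, ci_high=hi
    )


# pair categories for the block-partitioning rule
_STRONG, _RECOMB, _UNINFORMATIVE = 1, -1, 0


def classify_pair(
    ld: PairLD,
    strong_ci_low: float = STRONG_CI_LOW,
    strong_ci_high: float = STRONG_CI_HIGH,
    recomb_ci_high: float = RECOMB_CI_HIGH,
) -> int:
    """Categorise a pair: strong LD (+1), strong recombination (-1), else 0."""
    if not ld.informative:
        return _UNINFORMATIVE
    if ld.ci_high >= strong_ci_high and ld.ci_low >= strong_ci_low:
        return _STRONG
    if ld.ci_high < recomb_ci_high:
        return _RECOMB
    return _UNINFORMATIVE


def gabriel_blocks(
    genotypes: GenotypeMatrix,
    max_distance: int = 200_000,
    maf_min: float = 0.01,
    strong_ci_low: float = STRONG_CI_LOW,
    strong_ci_high: float = STRONG_CI_HIGH,
    recomb_ci_high: float = RECOMB_CI_HIGH,
    informative_fraction: float = INFORMATIVE_FRACTION,
    grid_step: float = 0.01,
) -> list[LDBlock]:
    """Partition each chromosome into confidence-interval haplotype blocks.

    Sites with MAF below ``maf_min`` are excluded.  A candidate span
    [i..j] over the retained sites of one chromosome is admissible when its
    end positions are within ``max_distance``, its endpoint pair is in
    strong LD, and at least ``informative_fraction`` of the informative
    pairs inside the span are in strong LD.  Admissible spans are accepted
    greedily by decreasing physical length (ties to the leftmost start),
    skipping spans that overlap an accepted block.  Returned blocks have
    >= 2 member sites; remaining polymorphic sites become singleton markers
    at SNPLDB construction.
    """
    genotypes._check_sorted()
    retained = [
        j
        for j in range(genotypes.n_sites)
        if genotypes.is_polymorphic(j) and genotypes.site_maf(j) >= maf_min
    ]
    blocks: list[LDBlock] = []
    # group retained site indices per chromosome
    by_chrom: dict[str, list[int]] = {}
    for j in retained:
        by_chrom.setdefault(str(genotypes.chrom[j]), []).append(j)
    for chrom, sites in by_chrom.items():
        m = len(sites)
        if m < 2:
            continue
        pos = genotypes.pos[sites]
        cat = np.zeros((m, m), dtype=np.int8)
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_distance:
                    continue
                ld = pair_ld(genotypes, sites[a], sites[b], grid_step=grid_step)
                cat[a, b] = classify_pair(
                    ld, strong_ci_low, strong_ci_high, recomb_ci_high
                )
        candidates: list[tuple[int, int, int]] = []  # (span_bp, a, b)
        for a in range(m):
            for b in range(a + 1, m):
                span = int(pos[b] - pos[a])
                if span > max_distance:
                    break
                if cat[a, b] != _STRONG:
                    continue
                sub = cat[a : b + 1, a : b + 1]
                n_strong = int((sub == _STRONG).sum())
                n_recomb = int((sub == _RECOMB).sum())
                n_informative = n_strong + n_recomb
                if n_informative < 1:
                    continue
                if n_strong / n_informative >= informative_fraction:
                    candidates.append((span, a, b))
        candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
        taken = np.zeros(m, dtype=bool)
        for span, a, b in candidates:
            if taken[a : b + 1].any():
                continue
            taken[a : b + 1] = True
            blocks.append(
                LDBlock(
                    chrom=chrom,
                    start=int(pos[a]),
                    end=int(pos[b]),
                    members=[sites[k] for k in range(a, b + 1)],
                )
            )
    blocks.sort(key=lambda blk: (str(blk.chrom), blk.start))
    return blocks


def marker_stats(allele_freqs: dict[str, float] | list[float]) -> tuple[float, float, float]:
    """(MAF, gene diversity, PIC) of a multi-allelic marker.

    gene diversity = 1 - sum p_k^2; PIC = 1 - sum p_k^2
    - sum_{k<l} 2 p_k^2 p_l^2; MAF is the second-largest allele frequency
    (0 for a monomorphic marker).
    """
    p = np.sort(np.asarray(
        list(allele_freqs.values()) if isinstance(allele_freqs, dict) else allele_freqs,
        dtype=float,
    ))[::-1]
    if p.size == 0:
        raise ValueError("marker has no alleles")
    maf = float(p[1]) if p.size > 1 else 0.0
    sum_p2 = float((p**2).sum())
    diversity = 1.0 - sum_p2
    cross = 0.0
    for k in range(p.size):
        for l in range(k + 1, p.size):
            cross += 2.0 * p[k] ** 2 * p[l] ** 2
    pic = 1.0 - sum_p2 - cross
    return maf, diversity, pic


def build_snpldb(
    genotypes: GenotypeMatrix,
    blocks: list[LDBlock],
    maf_min: float = 0.01,
    include_singletons: bool = True,
) -> list[SNPLDBMarker]:
    """Collapse blocks into multi-allelic SNPLDB markers.

    Each parent's allele at a block is the concatenation of its bases at
    the member sites.  Sites not in any block that are polymorphic with
    MAF >= ``maf_min`` become singleton biallelic markers named
    ``S{chrom}_{pos}``; multi-site markers are named
    ``{chrom}_BLOCK_{start}_{end}``.  Requires a fully imputed matrix.
    """
    if genotypes.has_missing():
        raise ValueError(
            "genotype matrix has missing calls; run impute_missing() before "
            "building SNPLDB markers"
        )
    markers: list[SNPLDBMarker] = []
    in_block: set[int] = set()
    for blk in blocks:
        in_block.update(blk.members)
        markers.append(_collapse(genotypes, blk.members, blk.name, blk.chrom, blk.start, blk.end))
    if include_singletons:
        for j in range(genotypes.n_sites):
            if j in in_block:
                continue
            if not genotypes.is_polymorphic(j) or genotypes.site_maf(j) < maf_min:
                continue
            chrom = str(genotypes.chrom[j])
            pos = int(genotypes.pos[j])
            markers.append(
                _collapse(genotypes, [j], f"S{chrom}_{pos}", chrom, pos, pos)
            )
    markers.sort(key=lambda mk: (mk.chrom, mk.start, mk.end))
    return markers


def _collapse(
    genotypes: GenotypeMatrix,
    sites: list[int],
    marker_id: str,
    chrom: str,
    start: int,
    end: int,
) -> SNPLDBMarker:
    parent_alleles: dict[str, str] = {}
    for idx, parent in enumerate(genotypes.parents):
        parent_alleles[parent] = "".join(
            genotypes.site_base(idx, j) for j in sites
        )
    freqs: dict[str, float] = {}
    n = len(parent_alleles)
    for allele in parent_alleles.values():
        freqs[allele] = freqs.get(allele, 0.0) + 1.0 / n
    maf, div, pic = marker_stats(freqs)
    return SNPLDBMarker(
        marker_id=marker_id,
        chrom=chrom,
        start=start,
        end=end,
        sites=list(sites),
        allele_freqs=freqs,
        parent_alleles=parent_alleles,
        maf=maf,
        gene_diversity=div,
        pic=pic,
    )


class SNPLDBTransformer(BaseEstimator, TransformerMixin):
    """Genotype matrix -> SNPLDB marker matrix, sklearn style.

    ``fit`` imputes missing calls, partitions chromosomes into
    confidence-interval haplotype blocks and collapses them into
    multi-allelic markers; ``transform`` returns the parent x marker allele
    matrix as a DataFrame.

    Attributes
    ----------
    blocks_ : list[LDBlock]
        Accepted multi-site blocks.
    markers_ : list[SNPLDBMarker]
        All markers (blocks + singleton SNPs), sorted by position.
    stats_ : pandas.DataFrame
        Per-marker MAF, gene diversity and PIC.
    """

    def __init__(
        self,
        max_distance: int = 200_000,
        maf_min: float = 0.01,
        strong_ci_low: float = STRONG_CI_LOW,
        strong_ci_high: float = STRONG_CI_HIGH,
        recomb_ci_high: float = RECOMB_CI_HIGH,
        informative_fraction: float = INFORMATIVE_FRACTION,
        grid_step: float = 0.01,
        impute_by_group: bool = False,
        include_singletons: bool = True,
    ):
        self.max_distance = max_distance
        self.maf_min = maf_min
        self.strong_ci_low = strong_ci_low
        self.strong_ci_high = strong_ci_high
        self.recomb_ci_high = recomb_ci_high
        self.informative_fraction = informative_fraction
        self.grid_step = grid_step
        self.impute_by_group = impute_by_group
        self.include_singletons = include_singletons

    def fit(self, genotypes: GenotypeMatrix, y=None) -> "SNPLDBTransformer":
        if not isinstance(genotypes, GenotypeMatrix):
            raise TypeError("fit expects a GenotypeMatrix")
        imputed = (
            impute_missing(genotypes, by_group=self.impute_by_group)
            if genotypes.has_missing()
            else genotypes
        )
        self.imputed_ = imputed
        self.blocks_ = gabriel_blocks(
            imputed,
            max_distance=self.max_distance,
            maf_min=self.maf_min,
            strong_ci_low=self.strong_ci_low,
            strong_ci_high=self.strong_ci_high,
            recomb_ci_high=self.recomb_ci_high,
            informative_fraction=self.informative_fraction,
            grid_step=self.grid_step,
        )
        self.markers_ = build_snpldb(
            imputed,
            self.blocks_,
            maf_min=self.maf_min,
            include_singletons=self.include_singletons,
        )
        self.stats_ = pd.DataFrame(
            [
                {
                    "marker_id": mk.marker_id,
                    "chrom": mk.chrom,
                    "start": mk.start,
                    "end": mk.end,
                    "n_sites": len(mk.sites),
                    "n_alleles": mk.n_alleles,
                    "maf": mk.maf,
                    "gene_diversity": mk.gene_diversity,
                    "pic": mk.pic,
                }
                for mk in self.markers_
            ]
        )
        return self

    def transform(self, genotypes: GenotypeMatrix | None = None) -> pd.DataFrame:
        """Parent x marker matrix of allele strings for the fitted markers."""
        if not hasattr(self, "markers_"):
            raise AttributeError("SNPLDBTransformer is not fitted; call fit() first")
        source = self.imputed_
        if genotypes is not None and genotypes is not source:
            if genotypes.has_missing():
                genotypes = impute_missing(genotypes, by_group=self.impute_by_group)
            source = genotypes
        data = {}
        for mk in self.markers_:
            data[mk.marker_id] = [
                "".join(source.site_base(i, j) for j in mk.sites)
                for i in range(source.n_parents)
            ]
        return pd.DataFrame(data, index=source.parents)
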