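"""Synthetic data with planted ground truth for every pipeline stage.

Two generators cover the pipeline's inputs:

* :func:`simulate_parents` / :func:`simulate_crosses` emulate the
  structure of a hybrid-rice NCII breeding trial: fully homozygous parental
  genotypes organised in LD blocks (each parent draws one haplotype from a
  small per-block repertoire, so within-block D' is high and between-block
  sites are independent), and replication-level F1 phenotypes built as

      y = grand_mean + g_female + g_male + SCA + rep effect + noise

  where the parental GCA values ``g`` are sums of planted causal
  SNPLDB-allele effects, centred within each role group so they satisfy
  the NCII sum-to-zero constraint, and the SCA matrix is double-centred to
  stay orthogonal to GCA.

* :func:`simulate_reference` builds a small random reference genome with
  toy gene models (exons, CDS, UTRs on both strands) plus SNPs, for the
  annotation stage.

All randomness flows from ``SimConfig.seed``; a fixed seed gives
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .datatypes import MISSING, CrossTable, GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_parents",
    "simulate_crosses",
    "simulate_reference",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic NCII trial.

    Defaults emulate a hybrid-rice breeding panel of 33 inbred parents —
    21 female (CMS) x 12 male (restorer) lines crossed in one full
    factorial with three field replications — and a genome of LD blocks
    with small haplotype repertoires.  Effect scales are in trait units
    around ``grand_mean``.
    """

    n_female: int = 21
    n_male: int = 12
    n_chromosomes: int = 3
    n_blocks_per_chrom: int = 6
    snps_per_block: tuple[int, int] = (2, 6)
    haplotypes_per_block: int = 3
    inter_block_gap: int = 60_000
    block_span: tuple[int, int] = (2_000, 120_000)
    maf_floor: float = 0.10
    missing_rate: float = 0.02
    n_causal_blocks: int = 4
    allele_effect_sd: float = 1.0
    sca_sd: float = 0.5
    rep_effect_sd: float = 0.5
    noise_sd: float = 1.0
    n_reps: int = 3
    grand_mean: float = 100.0
    n_traits: int = 3
    group_label: str = "sim"
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_female": self.n_female,
            "n_male": self.n_male,
            "n_chromosomes": self.n_chromosomes,
            "n_blocks_per_chrom": self.n_blocks_per_chrom,
            "haplotypes_per_block": self.haplotypes_per_block,
            "n_reps": self.n_reps,
            "n_traits": self.n_traits,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name} must be >= 1 (got {v})")
        if self.n_causal_blocks < 0:
            raise ValueError("n_causal_blocks must be >= 0")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if not (0 <= self.maf_floor < 0.5):
            raise ValueError("maf_floor must be in [0, 0.5)")
        lo, hi = self.snps_per_block
        if lo < 1 or hi < lo:
            raise ValueError("snps_per_block must be an increasing range with min >= 1")
        lo, hi = self.block_span
        if lo < 1 or hi < lo:
            raise ValueError("block_span must be an increasing range with min >= 1")
        if self.inter_block_gap < 1:
            raise ValueError("inter_block_gap must be >= 1")
        n_parents = self.n_female + self.n_male
        if self.haplotypes_per_block > n_parents:
            raise ValueError(
                f"haplotypes_per_block ({self.haplotypes_per_block}) exceeds the "
                f"number of parents ({n_parents})"
            )
        for name in ("allele_effect_sd", "sca_sd", "rep_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_parents(self) -> int:
        return self.n_female + self.n_male

    @property
    def traits(self) -> list[str]:
        return [f"T{k + 1}" for k in range(self.n_traits)]

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimTruth:
    """Planted ground truth of one simulation.

    ``true_blocks`` records (chrom, start, end, member site indices);
    ``causal_markers`` maps block name -> trait -> allele string -> effect;
    ``true_gca`` maps parent -> trait -> g (centred within role group);
    ``true_sca`` maps (female, male) -> trait -> s (filled by
    :func:`simulate_crosses`).
    """

    true_blocks: list[tuple[str, int, int, list[int]]] = field(default_factory=list)
    causal_markers: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)
    true_gca: dict[str, dict[str, float]] = field(default_factory=dict)
    true_sca: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def block_names(self) -> list[str]:
        return [f"{c}_BLOCK_{s}_{e}" for c, s, e, _m in self.true_blocks]


def _parent_names(config: SimConfig) -> tuple[list[str], list[str]]:
    females = [f"CMS{k + 1:02d}" for k in range(config.n_female)]
    males = [f"R{k + 1:02d}" for k in range(config.n_male)]
    return females, males


def _draw_block_repertoire(
    rng: np.random.Generator, n_snps: int, n_hap: int, n_parents: int, maf_floor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Haplotype repertoire (n_hap x n_snps binary) and parent assignment.

    Redraws until every site is polymorphic with frequency inside
    [maf_floor, 1 - maf_floor] across the assigned parents (skipped when
    the repertoire has a single haplotype, which is monomorphic by
    design).
    """
    for _attempt in range(10_000):
        haps = rng.integers(0, 2, size=(n_hap, n_snps))
        if n_hap > 1 and len({tuple(h) for h in haps}) < n_hap:
            continue
        assign = rng.integers(0, n_hap, size=n_parents)
        if n_hap == 1:
            return haps, assign
        freqs = haps[assign].mean(axis=0)
        if ((freqs >= maf_floor) & (freqs <= 1 - maf_floor)).all():
            return haps, assign
    raise RuntimeError(
        "could not draw a block haplotype repertoire satisfying maf_floor; "
        "lower maf_floor or increase the number of parents"
    )


def simulate_parents(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Generate homozygous parental genotypes with planted LD blocks.

    Each block draws a repertoire of ``haplotypes_per_block`` distinct
    binary haplotypes and assigns each parent one of them, injects missing
    calls at ``missing_rate`` (guaranteeing at least one typed parent per
    site), and records block boundaries, causal-allele effects and the
    implied per-parent GCA values in the returned :class:`SimTruth`.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    females, males = _parent_names(config)
    parents = females + males
    n_par = config.n_parents

    chroms: list[str] = []
    pos: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    columns: list[np.ndarray] = []
    block_haplotypes: list[list[str]] = []  # per block: parent haplotype base-strings
    truth = SimTruth()

    site_index = 0
    for c in range(config.n_chromosomes):
        chrom = str(c + 1)
        cursor = 10_000
        for _b in range(config.n_blocks_per_chrom):
            span = int(rng.integers(config.block_span[0], config.block_span[1] + 1))
            n_snps = int(
                rng.integers(config.snps_per_block[0], config.snps_per_block[1] + 1)
            )
            window = np.arange(cursor, cursor + span + 1)
            sites = np.sort(rng.choice(window, size=min(n_snps, window.size), replace=False))
            haps, assign = _draw_block_repertoire(
                rng, len(sites), config.haplotypes_per_block, n_par, config.maf_floor
            )
            member_idx = list(range(site_index, site_index + len(sites)))
            site_bases = []
            for k, p in enumerate(sites):
                ref, alt = rng.choice(_BASES, size=2, replace=False)
                chroms.append(chrom)
                pos.append(int(p))
                refs.append(str(ref))
                alts.append(str(alt))
                columns.append(haps[assign, k].astype(np.int8))
                site_bases.append((str(ref), str(alt)))
            block_haplotypes.append(
                [
                    "".join(site_bases[k][haps[assign[i], k]] for k in range(len(sites)))
                    for i in range(n_par)
                ]
            )
            truth.true_blocks.append(
                (chrom, int(sites[0]), int(sites[-1]), member_idx)
            )
            cursor += span + config.inter_block_gap
            site_index += len(sites)

    calls = np.column_stack(columns).astype(np.int8)

    # inject missing calls, keeping every site typed in >= 1 parent
    if config.missing_rate > 0:
        miss = rng.random(calls.shape) < config.missing_rate
        full = miss.all(axis=0)
        for j in np.flatnonzero(full):
            keep = rng.integers(0, n_par)
            miss[keep, j] = False
        calls[miss] = MISSING

    gm = GenotypeMatrix(
        parents=parents,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=calls,
        groups={p: config.group_label for p in parents},
    )

    _plant_effects(config, rng, gm, truth, block_haplotypes, females, males)
    return gm, truth


def _plant_effects(
    config: SimConfig,
    rng: np.random.Generator,
    gm: GenotypeMatrix,
    truth: SimTruth,
    block_haplotypes: list[list[str]],
    females: list[str],
    males: list[str],
) -> None:
    """Choose causal blocks, draw per-allele effects and derive true GCA.

    Allele strings come from the pre-missingness haplotype assignment, so
    the planted truth is exact regardless of injected missing calls.
    """
    polymorphic = [
        k
        for k, (_c, _s, _e, members) in enumerate(truth.true_blocks)
        if config.haplotypes_per_block > 1 and len(members) >= 1
    ]
    n_causal = min(config.n_causal_blocks, len(polymorphic))
    causal_idx = sorted(rng.choice(polymorphic, size=n_causal, replace=False)) if n_causal else []

    traits = config.traits
    raw_g = {p: {t: 0.0 for t in traits} for p in gm.parents}
    for k in causal_idx:
        chrom, start, end, members = truth.true_blocks[k]
        name = f"{chrom}_BLOCK_{start}_{end}"
        parent_strings = block_haplotypes[k]
        alleles = sorted(set(parent_strings))
        effects: dict[str, dict[str, float]] = {}
        for t in traits:
            per_allele = {
                a: float(rng.normal(0.0, config.allele_effect_sd)) for a in alleles
            }
            effects[t] = per_allele
            for p, s in zip(gm.parents, parent_strings):
                raw_g[p][t] += per_allele[s]
        truth.causal_markers[name] = effects

    # centre within role group so the NCII sum-to-zero constraint holds
    for t in traits:
        for role_parents in (females, males):
            mean = float(np.mean([raw_g[p][t] for p in role_parents]))
            for p in role_parents:
                raw_g[p][t] -= mean
    truth.true_gca = raw_g


def simulate_crosses(
    genotypes: GenotypeMatrix, truth: SimTruth, config: SimConfig
) -> CrossTable:
    """Generate the full-factorial NCII phenotype table.

    Every female x male pair appears with ``n_reps`` replications; record
    values are grand_mean + g_f + g_m + s_fm + rep effect + noise.  The
    SCA matrix is drawn i.i.d. normal and double-centred per trait; the
    double-centring is stored back into ``truth.true_sca``.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    females, males = _parent_names(config)
    for p in females + males:
        if p not in genotypes.parents:
            raise ValueError(f"parent {p!r} not present in the genotype matrix")
    if not females or not males:
        raise ValueError("both role groups must be non-empty")
    traits = config.traits

    sca = {}
    for t in traits:
        m = rng.normal(0.0, config.sca_sd, size=(len(females), len(males)))
        if config.sca_sd > 0 and len(females) > 1 and len(males) > 1:
            m = m - m.mean(axis=1, keepdims=True) - m.mean(axis=0, keepdims=True) + m.mean()
        else:
            m = np.zeros_like(m)
        sca[t] = m
    rep_eff = {
        t: rng.normal(0.0, config.rep_effect_sd, size=config.n_reps) for t in traits
    }

    rows = []
    for fi, f in enumerate(females):
        for mi, m in enumerate(males):
            truth.true_sca[(f, m)] = {t: float(sca[t][fi, mi]) for t in traits}
            for rep in range(1, config.n_reps + 1):
                row = {
                    "cross_id": f"{f}x{m}",
                    "female": f,
                    "male": m,
                    "group": config.group_label,
                    "rep": rep,
                }
                for t in traits:
                    noise = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
                    row[t] = (
                        config.grand_mean
                        + truth.true_gca[f][t]
                        + truth.true_gca[m][t]
                        + sca[t][fi, mi]
                        + rep_eff[t][rep - 1]
                        + noise
                    )
                rows.append(row)
    return CrossTable.from_dataframe(pd.DataFrame(rows), check_balance=False)


# ---------------------------------------------------------------------------
# toy reference genome + gene models for the annotation stage


def simulate_reference(
    seed: int = 0,
    n_chromosomes: int = 2,
    chrom_length: int = 20_000,
    n_genes_per_chrom: int = 3,
    n_snps: int = 60,
):
    """Random reference sequences, toy gene models and SNPs.

    Genes have 5' UTR, a multi-exon CDS (length a multiple of three, ATG
    start, no internal stops by construction of the codon pool) and 3' UTR,
    on alternating strands.  Returns ``(sequences, gene_models, snps)``
    where ``sequences`` maps chrom -> str, ``gene_models`` is a list of
    :class:`hybridgca.annotate.GeneModel` and ``snps`` is a DataFrame with
    chrom, pos (1-based), ref, alt.
    """
    from .annotate import GeneModel  # local import to avoid a cycle

    rng = np.random.default_rng([seed, 2])
    sequences: dict[str, np.ndarray] = {}
    models: list[GeneModel] = []
    snp_rows = []
    for c in range(n_chromosomes):
        chrom = str(c + 1)
        seq = rng.choice(_BASES, size=chrom_length)
        gene_span = chrom_length // (n_genes_per_chrom + 1)
        for g in range(n_genes_per_chrom):
            left = g * gene_span + 200
            strand = "+" if (g + c) % 2 == 0 else "-"
            utr5_len = int(rng.integers(30, 90))
            utr3_len = int(rng.integers(30, 90))
            n_exon_cds = int(rng.integers(2, 4))
            cds_lens = [int(rng.integers(30, 120)) for _ in range(n_exon_cds)]
            total = sum(cds_lens)
            cds_lens[-1] += (3 - total % 3) % 3
            intron_lens = [int(rng.integers(40, 150)) for _ in range(n_exon_cds - 1)]
            # genomic layout left->right in transcript order for '+' strand
            cursor = left
            utr5 = (cursor, cursor + utr5_len - 1)
            cursor += utr5_len
            cds_iv = []
            for k, ln in enumerate(cds_lens):
                cds_iv.append((cursor, cursor + ln - 1))
                cursor += ln
                if k < len(intron_lens):
                    cursor += intron_lens[k]
            utr3 = (cursor, cursor + utr3_len - 1)
            cursor += utr3_len
            if strand == "-":
                # mirror labels: transcript order runs right->left, so the
                # leftmost interval is the 3' UTR
                utr5, utr3 = (utr3[0], utr3[1]), (utr5[0], utr5[1])
            # exon intervals = first/last CDS chunks extended by the UTRs
            exons = []
            first = (min(utr5[0], utr3[0], cds_iv[0][0]), cds_iv[0][1])
            exons.append(first)
            for iv in cds_iv[1:-1]:
                exons.append(iv)
            if len(cds_iv) > 1:
                last = (cds_iv[-1][0], max(utr5[1], utr3[1], cds_iv[-1][1]))
                exons.append(last)
            else:
                exons[0] = (exons[0][0], max(utr5[1], utr3[1], cds_iv[0][1]))
            # write a clean CDS into the sequence: ATG + sense codons + stop
            _write_cds(rng, seq, cds_iv, strand)
            models.append(
                GeneModel(
                    gene_id=f"g{chrom}_{g + 1}",
                    transcript_id=f"g{chrom}_{g + 1}.1",
                    chrom=chrom,
                    strand=strand,
                    exons=exons,
                    cds=cds_iv,
                    phase=0,
                    utr5=[utr5],
                    utr3=[utr3],
                )
            )
        sequences[chrom] = seq
        positions = np.sort(
            rng.choice(np.arange(1, chrom_length + 1), size=n_snps, replace=False)
        )
        for p in positions:
            ref = str(seq[p - 1])
            alt = str(rng.choice(_BASES[_BASES != ref]))
            snp_rows.append({"chrom": chrom, "pos": int(p), "ref": ref, "alt": alt})
    seq_str = {c: "".join(s) for c, s in sequences.items()}
    return seq_str, models, pd.DataFrame(snp_rows)


_SENSE_CODONS = [
    c1 + c2 + c3
    for c1 in "ACGT"
    for c2 in "ACGT"
    for c3 in "ACGT"
    if c1 + c2 + c3 not in ("TAA", "TAG", "TGA")
]


def _write_cds(rng: np.random.Generator, seq: np.ndarray, cds_iv, strand: str) -> None:
    """Fill CDS intervals with ATG + sense codons + a stop, strand-aware."""
    length = sum(e - s + 1 for s, e in cds_iv)
    n_codons = length // 3
    codons = ["ATG"]
    codons += [str(rng.choice(_SENSE_CODONS)) for _ in range(max(n_codons - 2, 0))]
    if n_codons > 1:
        codons.append(str(rng.choice(["TAA", "TAG", "TGA"])))
    cds_seq = "".join(codons)[:length]
    if strand == "-":
        cds_seq = _revcomp(cds_seq)
        # transcript order is right-to-left; genomic fill stays left-to-right
    k = 0
    for s, e in cds_iv:
        for p in range(s, e + 1):
            seq[p - 1] = cds_seq[k]
            k += 1


_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]
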