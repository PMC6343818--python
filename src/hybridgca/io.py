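"""Readers and writers for the pipeline's file formats.

Genotypes travel as VCF v4.2 (biallelic SNPs, GT of 0/0, 1/1 or ./. —
inbred lines only, a heterozygous call is rejected), phenotypes as a TSV
with header ``cross_id female male group rep <trait...>``, and stage
outputs as TSVs whose leading comment lines declare the coordinate
convention.  Reading uses cyvcf2; writing emits plain text so outputs
stay diff-able and deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import MISSING, CrossTable, GenotypeMatrix, HeterozygousCallError

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_phenotypes",
    "write_phenotypes",
    "write_fasta",
    "write_gff3",
    "write_truth",
    "RunConfig",
    "sha256_file",
]


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Load a VCF of homozygous biallelic SNPs into a GenotypeMatrix.

    Multi-allelic records, indels and heterozygous genotypes are rejected
    (the panel is inbred; one allele per site per parent).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    parents = list(vcf.samples)
    chroms: list[str] = []
    pos: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    cols: list[np.ndarray] = []
    for var in vcf:
        if len(var.ALT) != 1:
            raise ValueError(
                f"multi-allelic record at {var.CHROM}:{var.POS}; split or filter first"
            )
        ref, alt = var.REF, var.ALT[0]
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"indel at {var.CHROM}:{var.POS}; only SNPs are supported")
        col = np.empty(len(parents), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            if a < 0 and b < 0:
                col[i] = MISSING
            elif a == b:
                col[i] = a
            else:
                raise HeterozygousCallError(
                    f"heterozygous genotype {a}/{b} for sample {parents[i]} at "
                    f"{var.CHROM}:{var.POS}; the panel must be inbred "
                    "(fully homozygous)"
                )
        chroms.append(var.CHROM)
        pos.append(var.POS)
        refs.append(ref)
        alts.append(alt)
        cols.append(col)
    if not cols:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        parents=parents,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(pos, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        calls=np.column_stack(cols),
    )


def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write a minimal deterministic VCF v4.2 (1-based POS, GT only)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=hybridgca",
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    seen: list[str] = []
    for c in genotypes.chrom:
        if c not in seen:
            seen.append(str(c))
    for c in seen:
        mx = int(genotypes.pos[genotypes.chrom == c].max())
        lines.append(f"##contig=<ID={c},length={mx + 1000}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header += genotypes.parents
    lines.append("\t".join(header))
    gt_map = {0: "0/0", 1: "1/1", MISSING: "./."}
    for j in range(genotypes.n_sites):
        row = [
            str(genotypes.chrom[j]),
            str(int(genotypes.pos[j])),
            ".",
            str(genotypes.ref[j]),
            str(genotypes.alt[j]),
            ".",
            "PASS",
            ".",
            "GT",
        ]
        row += [gt_map[int(v)] for v in genotypes.calls[:, j]]
        lines.append("\t".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_phenotypes(path: str | Path) -> CrossTable:
    """Load the phenotype TSV into a validated CrossTable."""
    df = pd.read_csv(path, sep="\t", comment="#")
    return CrossTable.from_dataframe(df)


def write_phenotypes(crosses: CrossTable, path: str | Path) -> None:
    crosses.df.to_csv(path, sep="\t", index=False)


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), width):
                fh.write(seq[k : k + width] + "\n")


def write_gff3(gene_models, path: str | Path) -> None:
    """Emit toy gene models as GFF3 (gene/mRNA/exon/CDS/UTR features)."""
    lines = ["##gff-version 3"]
    for gm in gene_models:
        s, e = gm.start, gm.end
        attrs = f"ID={gm.gene_id}"
        lines.append(
            f"{gm.chrom}\thybridgca\tgene\t{s}\t{e}\t.\t{gm.strand}\t.\t{attrs}"
        )
        lines.append(
            f"{gm.chrom}\thybridgca\tmRNA\t{s}\t{e}\t.\t{gm.strand}\t.\t"
            f"ID={gm.transcript_id};Parent={gm.gene_id}"
        )
        for a, b in gm.exons:
            lines.append(
                f"{gm.chrom}\thybridgca\texon\t{a}\t{b}\t.\t{gm.strand}\t.\t"
                f"Parent={gm.transcript_id}"
            )
        # CDS phase per chunk, accumulated in transcript order
        chunks = sorted(gm.cds, reverse=(gm.strand == "-"))
        phase = gm.phase
        for a, b in chunks:
            lines.append(
                f"{gm.chrom}\thybridgca\tCDS\t{a}\t{b}\t.\t{gm.strand}\t{phase}\t"
                f"Parent={gm.transcript_id}"
            )
            phase = (3 - ((b - a + 1 - phase) % 3)) % 3
        for a, b in gm.utr5:
            lines.append(
                f"{gm.chrom}\thybridgca\tfive_prime_UTR\t{a}\t{b}\t.\t{gm.strand}\t.\t"
                f"Parent={gm.transcript_id}"
            )
        for a, b in gm.utr3:
            lines.append(
                f"{gm.chrom}\thybridgca\tthree_prime_UTR\t{a}\t{b}\t.\t{gm.strand}\t.\t"
                f"Parent={gm.transcript_id}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_truth(truth, path: str | Path) -> None:
    """Serialise a SimTruth sidecar as JSON."""
    payload = {
        "true_blocks": [
            {"chrom": c, "start": s, "end": e, "members": m}
            for c, s, e, m in truth.true_blocks
        ],
        "causal_markers": truth.causal_markers,
        "true_gca": truth.true_gca,
        "true_sca": {f"{f}x{m}": v for (f, m), v in truth.true_sca.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# run configuration

_CONFIG_FIELDS: dict[str, type] = {
    "vcf": str,
    "phenotypes": str,
    "gff3": str,
    "fasta": str,
    "output_dir": str,
    "alpha": float,
    "max_distance": int,
    "maf_min": float,
    "strong_ci_low": float,
    "strong_ci_high": float,
    "recomb_ci_high": float,
    "informative_fraction": float,
    "min_carriers": int,
    "n_reps": int,
    "seed": int,
    "verbosity": int,
}


@dataclasses.dataclass
class RunConfig:
    """End-to-end pipeline configuration.

    Loadable from a flat ``key = value`` text file; unknown keys are
    rejected (silent typos corrupt reproduction).
    """

    vcf: str = ""
    phenotypes: str = ""
    gff3: str = ""
    fasta: str = ""
    output_dir: str = "hybridgca_out"
    alpha: float = 0.01
    max_distance: int = 200_000
    maf_min: float = 0.01
    strong_ci_low: float = 0.70
    strong_ci_high: float = 0.98
    recomb_ci_high: float = 0.90
    informative_fraction: float = 0.95
    min_carriers: int = 2
    n_reps: int = 3
    seed: int = 0
    verbosity: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.max_distance < 1:
            raise ValueError("max_distance must be >= 1 bp")
        if not (0 <= self.maf_min < 0.5):
            raise ValueError("maf_min must be in [0, 0.5)")
        for name in ("strong_ci_low", "strong_ci_high", "recomb_ci_high", "informative_fraction"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.min_carriers < 1:
            raise ValueError("min_carriers must be >= 1")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        kwargs: dict[str, object] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in _CONFIG_FIELDS:
                raise ValueError(f"{path}:{lineno}: unknown configuration key {key!r}")
            kwargs[key] = _CONFIG_FIELDS[key](value)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
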