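"""SNP functional annotation: genomic context, coding effect, Ts/Tv.

Each biallelic SNP is placed in exactly one region class —
intergenic, exon, intron, 5' UTR, 3' UTR or splice — using the precedence
CDS(exon) > UTR > splice > intron > intergenic when features overlap
(a single class per SNP is reported, so a convention is required).  The
splice region covers the two intronic bases at each exon-intron junction
(donor/acceptor), the common annotator default; the width is
configurable.  SNPs inside a CDS are additionally classified as
synonymous, missense or nonsense by mutating the affected codon and
translating with the standard nuclear code, handling the minus strand by
reverse complement.  Substitutions are classified as transitions
(C/T, G/A) or transversions (C/G, T/A, A/C, G/T).

Gene models come from a GFF3 file (via :mod:`gffutils`); only the first
transcript of each gene is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from Bio.Seq import Seq

__all__ = [
    "GeneModel",
    "SnpAnnotation",
    "load_gene_models",
    "classify_region",
    "coding_effect",
    "ts_tv",
    "annotate_snps",
    "summarize_annotation",
]

REGION_CLASSES = ["exon", "five_prime_utr", "three_prime_utr", "splice", "intron", "intergenic"]
CODING_EFFECTS = ["none", "synonymous", "missense", "nonsense"]

#: intronic bases on each side of an exon-intron junction called "splice"
SPLICE_WIDTH = 2

_VALID = set("ACGT")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_COMP = str.maketrans("ACGT", "TGCA")


@dataclass
class GeneModel:
    """One transcript's structure: exons, CDS chunks and UTRs (1-based,
    inclusive genomic intervals, sorted left to right)."""

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    phase: int = 0
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _e in self.exons) if self.exons else min(s for s, _e in self.cds)

    @property
    def end(self) -> int:
        return max(e for _s, e in self.exons) if self.exons else max(e for _s, e in self.cds)

    def introns(self) -> list[tuple[int, int]]:
        iv = sorted(self.exons)
        return [
            (iv[k][1] + 1, iv[k + 1][0] - 1)
            for k in range(len(iv) - 1)
            if iv[k + 1][0] - iv[k][1] > 1
        ]


@dataclass
class SnpAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    region: str
    effect: str  # none / synonymous / missense / nonsense
    substitution: str  # transition / transversion
    pair: str  # unordered pair, e.g. "C/T"
    gene_id: str = ""


def ts_tv(ref: str, alt: str) -> str:
    """Classify a substitution: 'transition' or 'transversion'."""
    ref, alt = ref.upper(), alt.upper()
    if ref not in _VALID or alt not in _VALID:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}/{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical; not a substitution")
    pair = {ref, alt}
    if pair <= _PURINES or pair <= _PYRIMIDINES:
        return "transition"
    return "transversion"


def load_gene_models(gff3_path: str) -> list[GeneModel]:
    """Parse gene models from GFF3, keeping the first mRNA per gene.

    Requires gene/mRNA/exon/CDS features; five_prime_UTR and
    three_prime_UTR features are used when present.
    """
    import gffutils

    with open(gff3_path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(
                    f"malformed GFF3 {gff3_path!r} at line {lineno}: "
                    f"expected 9 tab-separated columns, found {len(fields)}"
                )
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise ValueError(
                    f"malformed GFF3 {gff3_path!r} at line {lineno}: "
                    "start/end are not integers"
                )
    try:
        db = gffutils.create_db(
            str(gff3_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises various parse errors
        raise ValueError(f"malformed GFF3 {gff3_path!r}: {exc}") from exc
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        mrnas = list(db.children(gene, featuretype="mRNA", order_by="start"))
        if not mrnas:
            continue
        tx = mrnas[0]
        exons = [(f.start, f.end) for f in db.children(tx, featuretype="exon", order_by="start")]
        cds = [(f.start, f.end) for f in db.children(tx, featuretype="CDS", order_by="start")]
        utr5 = [
            (f.start, f.end)
            for f in db.children(tx, featuretype="five_prime_UTR", order_by="start")
        ]
        utr3 = [
            (f.start, f.end)
            for f in db.children(tx, featuretype="three_prime_UTR", order_by="start")
        ]
        phase = 0
        cds_feats = list(db.children(tx, featuretype="CDS", order_by="start"))
        if cds_feats:
            first = cds_feats[0] if tx.strand == "+" else cds_feats[-1]
            try:
                phase = int(first.frame)
            except (TypeError, ValueError):
                phase = 0
        models.append(
            GeneModel(
                gene_id=gene.id,
                transcript_id=tx.id,
                chrom=gene.seqid,
                strand=tx.strand,
                exons=exons or cds,
                cds=cds,
                phase=phase,
                utr5=utr5,
                utr3=utr3,
            )
        )
    return models


def _in_any(pos: int, intervals: list[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in intervals)


def classify_region(
    chrom: str,
    pos: int,
    gene_models: list[GeneModel],
    splice_width: int = SPLICE_WIDTH,
) -> tuple[str, GeneModel | None]:
    """Region class of a position, with the gene model that determined it.

    Precedence across overlapping features and genes:
    CDS (reported as ``exon``) > UTR > splice > intron > exon outside any
    CDS/UTR annotation > intergenic.
    """
    best: tuple[int, str, GeneModel | None] = (99, "intergenic", None)
    rank = {"exon_cds": 0, "five_prime_utr": 1, "three_prime_utr": 1,
            "splice": 2, "intron": 3, "exon_nc": 4}
    for gm in gene_models:
        if gm.chrom != chrom or not (gm.start <= pos <= gm.end):
            continue
        label: str | None = None
        if _in_any(pos, gm.cds):
            label, key = "exon", "exon_cds"
        elif _in_any(pos, gm.utr5):
            label, key = "five_prime_utr", "five_prime_utr"
        elif _in_any(pos, gm.utr3):
            label, key = "three_prime_utr", "three_prime_utr"
        else:
            key = None
            for s, e in gm.introns():
                if s <= pos <= e:
                    near_donor = pos - s < splice_width
                    near_acceptor = e - pos < splice_width
                    if near_donor or near_acceptor:
                        label, key = "splice", "splice"
                    else:
                        label, key = "intron", "intron"
                    break
            if label is None and _in_any(pos, gm.exons):
                label, key = "exon", "exon_nc"
        if label is not None and rank[key] < best[0]:
            best = (rank[key], label, gm)
    return best[1], best[2]


def coding_effect(
    cds_sequence: str,
    offset: int,
    ref: str,
    alt: str,
    strand: str = "+",
) -> str:
    """Effect of a substitution inside a CDS.

    ``cds_sequence`` is the spliced, phase-trimmed CDS in transcript
    orientation (starts at codon position 1); ``offset`` is the 0-based
    position of the site within it.  ``ref``/``alt`` are given on the
    transcript strand already when ``strand`` is '+', and on the genome
    (plus) strand when ``strand`` is '-' (they are complemented
    internally).  Returns 'synonymous', 'missense' or 'nonsense'.
    """
    ref, alt = ref.upper(), alt.upper()
    if ref == alt:
        raise ValueError("ref and alt are identical; not a valid SNP")
    if ref not in _VALID or alt not in _VALID:
        raise ValueError(f"bases must be A/C/G/T, got {ref!r}/{alt!r}")
    if strand == "-":
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    if not (0 <= offset < len(cds_sequence)):
        raise ValueError("offset outside the CDS")
    if cds_sequence[offset].upper() != ref:
        raise ValueError(
            f"reference base mismatch at CDS offset {offset}: "
            f"CDS has {cds_sequence[offset]!r}, variant says {ref!r}"
        )
    codon_start = offset - offset % 3
    codon = cds_sequence[codon_start : codon_start + 3].upper()
    if len(codon) < 3:
        raise ValueError("truncated terminal codon; CDS length not a multiple of 3")
    within = offset % 3
    mutated = codon[:within] + alt + codon[within + 1 :]
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq(mutated).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def _cds_context(gm: GeneModel, sequences: dict[str, str]) -> tuple[str, dict[int, int]]:
    """Spliced phase-trimmed CDS (transcript orientation) and a genomic
    position -> CDS offset map."""
    seq = sequences[gm.chrom]
    chunks: list[str] = []
    pos_map: dict[int, int] = {}
    offset = 0
    for s, e in sorted(gm.cds):
        chunks.append(seq[s - 1 : e])
        for p in range(s, e + 1):
            pos_map[p] = offset
            offset += 1
    cds_seq = "".join(chunks).upper()
    if gm.strand == "-":
        n = len(cds_seq)
        cds_seq = cds_seq.translate(_COMP)[::-1]
        pos_map = {p: n - 1 - o for p, o in pos_map.items()}
    if gm.phase:
        n = len(cds_seq)
        cds_seq = cds_seq[gm.phase :]
        pos_map = {p: o - gm.phase for p, o in pos_map.items() if o >= gm.phase}
    return cds_seq, pos_map


def annotate_snps(
    snps: pd.DataFrame,
    gene_models: list[GeneModel],
    sequences: dict[str, str] | None = None,
    splice_width: int = SPLICE_WIDTH,
) -> list[SnpAnnotation]:
    """Annotate a table of SNPs (columns chrom, pos, ref, alt).

    ``sequences`` (chrom -> sequence string) enables coding-effect calls;
    without it every exonic SNP gets effect 'none'.  CDSs whose
    phase-corrected length is not a multiple of three are skipped for
    coding effect with a warning.
    """
    cds_cache: dict[str, tuple[str, dict[int, int]] | None] = {}
    out: list[SnpAnnotation] = []
    for row in snps.itertuples(index=False):
        chrom, pos, ref, alt = str(row.chrom), int(row.pos), str(row.ref), str(row.alt)
        if len(ref) != 1 or len(alt) != 1:
            raise ValueError(f"only single-base substitutions are annotated: {chrom}:{pos}")
        region, gm = classify_region(chrom, pos, gene_models, splice_width=splice_width)
        effect = "none"
        gene_id = gm.gene_id if gm is not None else ""
        if region == "exon" and gm is not None and sequences is not None and _in_any(pos, gm.cds):
            cached = cds_cache.get(gm.transcript_id, "unset")
            if cached == "unset":
                cds_seq, pos_map = _cds_context(gm, sequences)
                if len(cds_seq) % 3 != 0:
                    warnings.warn(
                        f"CDS of {gm.transcript_id} has length {len(cds_seq)} "
                        "after phase correction (not a multiple of 3); coding "
                        "effects skipped",
                        stacklevel=2,
                    )
                    cached = None
                else:
                    cached = (cds_seq, pos_map)
                cds_cache[gm.transcript_id] = cached
            if cached is not None:
                cds_seq, pos_map = cached
                if pos in pos_map:
                    effect = coding_effect(cds_seq, pos_map[pos], ref, alt, gm.strand)
        out.append(
            SnpAnnotation(
                chrom=chrom,
                pos=pos,
                ref=ref,
                alt=alt,
                region=region,
                effect=effect,
                substitution=ts_tv(ref, alt),
                pair="/".join(sorted((ref.upper(), alt.upper()))),
                gene_id=gene_id,
            )
        )
    return out


def summarize_annotation(annotations: list[SnpAnnotation]) -> dict[str, pd.Series]:
    """Counts per region class, coding effect, substitution class and
    chromosome; each table sums to the number of SNPs (effects sum over
    the four effect categories including 'none')."""
    df = pd.DataFrame(
        [
            {
                "chrom": a.chrom,
                "region": a.region,
                "effect": a.effect,
                "substitution": a.substitution,
            }
            for a in annotations
        ],
        columns=["chrom", "region", "effect", "substitution"],
    )
    region = df["region"].value_counts().reindex(REGION_CLASSES, fill_value=0)
    effect = df["effect"].value_counts().reindex(CODING_EFFECTS, fill_value=0)
    subst = df["substitution"].value_counts().reindex(
        ["transition", "transversion"], fill_value=0
    )
    per_chrom = df["chrom"].value_counts().sort_index()
    return {
        "region": region,
        "effect": effect,
        "substitution": subst,
        "chromosome": per_chrom,
    }


def annotations_to_frame(annotations: list[SnpAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": a.chrom,
                "pos": a.pos,
                "ref": a.ref,
                "alt": a.alt,
                "region": a.region,
                "effect": a.effect,
                "substitution": a.substitution,
                "pair": a.pair,
                "gene_id": a.gene_id,
            }
            for a in annotations
        ]
    )
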