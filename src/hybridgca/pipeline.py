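"""End-to-end orchestration: GCA -> imputation -> blocks -> SNPLDB ->
association -> favourable-allele mining, with optional SNP annotation.

Every stage writes a TSV under the configured output directory and the run
finishes with a JSON manifest (tool and library versions, parameters, seed,
input checksums) so an identical configuration and inputs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import scipy

from . import __version__
from .annotate import annotate_snps, annotations_to_frame, load_gene_models, summarize_annotation
from .association import SNPLDBAssociation, records_to_frame
from .datatypes import CrossTable, GenotypeMatrix
from .gca import GCAEstimator, profiles_to_frame
from .io import RunConfig, read_phenotypes, read_vcf, sha256_file
from .ld import SNPLDBTransformer

__all__ = ["run_pipeline"]

logger = logging.getLogger(__name__)

_COORD_NOTE = "# coordinates: 1-based, inclusive (VCF convention)\n"
_BED_NOTE = "# coordinates: 0-based, half-open (BED convention)\n"


def _write_tsv(df: pd.DataFrame, path: Path, note: str = _COORD_NOTE, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(note)
        df.to_csv(fh, sep="\t", index=index)


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis; returns the manifest dictionary.

    Raises with a stage-named message on any failure so callers can exit
    non-zero.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": {"name": "hybridgca", "version": __version__},
        "libraries": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "parameters": config.to_dict(),
        "inputs": {},
        "outputs": [],
    }

    def _stage(name: str):
        logger.info("stage: %s", name)

    try:
        _stage("read inputs")
        crosses: CrossTable = read_phenotypes(config.phenotypes)
        genotypes: GenotypeMatrix = read_vcf(config.vcf)
        manifest["inputs"]["phenotypes"] = sha256_file(config.phenotypes)
        manifest["inputs"]["vcf"] = sha256_file(config.vcf)
    except Exception as exc:
        raise RuntimeError(f"[input] {exc}") from exc

    try:
        _stage("gca")
        gca = GCAEstimator(alpha=config.alpha).fit(crosses)
        gca_frame = profiles_to_frame(gca.profiles_, gca.traits_)
        _write_tsv(gca_frame, out / "gca_effects.tsv")
        anova_rows = []
        for (grp, trait), table in gca.anova_.items():
            frame = table.to_frame()
            frame.insert(0, "trait", trait)
            frame.insert(0, "group", grp)
            anova_rows.append(frame)
        _write_tsv(pd.concat(anova_rows, ignore_index=True), out / "anova_hybrids.tsv")
    except Exception as exc:
        raise RuntimeError(f"[gca] {exc}") from exc

    try:
        _stage("blocks + snpldb")
        transformer = SNPLDBTransformer(
            max_distance=config.max_distance,
            maf_min=config.maf_min,
            strong_ci_low=config.strong_ci_low,
            strong_ci_high=config.strong_ci_high,
            recomb_ci_high=config.recomb_ci_high,
            informative_fraction=config.informative_fraction,
        )
        transformer.fit(genotypes)
        blocks_df = pd.DataFrame(
            [
                {
                    "chrom": b.chrom,
                    "start": b.start,
                    "end": b.end,
                    "n_sites": len(b.members),
                    "name": b.name,
                }
                for b in transformer.blocks_
            ],
            columns=["chrom", "start", "end", "n_sites", "name"],
        )
        _write_tsv(blocks_df, out / "blocks.tsv")
        bed = blocks_df.assign(start=blocks_df["start"] - 1)[["chrom", "start", "end", "name"]]
        _write_tsv(bed, out / "blocks.bed", note=_BED_NOTE)
        marker_matrix = transformer.transform(None)
        marker_matrix.index.name = "parent"
        _write_tsv(marker_matrix, out / "marker_matrix.tsv", index=True)
        _write_tsv(transformer.stats_, out / "marker_stats.tsv")
    except Exception as exc:
        raise RuntimeError(f"[snpldb] {exc}") from exc

    try:
        _stage("association")
        gca_table = gca.gca_matrix()
        missing = [p for p in genotypes.parents if p not in gca_table.index]
        if missing:
            raise ValueError(f"no GCA values for genotyped parent(s) {missing[:10]}")
        gca_table = gca_table.loc[genotypes.parents]
        assoc = SNPLDBAssociation(alpha=config.alpha, min_carriers=config.min_carriers)
        assoc.fit(transformer.markers_, gca_table)
        _write_tsv(records_to_frame(assoc.records_), out / "association.tsv")
        fav_df = pd.DataFrame(
            [
                {
                    "trait": f.trait,
                    "marker_id": f.marker_id,
                    "allele": f.allele,
                    "effect": f.effect,
                    "carriers": ",".join(f.carriers),
                }
                for f in assoc.favourable_
            ],
            columns=["trait", "marker_id", "allele", "effect", "carriers"],
        )
        _write_tsv(fav_df, out / "favourable_alleles.tsv")
        _write_tsv(assoc.tally_, out / "parent_tally.tsv", index=True)
        summary = assoc.summary_
        with open(out / "summary.txt", "w") as fh:
            fh.write(
                f"markers: {len(transformer.markers_)}\n"
                f"blocks (multi-site): {len(transformer.blocks_)}\n"
                f"tests: {int(summary['n_tests'])}\n"
                f"significant records (alpha={config.alpha}): "
                f"{int(summary['n_significant'])}\n"
                f"mean R2 among significant (%): {summary['mean_r2_significant']:.1f}\n"
                f"favourable alleles: {len(assoc.favourable_)}\n"
            )
    except Exception as exc:
        raise RuntimeError(f"[association] {exc}") from exc

    if config.gff3 and config.fasta:
        try:
            _stage("annotation")
            from pyfaidx import Fasta

            models = load_gene_models(config.gff3)
            fa = Fasta(config.fasta)
            sequences = {name: str(fa[name][:]) for name in fa.keys()}
            snps = pd.DataFrame(
                {
                    "chrom": genotypes.chrom,
                    "pos": genotypes.pos,
                    "ref": genotypes.ref,
                    "alt": genotypes.alt,
                }
            )
            anns = annotate_snps(snps, models, sequences)
            _write_tsv(annotations_to_frame(anns), out / "annotation.tsv")
            summary_tables = summarize_annotation(anns)
            rows = []
            for kind, series in summary_tables.items():
                for key, count in series.items():
                    rows.append({"table": kind, "class": key, "count": int(count)})
            _write_tsv(pd.DataFrame(rows), out / "annotation_summary.tsv")
            manifest["inputs"]["gff3"] = sha256_file(config.gff3)
            manifest["inputs"]["fasta"] = sha256_file(config.fasta)
        except Exception as exc:
            raise RuntimeError(f"[annotation] {exc}") from exc

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest
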