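"""Core containers shared across pipeline stages.

Two containers travel through the whole pipeline:

* :class:`GenotypeMatrix` — homozygous allele calls of inbred parents at
  biallelic SNP sites (the substrate of LD-block partitioning and SNPLDB
  construction).
* :class:`CrossTable` — replication-level phenotype records of an NCII
  (North Carolina design II) factorial of female x male crosses (the
  substrate of GCA estimation).

Coordinates are VCF conventions throughout: 1-based positions, inclusive
intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: sentinel for a missing homozygous call in ``GenotypeMatrix.calls``
MISSING: int = -1

#: required leading columns of a phenotype table; remaining columns are traits
PHENOTYPE_COLUMNS = ["cross_id", "female", "male", "group", "rep"]


class HeterozygousCallError(ValueError):
    """A genotype violated the inbred (fully homozygous) contract."""


@dataclass
class GenotypeMatrix:
    """Parents x SNP sites matrix of homozygous calls.

    Parameters
    ----------
    parents:
        Parent line identifiers, one per row of ``calls``.
    chrom, pos, ref, alt:
        Per-site arrays: chromosome name, 1-based position, reference and
        alternate single bases.  Sites must be sorted by (chrom, pos) with
        chromosomes contiguous, positions strictly increasing within a
        chromosome.
    calls:
        ``int8`` array of shape (n_parents, n_sites); 0 = ref/ref,
        1 = alt/alt, -1 = missing.  Parents are inbred so a single allele
        index per site suffices.
    groups:
        Optional parent -> subpopulation label (e.g. indica/japonica),
        used by group-aware imputation.
    """

    parents: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    calls: np.ndarray
    groups: dict[str, str] | None = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref, dtype=object)
        self.alt = np.asarray(self.alt, dtype=object)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        n_par, n_sites = len(self.parents), len(self.pos)
        if self.calls.shape != (n_par, n_sites):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{n_par} parents x {n_sites} sites"
            )
        if not np.isin(self.calls, (-1, 0, 1)).all():
            raise ValueError("calls must be 0 (ref), 1 (alt) or -1 (missing)")
        self._check_sorted()

    def _check_sorted(self) -> None:
        seen: set[str] = set()
        prev_chrom: str | None = None
        for j in range(self.n_sites):
            c = self.chrom[j]
            if c != prev_chrom:
                if c in seen:
                    raise ValueError(f"sites of chromosome {c} are not contiguous")
                seen.add(c)
                prev_chrom = c
            elif self.pos[j] <= self.pos[j - 1]:
                raise ValueError(
                    f"positions not strictly increasing on chromosome {c} "
                    f"at index {j} (pos {self.pos[j]})"
                )

    @property
    def n_parents(self) -> int:
        return len(self.parents)

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    def alt_freq(self, j: int) -> float:
        """Alternate-allele frequency at site ``j`` over non-missing parents."""
        col = self.calls[:, j]
        typed = col[col != MISSING]
        if typed.size == 0:
            raise ValueError(f"site {j} has no non-missing calls")
        return float(np.mean(typed == 1))

    def site_maf(self, j: int) -> float:
        """Minor allele frequency at site ``j``: min(p, 1-p) of the alt freq."""
        p = self.alt_freq(j)
        return min(p, 1.0 - p)

    def is_polymorphic(self, j: int) -> bool:
        col = self.calls[:, j]
        typed = col[col != MISSING]
        return typed.size > 0 and bool((typed != typed[0]).any())

    def has_missing(self) -> bool:
        return bool((self.calls == MISSING).any())

    def site_base(self, parent_idx: int, j: int) -> str:
        """Base character carried by ``parent_idx`` at site ``j``."""
        call = self.calls[parent_idx, j]
        if call == MISSING:
            raise ValueError(f"missing call for parent index {parent_idx} at site {j}")
        return str(self.alt[j] if call == 1 else self.ref[j])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            parents=list(self.parents),
            chrom=self.chrom.copy(),
            pos=self.pos.copy(),
            ref=self.ref.copy(),
            alt=self.alt.copy(),
            calls=self.calls.copy(),
            groups=dict(self.groups) if self.groups is not None else None,
        )


@dataclass
class CrossTable:
    """Replication-level NCII phenotype records.

    ``df`` holds one row per (cross, replication) with the columns of
    :data:`PHENOTYPE_COLUMNS` followed by one numeric column per trait.
    """

    df: pd.DataFrame
    traits: list[str] = field(default_factory=list)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, check_balance: bool = True) -> "CrossTable":
        missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"phenotype table missing required column(s): {missing}")
        traits = [c for c in df.columns if c not in PHENOTYPE_COLUMNS]
        if not traits:
            raise ValueError("phenotype table has no trait columns")
        for t in traits:
            vals = pd.to_numeric(df[t], errors="coerce")
            bad = df.index[vals.isna()]
            if len(bad):
                raise ValueError(
                    f"non-numeric or missing value for trait {t!r} at row(s) "
                    f"{list(bad[:5])}"
                )
            if not np.isfinite(vals).all():
                raise ValueError(f"non-finite value for trait {t!r}")
            df = df.assign(**{t: vals.astype(float)})
        dup = df.duplicated(subset=["female", "male", "rep"], keep=False)
        if dup.any():
            raise ValueError(
                "duplicate (female, male, rep) record(s) at rows "
                f"{list(df.index[dup][:5])}"
            )
        table = cls(df=df.reset_index(drop=True), traits=traits)
        if check_balance:
            for g in table.groups():
                if not table.is_balanced(g):
                    warnings.warn(
                        f"group {g!r} is not a complete balanced factorial; "
                        "GCA uses record-level weighted means",
                        stacklevel=2,
                    )
        return table

    def groups(self) -> list[str]:
        return list(pd.unique(self.df["group"]))

    def subset(self, group: str) -> pd.DataFrame:
        sub = self.df[self.df["group"] == group]
        if sub.empty:
            raise ValueError(f"no records for group {group!r}")
        return sub

    def females(self, group: str) -> list[str]:
        return list(pd.unique(self.subset(group)["female"]))

    def males(self, group: str) -> list[str]:
        return list(pd.unique(self.subset(group)["male"]))

    def is_balanced(self, group: str) -> bool:
        """True when the group is a complete female x male factorial with
        equal replication."""
        sub = self.subset(group)
        counts = sub.groupby(["female", "male"]).size()
        n_f = sub["female"].nunique()
        n_m = sub["male"].nunique()
        return len(counts) == n_f * n_m and counts.nunique() == 1
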