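"""Single-factor ANOVA association of SNPLDB alleles with GCA effects.

Each multi-allelic marker is tested against the per-parent GCA effect
values of one trait with a one-way ANOVA (alleles as groups)::

    y_ij = mu + a_i + e_ij

where ``a_i`` is the effect of the i-th allele.  The test reports F, the
P value from the F distribution, R^2 = SS_between / SS_total (as a
percentage of phenotypic variance explained) and the per-allele effects
(allele mean minus the grand mean of the retained parents).  Significant
markers default to a per-test alpha of 0.01 with no genome-wide
correction, matching the published analysis; Bonferroni and
Benjamini-Hochberg corrections are available behind a flag.

Alleles carried by fewer than ``min_carriers`` parents are dropped from a
marker's test (their carriers excluded for that marker) since one-carrier
groups contribute no within-group variance.

"Favourable" alleles are the positive-effect alleles of significant
records; mining them and tallying carriers per parent reproduces the
breeding-oriented output of the analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .ld import SNPLDBMarker

__all__ = [
    "AssociationRecord",
    "FavourableAllele",
    "anova_association",
    "scan",
    "mine_favourable",
    "parent_tally",
    "SNPLDBAssociation",
]

logger = logging.getLogger(__name__)

#: smallest positive double, reported when the within-group variance is zero
_P_FLOOR = float(np.nextafter(0, 1))


@dataclass
class AssociationRecord:
    """One marker x trait one-way ANOVA result.

    ``allele_effects`` maps allele -> (n carriers, mean GCA, effect), with
    effect = allele mean - grand mean of the retained parents.
    ``degenerate`` flags a zero within-group variance with distinct group
    means (P reported as the smallest positive double).
    """

    marker_id: str
    trait: str
    chrom: str
    start: int
    end: int
    f_stat: float
    p_value: float
    r_squared: float  # percent of variance explained, in [0, 100]
    allele_effects: dict[str, tuple[int, float, float]]
    significant: bool
    degenerate: bool = False
    p_adjusted: float | None = None


@dataclass
class FavourableAllele:
    """A positive-effect allele at a significant marker, with its carriers."""

    marker_id: str
    trait: str
    allele: str
    effect: float
    carriers: list[str] = field(default_factory=list)


def _oneway(groups: list[np.ndarray]) -> tuple[float, float, float, bool]:
    """One-way ANOVA from group samples: (F, P, R^2 percent, degenerate)."""
    n = sum(g.size for g in groups)
    k = len(groups)
    grand = sum(g.sum() for g in groups) / n
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    sst = ssb + ssw
    if sst <= 0 or ssb <= 1e-14 * sst:
        return 0.0, 1.0, 0.0, False
    if ssw <= 1e-14 * sst:
        return np.inf, _P_FLOOR, 100.0, True
    df_b, df_w = k - 1, n - k
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p, float(100.0 * ssb / sst), False


def anova_association(
    marker: SNPLDBMarker,
    gca: dict[str, float] | pd.Series,
    trait: str = "",
    alpha: float = 0.01,
    min_carriers: int = 2,
) -> AssociationRecord | None:
    """Test one marker against one trait's GCA values.

    Returns ``None`` (with a logged reason) when fewer than two allele
    groups remain after dropping alleles with < ``min_carriers`` carriers.
    Parents must all have a GCA value; restrict the marker matrix first if
    they do not.
    """
    if isinstance(gca, pd.Series):
        gca = gca.to_dict()
    by_allele: dict[str, list[float]] = {}
    missing = [p for p in marker.parent_alleles if p not in gca]
    if missing:
        raise ValueError(
            f"marker {marker.marker_id}: no GCA value for parent(s) {missing[:5]}"
        )
    for parent, allele in marker.parent_alleles.items():
        by_allele.setdefault(allele, []).append(gca[parent])
    groups = {a: np.asarray(v, dtype=float) for a, v in by_allele.items() if len(v) >= min_carriers}
    if len(groups) < 2:
        logger.info(
            "marker %s skipped for trait %s: %d allele group(s) with >= %d carriers",
            marker.marker_id, trait, len(groups), min_carriers,
        )
        return None
    alleles = sorted(groups)
    f, p, r2, degenerate = _oneway([groups[a] for a in alleles])
    grand = float(np.concatenate([groups[a] for a in alleles]).mean())
    effects = {
        a: (int(groups[a].size), float(groups[a].mean()), float(groups[a].mean() - grand))
        for a in alleles
    }
    return AssociationRecord(
        marker_id=marker.marker_id,
        trait=trait,
        chrom=marker.chrom,
        start=marker.start,
        end=marker.end,
        f_stat=f,
        p_value=p,
        r_squared=r2,
        allele_effects=effects,
        significant=bool(p < alpha),
        degenerate=degenerate,
    )


def scan(
    markers: list[SNPLDBMarker],
    gca_table: pd.DataFrame,
    alpha: float = 0.01,
    min_carriers: int = 2,
    correction: str | None = None,
) -> tuple[list[AssociationRecord], dict[str, float]]:
    """Test every (marker, trait) pair.

    ``gca_table`` is a parent-indexed DataFrame with one column per trait.
    ``correction`` in {None, "bonferroni", "fdr_bh"} adjusts P values per
    trait before calling significance.  Returns the records sorted by
    (trait, chrom, start) and a summary with the number of tests,
    significant records and mean R^2 among significant records.
    """
    marker_parents = set()
    for mk in markers:
        marker_parents.update(mk.parent_alleles)
    table_parents = set(gca_table.index)
    offenders = sorted(marker_parents ^ table_parents) if markers else []
    if offenders:
        raise ValueError(
            "marker matrix and GCA table parents differ; offending ids: "
            f"{offenders[:10]}"
        )
    records: list[AssociationRecord] = []
    for trait in gca_table.columns:
        gca = gca_table[trait].to_dict()
        trait_records = []
        for mk in markers:
            if mk.is_monomorphic:
                continue
            rec = anova_association(
                mk, gca, trait=str(trait), alpha=alpha, min_carriers=min_carriers
            )
            if rec is not None:
                trait_records.append(rec)
        if correction is not None and trait_records:
            pvals = np.array([r.p_value for r in trait_records])
            reject, p_adj, _, _ = multipletests(pvals, alpha=alpha, method=correction)
            for rec, rej, pa in zip(trait_records, reject, p_adj):
                rec.p_adjusted = float(pa)
                rec.significant = bool(rej)
        records.extend(trait_records)
    records.sort(key=lambda r: (r.trait, r.chrom, r.start))
    sig = [r for r in records if r.significant]
    summary = {
        "n_tests": float(len(records)),
        "n_significant": float(len(sig)),
        "mean_r2_significant": float(np.mean([r.r_squared for r in sig])) if sig else float("nan"),
    }
    return records, summary


def mine_favourable(
    records: list[AssociationRecord],
    marker_matrix: pd.DataFrame | dict[str, dict[str, str]],
) -> list[FavourableAllele]:
    """Extract positive-effect alleles of significant records with carriers.

    ``marker_matrix`` is parent x marker (DataFrame) or
    marker -> parent -> allele (dict).
    """
    favs: list[FavourableAllele] = []
    for rec in records:
        if not rec.significant:
            continue
        if isinstance(marker_matrix, pd.DataFrame):
            col = marker_matrix[rec.marker_id]
            parent_alleles = col.to_dict()
        else:
            parent_alleles = marker_matrix[rec.marker_id]
        for allele, (_n, _mean, effect) in rec.allele_effects.items():
            if effect > 0:
                carriers = sorted(p for p, a in parent_alleles.items() if a == allele)
                favs.append(
                    FavourableAllele(
                        marker_id=rec.marker_id,
                        trait=rec.trait,
                        allele=allele,
                        effect=effect,
                        carriers=carriers,
                    )
                )
    return favs


def parent_tally(favourables: list[FavourableAllele]) -> pd.DataFrame:
    """Count favourable alleles carried per parent per trait.

    Returns a parent x trait DataFrame of counts, rows sorted by parent id.
    """
    counts: dict[str, dict[str, int]] = {}
    traits: list[str] = []
    for fav in favourables:
        if fav.trait not in traits:
            traits.append(fav.trait)
        for p in fav.carriers:
            counts.setdefault(p, {})
            counts[p][fav.trait] = counts[p].get(fav.trait, 0) + 1
    parents = sorted(counts)
    out = pd.DataFrame(0, index=parents, columns=sorted(traits), dtype=int)
    for p, per_trait in counts.items():
        for t, c in per_trait.items():
            out.loc[p, t] = c
    out.index.name = "parent"
    return out


def records_to_frame(records: list[AssociationRecord]) -> pd.DataFrame:
    """Flatten records into the report layout: trait, marker, chrom, P, R^2."""
    return pd.DataFrame(
        [
            {
                "trait": r.trait,
                "marker_id": r.marker_id,
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "F": r.f_stat,
                "P": r.p_value,
                "r2_percent": r.r_squared,
                "significant": r.significant,
                "degenerate": r.degenerate,
            }
            for r in records
        ]
    )


class SNPLDBAssociation(BaseEstimator):
    """Marker-trait association scan, sklearn style.

    Parameters mirror :func:`scan`; ``standardize_within_group`` optionally
    z-scores the GCA values within each (group, role) stratum before the
    pooled test (off by default, matching the pooled analysis of the whole
    panel).

    Attributes
    ----------
    records_ : list[AssociationRecord]
    favourable_ : list[FavourableAllele]
    tally_ : pandas.DataFrame
        Parent x trait counts of favourable alleles carried.
    summary_ : dict
    """

    def __init__(
        self,
        alpha: float = 0.01,
        min_carriers: int = 2,
        correction: str | None = None,
        standardize_within_group: bool = False,
    ):
        self.alpha = alpha
        self.min_carriers = min_carriers
        self.correction = correction
        self.standardize_within_group = standardize_within_group

    def fit(
        self,
        markers: list[SNPLDBMarker],
        gca_table: pd.DataFrame,
        strata: pd.Series | None = None,
    ) -> "SNPLDBAssociation":
        if not isinstance(gca_table, pd.DataFrame):
            raise TypeError("gca_table must be a parent-indexed DataFrame of g values")
        table = gca_table.astype(float)
        if self.standardize_within_group:
            if strata is None:
                raise ValueError(
                    "standardize_within_group requires per-parent strata labels"
                )
            table = table.groupby(strata).transform(
                lambda col: (col - col.mean()) / (col.std(ddof=1) or 1.0)
            )
        self.records_, self.summary_ = scan(
            markers,
            table,
            alpha=self.alpha,
            min_carriers=self.min_carriers,
            correction=self.correction,
        )
        matrix = {mk.marker_id: mk.parent_alleles for mk in markers}
        self.favourable_ = mine_favourable(self.records_, matrix)
        self.tally_ = parent_tally(self.favourable_)
        return self

    def significant_(self) -> list[AssociationRecord]:
        if not hasattr(self, "records_"):
            raise AttributeError("SNPLDBAssociation is not fitted; call fit() first")
        return [r for r in self.records_ if r.significant]
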