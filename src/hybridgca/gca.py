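"""General combining ability (GCA) analysis of an NCII factorial.

In a North Carolina design II, a set of female lines (in hybrid rice,
cytoplasmic male sterile lines) is crossed with a set of male lines
(restorers) in a complete factorial, and the F1 hybrids are evaluated in a
randomized complete block design (replications as blocks).  The GCA effect
of parent ``i`` for a trait is the deviation of the mean of its crosses from
the mean of all crosses in the group::

    g_i = y_i - y_bar

where ``y_i`` averages every replication-level record of crosses involving
parent ``i`` and ``y_bar`` averages all records of the subpopulation group.
Female and male effects are estimated independently; in a balanced factorial
each role's effects sum to zero by construction.

The module also provides the hybrids' RCBD ANOVA (crosses as treatments,
replications as blocks), least-significant-difference letter groups at a
chosen alpha, and mid-parent heterosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .datatypes import CrossTable

__all__ = [
    "AnovaTable",
    "GCAProfile",
    "GCAEstimator",
    "estimate_gca",
    "anova_hybrids",
    "lsd_groups",
    "lsd_threshold",
    "mid_parent_heterosis",
]


@dataclass
class AnovaTable:
    """Sums-of-squares decomposition of an RCBD trial.

    ``sources`` maps source name -> (df, SS, MS, F, P); F and P are only
    filled for the treatment ("crosses") row.  ``zero_variance`` flags a
    table whose total SS is (numerically) zero, in which case the F test is
    undefined and the effect is reported as not significant.
    """

    sources: dict[str, tuple[int, float, float, float | None, float | None]]
    zero_variance: bool = False

    @property
    def ms_error(self) -> float:
        return self.sources["residual"][2]

    @property
    def df_error(self) -> int:
        return self.sources["residual"][0]

    @property
    def f_crosses(self) -> float | None:
        return self.sources["crosses"][3]

    @property
    def p_crosses(self) -> float | None:
        return self.sources["crosses"][4]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"source": k, "df": v[0], "ss": v[1], "ms": v[2], "F": v[3], "P": v[4]}
            for k, v in self.sources.items()
        ]
        return pd.DataFrame(rows)


@dataclass
class GCAProfile:
    """Per-parent GCA effects with LSD letters for one role in one group."""

    parent: str
    group: str
    role: str  # "female" or "male"
    effects: dict[str, float] = field(default_factory=dict)
    letters: dict[str, str] = field(default_factory=dict)


def anova_hybrids(crosses: CrossTable, group: str, trait: str) -> AnovaTable:
    """Two-way RCBD ANOVA of the hybrids of one group for one trait.

    Sources: crosses (genotypes), replications (blocks), residual.
    Requires at least two crosses and two replications (otherwise the
    residual has no degrees of freedom).
    """
    sub = crosses.subset(group)
    if trait not in crosses.traits:
        raise ValueError(f"unknown trait {trait!r}")
    y = sub[trait].to_numpy(float)
    cross_ids = sub["female"].astype(str) + "\x00" + sub["male"].astype(str)
    reps = sub["rep"]
    t = cross_ids.nunique()
    r = reps.nunique()
    if t < 2:
        raise ValueError("RCBD ANOVA needs >= 2 crosses")
    if r < 2:
        raise ValueError("RCBD ANOVA needs >= 2 replications (no residual df)")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())
    cross_means = sub.groupby(cross_ids.to_numpy())[trait].mean()
    rep_means = sub.groupby(reps.to_numpy())[trait].mean()
    n_per_cross = len(sub) / t
    n_per_rep = len(sub) / r
    ss_crosses = float(n_per_cross * ((cross_means - grand) ** 2).sum())
    ss_reps = float(n_per_rep * ((rep_means - grand) ** 2).sum())
    ss_res = ss_total - ss_crosses - ss_reps
    df_c, df_r = t - 1, r - 1
    df_e = len(sub) - 1 - df_c - df_r
    ms_c = ss_crosses / df_c
    ms_r = ss_reps / df_r
    ms_e = max(ss_res, 0.0) / df_e
    scale = max(ss_total, 1.0)
    if ss_total <= 1e-12 * scale or ms_e <= 1e-12 * scale:
        if ss_total <= 1e-12 * scale:
            return AnovaTable(
                sources={
                    "crosses": (df_c, ss_crosses, ms_c, None, None),
                    "replications": (df_r, ss_reps, ms_r, None, None),
                    "residual": (df_e, max(ss_res, 0.0), ms_e, None, None),
                    "total": (len(sub) - 1, ss_total, np.nan, None, None),
                },
                zero_variance=True,
            )
        f = np.inf
        p = 0.0
    else:
        f = ms_c / ms_e
        p = float(stats.f.sf(f, df_c, df_e))
    return AnovaTable(
        sources={
            "crosses": (df_c, ss_crosses, ms_c, float(f), p),
            "replications": (df_r, ss_reps, ms_r, None, None),
            "residual": (df_e, max(ss_res, 0.0), ms_e, None, None),
            "total": (len(sub) - 1, ss_total, np.nan, None, None),
        }
    )


def lsd_threshold(mse: float, df_error: int, n_per_mean: float, alpha: float = 0.01) -> float:
    """Least significant difference: t(1-alpha/2, df) * sqrt(2*MSE/n)."""
    if mse < 0:
        raise ValueError("mse must be >= 0")
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    if n_per_mean < 1:
        raise ValueError("n_per_mean must be >= 1")
    t_crit = stats.t.ppf(1 - alpha / 2.0, df_error)
    return float(t_crit * np.sqrt(2.0 * mse / n_per_mean))


def _letters_from_means(names: list[str], means: np.ndarray, lsd: float) -> dict[str, str]:
    """Insert-and-absorb letter assignment on descending-sorted means.

    Means closer than ``lsd`` share a letter; ties in means are broken by
    name so output is deterministic.
    """
    order = sorted(range(len(names)), key=lambda i: (-means[i], names[i]))
    sm = [means[i] for i in order]
    n = len(order)
    ranges: list[tuple[int, int]] = []
    for i in range(n):
        j = i
        while j + 1 < n and sm[i] - sm[j + 1] < lsd:
            j += 1
        if not ranges or j > ranges[-1][1]:
            ranges.append((i, j))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {nm: "" for nm in names}
    for k, (lo, hi) in enumerate(ranges):
        letter = alphabet[k % len(alphabet)] * (k // len(alphabet) + 1)
        for idx in order[lo : hi + 1]:
            letters[names[idx]] += letter
    return letters


def lsd_groups(
    means: dict[str, float] | pd.Series,
    mse: float,
    df_error: int,
    n_per_mean: float,
    alpha: float = 0.01,
) -> dict[str, str]:
    """Assign LSD letter groups to a set of means.

    Two means sharing any letter are not significantly different at
    ``alpha``; letters are assigned by descending mean.
    """
    if isinstance(means, pd.Series):
        means = means.to_dict()
    names = list(means)
    vals = np.array([means[nm] for nm in names], dtype=float)
    lsd = lsd_threshold(mse, df_error, n_per_mean, alpha)
    return _letters_from_means(names, vals, lsd)


def estimate_gca(
    crosses: CrossTable, group: str, alpha: float = 0.01, letters: bool = True
) -> list[GCAProfile]:
    """Estimate GCA effects g_i = y_i - y_bar for every parent of a group.

    ``y_i`` is the mean of all replication-level records of crosses that
    involve parent ``i``; ``y_bar`` is the mean of all records of the group.
    Females and males are estimated independently.  For an unbalanced design
    the same record-level means are used (a warning is emitted when the
    table is constructed).

    When ``letters`` is set, LSD letter groups at ``alpha`` are attached per
    role and trait, using the residual mean square of the hybrids' RCBD
    ANOVA and n_per_mean = (crosses per parent) x replications.
    """
    sub = crosses.subset(group)
    profiles: list[GCAProfile] = []
    grand = {t: float(sub[t].mean()) for t in crosses.traits}
    anova_cache: dict[str, AnovaTable] = {}
    if letters:
        for t in crosses.traits:
            anova_cache[t] = anova_hybrids(crosses, group, t)
    n_reps = sub["rep"].nunique()
    for role, other in (("female", "male"), ("male", "female")):
        parents = list(pd.unique(sub[role]))
        if not parents:
            raise ValueError(f"group {group!r} has no {role} parents")
        eff: dict[str, dict[str, float]] = {p: {} for p in parents}
        for t in crosses.traits:
            parent_means = sub.groupby(role)[t].mean()
            for p in parents:
                if p not in parent_means.index:
                    raise ValueError(f"parent {p!r} has no crosses in group {group!r}")
                eff[p][t] = float(parent_means[p] - grand[t])
        role_profiles = [
            GCAProfile(parent=p, group=group, role=role, effects=eff[p]) for p in parents
        ]
        if letters:
            n_other = sub[other].nunique()
            n_per_mean = n_other * n_reps
            for t in crosses.traits:
                table = anova_cache[t]
                if table.zero_variance:
                    lt = {p: "a" for p in parents}
                else:
                    lt = lsd_groups(
                        {p: eff[p][t] for p in parents},
                        table.ms_error,
                        table.df_error,
                        n_per_mean,
                        alpha,
                    )
                for prof in role_profiles:
                    prof.letters[t] = lt[prof.parent]
        profiles.extend(role_profiles)
    return profiles


def mid_parent_heterosis(f1_mean: float, p1_mean: float, p2_mean: float) -> float:
    """Mid-parent heterosis in percent: 100 * (F1 - MP) / MP, MP=(P1+P2)/2."""
    mp = (p1_mean + p2_mean) / 2.0
    if mp == 0:
        raise ValueError("mid-parent mean is zero; heterosis undefined")
    return 100.0 * (f1_mean - mp) / mp


def profiles_to_frame(profiles: list[GCAProfile], traits: list[str]) -> pd.DataFrame:
    """Long-to-wide convenience: parent x trait table of g values and letters."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"parent": p.parent, "group": p.group, "role": p.role}
        for t in traits:
            row[t] = p.effects.get(t, np.nan)
            row[f"{t}_letters"] = p.letters.get(t, "")
        rows.append(row)
    return pd.DataFrame(rows)


class GCAEstimator(BaseEstimator):
    """Estimate GCA effects of an NCII factorial, sklearn style.

    Parameters
    ----------
    group:
        Restrict estimation to one subpopulation group; ``None`` fits every
        group in the table.
    alpha:
        Significance level of the LSD letter grouping.
    letters:
        Attach LSD letters to the fitted profiles.

    Attributes
    ----------
    profiles_ : list[GCAProfile]
        Per-parent effect profiles across fitted groups.
    effects_ : pandas.DataFrame
        Parent x trait table of g values (one row per parent with group and
        role columns).
    anova_ : dict[(group, trait), AnovaTable]
        Hybrids' RCBD ANOVA per group and trait.
    """

    def __init__(self, group: str | None = None, alpha: float = 0.01, letters: bool = True):
        self.group = group
        self.alpha = alpha
        self.letters = letters

    def fit(self, crosses: CrossTable | pd.DataFrame, y=None) -> "GCAEstimator":
        if isinstance(crosses, pd.DataFrame):
            crosses = CrossTable.from_dataframe(crosses)
        if not isinstance(crosses, CrossTable):
            raise TypeError("fit expects a CrossTable or phenotype DataFrame")
        groups = [self.group] if self.group is not None else crosses.groups()
        self.traits_ = list(crosses.traits)
        self.profiles_ = []
        self.anova_ = {}
        self.group_means_ = {}
        for g in groups:
            self.profiles_.extend(
                estimate_gca(crosses, g, alpha=self.alpha, letters=self.letters)
            )
            sub = crosses.subset(g)
            self.group_means_[g] = {t: float(sub[t].mean()) for t in crosses.traits}
            for t in crosses.traits:
                self.anova_[(g, t)] = anova_hybrids(crosses, g, t)
        self.effects_ = profiles_to_frame(self.profiles_, self.traits_)
        return self

    def effects_table(self) -> pd.DataFrame:
        self._check_fitted()
        return self.effects_.copy()

    def gca_matrix(self) -> pd.DataFrame:
        """Parent-indexed matrix of g values (all roles and groups pooled),
        the association module's response variable."""
        self._check_fitted()
        return self.effects_.set_index("parent")[self.traits_]

    def predict(self, pairs: list[tuple[str, str]], trait: str) -> np.ndarray:
        """Predict F1 cross means as group mean + g_female + g_male."""
        self._check_fitted()
        eff = {(p.parent, p.role): p for p in self.profiles_}
        out = np.empty(len(pairs))
        for k, (f, m) in enumerate(pairs):
            pf = eff.get((f, "female"))
            pm = eff.get((m, "male"))
            if pf is None or pm is None:
                raise ValueError(f"unknown cross {(f, m)!r}")
            if pf.group != pm.group:
                raise ValueError(f"cross {(f, m)!r} spans groups")
            mu = self.group_means_[pf.group][trait]
            out[k] = mu + pf.effects[trait] + pm.effects[trait]
        return out

    def _check_fitted(self) -> None:
        if not hasattr(self, "profiles_"):
            raise AttributeError("GCAEstimator is not fitted; call fit() first")
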