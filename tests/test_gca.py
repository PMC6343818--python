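"""GCA estimation, hybrids' ANOVA, LSD letters and heterosis."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hybridgca.datatypes import CrossTable
from hybridgca.gca import (
    GCAEstimator,
    anova_hybrids,
    estimate_gca,
    lsd_groups,
    lsd_threshold,
    mid_parent_heterosis,
)

from conftest import cross_table_from_means


def _effects(profiles, role):
    return {p.parent: p.effects["Y"] for p in profiles if p.role == role}


class TestEstimateGca:
    def test_null_case_all_zero(self):
        df = cross_table_from_means(
            {(f, m): 7.5 for f in ("f1", "f2") for m in ("m1", "m2")}, n_reps=2
        )
        profiles = estimate_gca(CrossTable.from_dataframe(df), "g1")
        for p in profiles:
            assert p.effects["Y"] == pytest.approx(0.0)
            assert p.letters["Y"] == "a"

    def test_two_by_two_hand_oracle(self, two_by_two_crosses):
        profiles = estimate_gca(
            CrossTable.from_dataframe(two_by_two_crosses), "g1", letters=False
        )
        assert _effects(profiles, "female") == pytest.approx({"f1": 2.0, "f2": -2.0})
        assert _effects(profiles, "male") == pytest.approx({"m1": -2.0, "m2": 2.0})

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_balanced_matches_mean_difference_oracle(self, seed):
        """g_i from the estimator equals a plain-loop evaluation of
        y_i - y_bar on random balanced factorials."""
        rng = np.random.default_rng(seed)
        n_f, n_m, reps = rng.integers(2, 7), rng.integers(2, 7), rng.integers(1, 4)
        rows = []
        for f in range(n_f):
            for m in range(n_m):
                for r in range(reps):
                    rows.append(
                        {
                            "cross_id": f"f{f}xm{m}",
                            "female": f"f{f}",
                            "male": f"m{m}",
                            "group": "g1",
                            "rep": r + 1,
                            "Y": rng.normal(50, 10),
                        }
                    )
        df = pd.DataFrame(rows)
        profiles = estimate_gca(CrossTable.from_dataframe(df), "g1", letters=False)
        grand = df["Y"].mean()
        for role, col in (("female", "female"), ("male", "male")):
            got = _effects(profiles, role)
            for parent, g in got.items():
                oracle = df[df[col] == parent]["Y"].mean() - grand
                assert g == pytest.approx(oracle, abs=1e-9)
            assert sum(got.values()) == pytest.approx(0.0, abs=1e-9)

    def test_shift_invariance(self, two_by_two_crosses):
        """Adding a constant to every record leaves g unchanged."""
        base = estimate_gca(
            CrossTable.from_dataframe(two_by_two_crosses), "g1", letters=False
        )
        shifted_df = two_by_two_crosses.assign(Y=two_by_two_crosses["Y"] + 123.4)
        shifted = estimate_gca(
            CrossTable.from_dataframe(shifted_df), "g1", letters=False
        )
        assert _effects(shifted, "female") == pytest.approx(_effects(base, "female"))
        assert _effects(shifted, "male") == pytest.approx(_effects(base, "male"))

    def test_unbalanced_design_warns(self, two_by_two_crosses):
        df = two_by_two_crosses.iloc[:-1]  # drop one cross
        with pytest.warns(UserWarning, match="balanced"):
            CrossTable.from_dataframe(df)


class TestAnovaHybrids:
    def test_sums_of_squares_oracle_toy_table(self):
        """3 crosses x 2 reps: every SS equals the brute-force definition."""
        means = {("f1", "m1"): 10.0, ("f1", "m2"): 14.0, ("f1", "m3"): 9.0}
        df = cross_table_from_means(means, n_reps=2)
        # perturb reps so the block term is non-trivial
        df.loc[df["rep"] == 2, "Y"] += [1.0, 3.0, -1.0]
        ct = CrossTable.from_dataframe(df, check_balance=False)
        table = anova_hybrids(ct, "g1", "Y")
        y = df["Y"].to_numpy()
        grand = y.mean()
        sst = ((y - grand) ** 2).sum()
        ss_c = sum(
            2 * (df[df["male"] == m]["Y"].mean() - grand) ** 2 for m in ("m1", "m2", "m3")
        )
        ss_r = sum(3 * (df[df["rep"] == r]["Y"].mean() - grand) ** 2 for r in (1, 2))
        ss_e = sst - ss_c - ss_r
        assert table.sources["crosses"][1] == pytest.approx(ss_c, rel=1e-12)
        assert table.sources["replications"][1] == pytest.approx(ss_r, rel=1e-12)
        assert table.sources["residual"][1] == pytest.approx(ss_e, rel=1e-9)
        assert table.sources["total"][1] == pytest.approx(sst, rel=1e-12)
        assert table.sources["crosses"][0] == 2
        assert table.sources["replications"][0] == 1
        assert table.sources["residual"][0] == 2

    def test_matches_statsmodels_ols_decomposition(self):
        """Cross-check the RCBD table against an independent OLS fit."""
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(42)
        rows = []
        for c in range(4):
            for r in range(3):
                rows.append(
                    {
                        "cross_id": f"c{c}",
                        "female": f"f{c}",
                        "male": "m0",
                        "group": "g1",
                        "rep": r + 1,
                        "Y": rng.normal(20, 4),
                    }
                )
        df = pd.DataFrame(rows)
        ct = CrossTable.from_dataframe(df, check_balance=False)
        table = anova_hybrids(ct, "g1", "Y")
        fit = smf.ols("Y ~ C(cross_id) + C(rep)", data=df).fit()
        sm_table = sm.stats.anova_lm(fit, typ=1)
        assert table.sources["crosses"][1] == pytest.approx(
            sm_table.loc["C(cross_id)", "sum_sq"], rel=1e-9
        )
        assert table.sources["replications"][1] == pytest.approx(
            sm_table.loc["C(rep)", "sum_sq"], rel=1e-9
        )
        assert table.p_crosses == pytest.approx(
            sm_table.loc["C(cross_id)", "PR(>F)"], rel=1e-9
        )

    def test_zero_variance_flagged(self):
        df = cross_table_from_means(
            {("f1", "m1"): 5.0, ("f1", "m2"): 5.0}, n_reps=2
        )
        table = anova_hybrids(CrossTable.from_dataframe(df), "g1", "Y")
        assert table.zero_variance
        assert table.f_crosses is None

    def test_single_replication_error(self):
        df = cross_table_from_means({("f1", "m1"): 5.0, ("f1", "m2"): 6.0}, n_reps=1)
        with pytest.raises(ValueError, match="replications"):
            anova_hybrids(CrossTable.from_dataframe(df), "g1", "Y")

    def test_planted_genotype_variance_significant(self, default_panel):
        cfg, _gm, _truth, crosses = default_panel
        table = anova_hybrids(crosses, cfg.group_label, "T1")
        assert table.p_crosses < 0.01


class TestLsdGroups:
    @staticmethod
    def _mse_for_lsd(lsd, n, df_error, alpha):
        t = stats.t.ppf(1 - alpha / 2, df_error)
        return lsd**2 * n / (2 * t**2)

    def test_all_equal_share_a(self):
        letters = lsd_groups({"a": 1.0, "b": 1.0, "c": 1.0}, 1.0, 10, 2)
        assert set(letters.values()) == {"a"}

    @pytest.mark.parametrize(
        "means, expected",
        [
            ({"p1": 10.0, "p2": 5.0, "p3": 0.0}, {"p1": "a", "p2": "b", "p3": "c"}),
            ({"p1": 10.0, "p2": 9.0, "p3": 0.0}, {"p1": "a", "p2": "a", "p3": "b"}),
        ],
    )
    def test_pairwise_oracle_with_lsd_two(self, means, expected):
        """With the LSD fixed at 2 the letters follow the pairwise table."""
        alpha, df_error, n = 0.01, 30, 4
        mse = self._mse_for_lsd(2.0, n, df_error, alpha)
        assert lsd_threshold(mse, df_error, n, alpha) == pytest.approx(2.0)
        assert lsd_groups(means, mse, df_error, n, alpha) == expected

    def test_chain_overlap_shares_letters(self):
        # 10 ~ 9, 9 ~ 8, but 10 !~ 8: middle mean carries both letters
        alpha, df_error, n = 0.01, 30, 4
        mse = self._mse_for_lsd(1.5, n, df_error, alpha)
        letters = lsd_groups({"x": 10.0, "y": 9.0, "z": 8.0}, mse, df_error, n, alpha)
        assert letters == {"x": "a", "y": "ab", "z": "b"}

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            lsd_threshold(-1.0, 10, 2)
        with pytest.raises(ValueError):
            lsd_threshold(1.0, 0, 2)
        with pytest.raises(ValueError):
            lsd_threshold(1.0, 10, 0.5)


class TestMidParentHeterosis:
    def test_identity_zero(self):
        assert mid_parent_heterosis(10.0, 12.0, 8.0) == pytest.approx(0.0)

    def test_fifty_percent(self):
        assert mid_parent_heterosis(15.0, 10.0, 10.0) == pytest.approx(50.0)

    def test_zero_mid_parent_error(self):
        with pytest.raises(ValueError, match="mid-parent"):
            mid_parent_heterosis(1.0, 5.0, -5.0)


class TestGCAEstimator:
    def test_sklearn_params_round_trip(self):
        from sklearn.base import clone

        est = GCAEstimator(alpha=0.05, letters=False)
        assert est.get_params()["alpha"] == 0.05
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_predict_zero_noise_equals_cross_means(self):
        from hybridgca.simulate import SimConfig, simulate_crosses, simulate_parents

        cfg = SimConfig(seed=21, noise_sd=0, sca_sd=0, rep_effect_sd=0)
        gm, truth = simulate_parents(cfg)
        ct = simulate_crosses(gm, truth, cfg)
        est = GCAEstimator(letters=False).fit(ct)
        sub = ct.df
        pairs = list({(r.female, r.male) for r in sub.itertuples()})
        pred = est.predict(pairs, "T1")
        for (f, m), p in zip(pairs, pred):
            obs = sub[(sub["female"] == f) & (sub["male"] == m)]["T1"].mean()
            assert p == pytest.approx(obs, abs=1e-9)

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            GCAEstimator().effects_table()


# Reference GCA effect tables of an 8 CMS x 6 restorer indica NCII panel
# (published values, frozen here as a consistency fixture).  Under the
# deviation-from-mean definition the CMS effects of each trait must sum to
# ~0 up to the table's rounding (11 traits, values printed to 0.1).
INDICA_CMS_GCA = {
    "DH": [-14.4, -7.4, -10.6, 24.9, 11.1, -1.3, -4.9, 2.7],
    "PH": [6.2, -16.9, 27.7, -17.1, -7.9, 0.8, 9.3, -2.2],
    "NPPP": [4.2, -7.5, 3.0, 5.2, 2.6, 1.3, -0.8, -8.0],
    "NSPP": [-85.0, 0.9, 107.4, -56.1, -6.7, 24.0, 21.9, -6.6],
    "NFGPP": [-57.4, -7.0, 104.2, -40.7, 6.2, -18.0, 33.2, -20.5],
    "PL": [0.4, 1.0, 5.4, -3.0, 3.7, -3.7, -2.3, -1.6],
    "SW": [0.5, -0.1, -0.3, -0.1, 0.6, -0.4, -0.2, -0.2],
    "ST": [0.04, 0.03, -0.11, -0.12, 0.23, -0.01, -0.02, -0.03],
    "SL": [-0.07, -0.04, 0.48, -1.55, 0.00, 0.89, 0.13, 0.17],
    "TGW": [10.0, 1.0, 0.4, -7.1, -0.5, -2.5, -2.5, 1.3],
    "GYPP": [62.1, 212.3, 284.6, -425.8, 81.3, -135.8, 35.2, -113.9],
}


def test_published_cms_gca_values_sum_to_zero():
    """The frozen CMS GCA reference values are internally consistent with
    the deviation-from-mean definition: per-trait sums vanish up to the
    table's rounding resolution."""
    for trait, values in INDICA_CMS_GCA.items():
        assert len(values) == 8
        assert abs(sum(values)) <= 0.5, trait
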