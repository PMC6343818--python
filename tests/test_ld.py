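"""LD statistics, D' confidence intervals, block partitioning, SNPLDB markers."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hybridgca.datatypes import MISSING
from hybridgca.ld import (
    SNPLDBTransformer,
    build_snpldb,
    classify_pair,
    dprime_ci,
    gabriel_blocks,
    impute_missing,
    marker_stats,
    pair_ld,
    site_maf,
)

from conftest import make_genotypes


def _matrix_from_hap_counts(n_AB, n_Ab, n_aB, n_ab):
    """Two-site matrix realising the requested haplotype counts."""
    col_i = "1" * (n_AB + n_Ab) + "0" * (n_aB + n_ab)
    col_j = "1" * n_AB + "0" * n_Ab + "1" * n_aB + "0" * n_ab
    return make_genotypes([col_i, col_j])


class TestImputeMissing:
    def test_identity_without_missing(self):
        gm = make_genotypes(["0101", "1100"])
        out = impute_missing(gm)
        assert np.array_equal(out.calls, gm.calls)

    def test_majority_fill(self):
        gm = make_genotypes(["110."])  # {alt, alt, ref, missing} -> alt
        out = impute_missing(gm)
        assert out.calls[3, 0] == 1

    def test_tie_goes_to_ref(self):
        gm = make_genotypes(["1100."])  # 2 alt, 2 ref, 1 missing -> ref
        out = impute_missing(gm)
        assert out.calls[4, 0] == 0

    def test_by_group_majority(self):
        groups = {"p1": "A", "p2": "A", "p3": "A", "p4": "B", "p5": "B", "p6": "B"}
        gm = make_genotypes(["11.000"], groups=groups)
        # overall majority is ref, but within group A it is alt
        assert impute_missing(gm).calls[2, 0] == 0
        assert impute_missing(gm, by_group=True).calls[2, 0] == 1

    def test_fully_missing_site_error(self):
        gm = make_genotypes(["...."])
        with pytest.raises(ValueError, match="missing in every parent"):
            impute_missing(gm)


class TestSiteMaf:
    def test_monomorphic_zero(self):
        assert site_maf(make_genotypes(["0000"]), 0) == 0.0

    def test_one_alt_of_33(self):
        gm = make_genotypes(["1" + "0" * 32])
        assert site_maf(gm, 0) == pytest.approx(1 / 33)

    def test_half_and_half(self):
        gm = make_genotypes(["1" * 16 + "0" * 16])
        assert site_maf(gm, 0) == pytest.approx(0.5)

    def test_missing_excluded(self):
        gm = make_genotypes(["10.."])
        assert site_maf(gm, 0) == pytest.approx(0.5)


class TestPairLD:
    def test_identical_columns_complete_ld(self):
        gm = make_genotypes(["0011", "0011"])
        ld = pair_ld(gm, 0, 1)
        assert ld.dprime == pytest.approx(1.0)
        assert ld.r2 == pytest.approx(1.0)

    def test_worked_counts_4114(self):
        """Counts (AB,Ab,aB,ab)=(4,1,1,4): D=0.15, D'=0.6, r2=0.36 by the
        definitions evaluated by hand."""
        gm = _matrix_from_hap_counts(4, 1, 1, 4)
        ld = pair_ld(gm, 0, 1)
        assert ld.D == pytest.approx(0.15)
        assert ld.dprime == pytest.approx(0.6)
        assert ld.r2 == pytest.approx(0.36)
        assert ld.n_informative == 10

    def test_three_haplotype_classes_give_dprime_one(self):
        gm = _matrix_from_hap_counts(5, 0, 3, 4)
        assert pair_ld(gm, 0, 1).dprime == pytest.approx(1.0)

    def test_monomorphic_pair_flagged(self):
        gm = make_genotypes(["0000", "0101"])
        assert not pair_ld(gm, 0, 1).informative

    def test_independent_sites_low_ld(self):
        rng = np.random.default_rng(123)
        calls = rng.integers(0, 2, size=(1000, 2)).astype(np.int8)
        gm = make_genotypes(
            ["".join(str(v) for v in calls[:, j]) for j in range(2)]
        )
        ld = pair_ld(gm, 0, 1)
        assert ld.dprime < 0.15
        assert ld.r2 < 0.02


class TestDprimeCI:
    def test_perfect_ld_concentrates_near_one(self):
        lo, hi = dprime_ci((20, 0, 0, 20))
        assert hi == pytest.approx(1.0)
        assert lo >= 0.7

    def test_more_data_narrower_interval(self):
        lo8, hi8 = dprime_ci((3, 1, 1, 3))
        lo80, hi80 = dprime_ci((30, 10, 10, 30))
        assert (hi80 - lo80) < (hi8 - lo8)

    def test_against_independent_grid_oracle(self):
        """Brute-force re-implementation of the grid likelihood with plain
        Python loops must agree exactly."""
        counts = (4, 1, 1, 4)
        n = sum(counts)
        pa = (counts[0] + counts[1]) / n
        pb = (counts[0] + counts[2]) / n
        d_obs = counts[0] / n - pa * pb
        dmax = (
            min(pa * (1 - pb), (1 - pa) * pb)
            if d_obs >= 0
            else min(pa * pb, (1 - pa) * (1 - pb))
        )
        sign = 1.0 if d_obs >= 0 else -1.0
        weights = []
        grid = [round(0.01 * k, 10) for k in range(101)]
        for g in grid:
            d = sign * g * dmax
            probs = [
                pa * pb + d,
                pa * (1 - pb) - d,
                (1 - pa) * pb - d,
                (1 - pa) * (1 - pb) + d,
            ]
            ll = 0.0
            ok = True
            for c, p in zip(counts, probs):
                if c > 0:
                    if p <= 0:
                        ok = False
                        break
                    ll += c * math.log(p)
            weights.append(math.exp(ll) if ok else 0.0)
        total = sum(weights)
        cum, lo, hi = 0.0, None, None
        for g, w in zip(grid, weights):
            cum += w / total
            if lo is None and cum >= 0.05:
                lo = g
            if hi is None and cum >= 0.95:
                hi = g
        assert dprime_ci(counts) == (pytest.approx(lo), pytest.approx(hi))

    def test_degenerate_frequencies_error(self):
        with pytest.raises(ValueError, match="polymorphic"):
            dprime_ci((10, 0, 10, 0))

    def test_total_count_too_small(self):
        with pytest.raises(ValueError, match=">= 2"):
            dprime_ci((1, 0, 0, 0))


def _oracle_blocks(gm, max_distance=200_000, maf_min=0.01, informative_fraction=0.95):
    """Exhaustive enumeration of admissible spans with the same pair rules,
    selected greedily by physical length: independent of the implementation's
    candidate bookkeeping."""
    retained = [
        j
        for j in range(gm.n_sites)
        if gm.is_polymorphic(j) and gm.site_maf(j) >= maf_min
    ]
    by_chrom = {}
    for j in retained:
        by_chrom.setdefault(str(gm.chrom[j]), []).append(j)
    result = []
    for chrom, sites in by_chrom.items():
        m = len(sites)
        pos = [int(gm.pos[j]) for j in sites]
        cat = {}
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_distance:
                    continue
                cat[(a, b)] = classify_pair(pair_ld(gm, sites[a], sites[b]))
        spans = []
        for a in range(m):
            for b in range(a + 1, m):
                if pos[b] - pos[a] > max_distance:
                    continue
                if cat.get((a, b)) != 1:
                    continue
                inner = [
                    cat[(x, y)]
                    for x in range(a, b + 1)
                    for y in range(x + 1, b + 1)
                    if (x, y) in cat and cat[(x, y)] != 0
                ]
                if not inner:
                    continue
                strong = sum(1 for c in inner if c == 1)
                if strong / len(inner) >= informative_fraction:
                    spans.append((pos[b] - pos[a], a, b))
        spans.sort(key=lambda s: (-s[0], s[1], s[2]))
        used = set()
        for _span, a, b in spans:
            if any(k in used for k in range(a, b + 1)):
                continue
            used.update(range(a, b + 1))
            result.append((chrom, pos[a], pos[b], tuple(sites[a : b + 1])))
    return sorted(result)


class TestGabrielBlocks:
    def test_single_site_no_block_singleton_marker(self):
        gm = make_genotypes(["0011"], positions=[1234], chrom="3")
        blocks = gabriel_blocks(gm)
        assert blocks == []
        markers = build_snpldb(gm, blocks)
        assert [m.marker_id for m in markers] == ["S3_1234"]

    def test_five_perfect_sites_one_block(self):
        col = "0" * 15 + "1" * 15
        gm = make_genotypes([col] * 5, positions=[1000, 3000, 5000, 7000, 9000])
        blocks = gabriel_blocks(gm)
        assert len(blocks) == 1
        assert (blocks[0].start, blocks[0].end) == (1000, 9000)
        assert len(blocks[0].members) == 5

    def test_max_distance_respected(self):
        col = "0" * 15 + "1" * 15
        gm = make_genotypes([col, col], positions=[1000, 300_000])
        assert gabriel_blocks(gm, max_distance=200_000) == []

    def test_low_maf_sites_excluded(self):
        col = "0" * 15 + "1" * 15
        rare = "1" + "0" * 29
        gm = make_genotypes([col, rare, col], positions=[1000, 2000, 3000])
        blocks = gabriel_blocks(gm, maf_min=0.05)
        assert len(blocks) == 1
        assert blocks[0].members == [0, 2]

    def test_matches_exhaustive_enumeration_on_random_instances(self):
        """Partitioning equals the brute-force span enumeration on random
        small instances (mix of structured and unstructured panels)."""
        rng = np.random.default_rng(2024)
        for trial in range(40):
            n_par = int(rng.integers(8, 41))
            n_sites = int(rng.integers(2, 13))
            structured = trial % 2 == 0
            if structured:
                n_hap = int(rng.integers(2, 4))
                haps = rng.integers(0, 2, size=(n_hap, n_sites))
                assign = rng.integers(0, n_hap, size=n_par)
                calls = haps[assign]
            else:
                calls = rng.integers(0, 2, size=(n_par, n_sites))
            positions = np.sort(
                rng.choice(np.arange(1, 500_000), size=n_sites, replace=False)
            )
            gm = make_genotypes(
                ["".join(str(v) for v in calls[:, j]) for j in range(n_sites)],
                positions=[int(p) for p in positions],
            )
            got = sorted(
                (b.chrom, b.start, b.end, tuple(b.members)) for b in gabriel_blocks(gm)
            )
            assert got == _oracle_blocks(gm), f"trial {trial}"

    def test_recovers_planted_two_haplotype_blocks(self, clean_two_hap_panel):
        _cfg, gm, truth = clean_two_hap_panel
        got = {(b.chrom, b.start, b.end) for b in gabriel_blocks(gm)}
        want = {(c, s, e) for c, s, e, mem in truth.true_blocks if len(mem) >= 2}
        assert got == want

    def test_blocks_disjoint_and_within_distance(self, default_panel):
        _cfg, gm, _truth, _crosses = default_panel
        imputed = impute_missing(gm)
        blocks = gabriel_blocks(imputed)
        seen = set()
        for b in blocks:
            assert b.end - b.start <= 200_000
            assert not (set(b.members) & seen)
            seen.update(b.members)


class TestBuildSnpldb:
    def test_two_haplotype_collapse(self):
        from hybridgca.ld import LDBlock

        gm = make_genotypes(["0011", "0011"])
        markers = build_snpldb(gm, [LDBlock("1", 1000, 2000, [0, 1])])
        mk = markers[0]
        assert mk.marker_id == "1_BLOCK_1000_2000"
        assert mk.allele_freqs == {"AA": pytest.approx(0.5), "GG": pytest.approx(0.5)}

    def test_singleton_marker_naming(self):
        gm = make_genotypes(["0011"], positions=[16441661], chrom="4")
        markers = build_snpldb(gm, [])
        assert markers[0].marker_id == "S4_16441661"

    def test_monomorphic_block_flagged(self):
        from hybridgca.ld import LDBlock

        gm = make_genotypes(["0000", "0000"])
        markers = build_snpldb(gm, [LDBlock("1", 1000, 2000, [0, 1])])
        assert markers[0].is_monomorphic

    def test_missing_calls_rejected(self):
        gm = make_genotypes(["00.1"])
        with pytest.raises(ValueError, match="impute"):
            build_snpldb(gm, [])


class TestMarkerStats:
    def test_monomorphic_all_zero(self):
        assert marker_stats({"A": 1.0}) == (0.0, pytest.approx(0.0), pytest.approx(0.0))

    def test_biallelic_half(self):
        maf, div, pic = marker_stats({"A": 0.5, "G": 0.5})
        assert (maf, div, pic) == (0.5, pytest.approx(0.5), pytest.approx(0.375))

    def test_three_alleles_brute_force(self):
        freqs = [0.5, 0.25, 0.25]
        maf, div, pic = marker_stats(freqs)
        assert div == pytest.approx(0.625)
        sum_p2 = sum(p**2 for p in freqs)
        cross = sum(
            2 * freqs[k] ** 2 * freqs[l] ** 2
            for k in range(3)
            for l in range(k + 1, 3)
        )
        assert pic == pytest.approx(1 - sum_p2 - cross)
        assert maf == 0.25

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=6)
    )
    def test_pic_never_exceeds_diversity(self, raw):
        freqs = [x / sum(raw) for x in raw]
        _maf, div, pic = marker_stats(freqs)
        assert pic <= div + 1e-12
        if len(freqs) == 1:
            assert pic == pytest.approx(div)


class TestSNPLDBTransformer:
    def test_fit_transform_shapes(self, default_panel):
        _cfg, gm, _truth, _crosses = default_panel
        tf = SNPLDBTransformer().fit(gm)
        matrix = tf.transform(None)
        assert list(matrix.index) == gm.parents
        assert set(matrix.columns) == {m.marker_id for m in tf.markers_}
        assert (tf.stats_["pic"] <= tf.stats_["gene_diversity"] + 1e-12).all()

    def test_sklearn_clone(self):
        from sklearn.base import clone

        tf = SNPLDBTransformer(max_distance=100_000)
        assert clone(tf).get_params()["max_distance"] == 100_000

    def test_unfitted_transform_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            SNPLDBTransformer().transform(None)
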