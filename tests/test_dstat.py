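"""D-statistics: pattern sums, arrangements, jackknife, BH, heatmaps."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petalspectrum.dstat import (
    DStatistics,
    GenotypeTable,
    PatternSums,
    arrange_trio,
    bh_adjust,
    d_statistic,
    heatmap_matrix,
    jackknife_significance,
    site_pattern_sums,
    TrioDResult,
)
from petalspectrum.exceptions import (
    InputError,
    InsufficientBlocksError,
    MappingError,
)
from petalspectrum.simulate import TrioSimSpec, gen_tree, sim_genotypes


def table_from_freqs(rows, blocks=None):
    freqs = pd.DataFrame(rows, columns=["P1", "P2", "P3", "OUT"])
    if blocks is None:
        blocks = np.zeros(len(freqs), dtype=int)
    return GenotypeTable(freqs, blocks, outgroup="OUT")


def sums_from_totals(abba, baba, bbaa, trio=("A", "B", "C"), n_blocks=1):
    frame = pd.DataFrame(
        {
            "abba": np.full(n_blocks, abba / n_blocks),
            "baba": np.full(n_blocks, baba / n_blocks),
            "bbaa": np.full(n_blocks, bbaa / n_blocks),
        },
        index=pd.Index(range(n_blocks), name="block"),
    )
    return PatternSums(trio=trio, blocks=frame)


class TestPatternSums:
    def test_single_site_definitions(self):
        s = site_pattern_sums(table_from_freqs([[0, 1, 1, 0]]), ("P1", "P2", "P3"))
        assert s.totals() == (1.0, 0.0, 0.0)
        s = site_pattern_sums(table_from_freqs([[1, 0, 1, 0]]), ("P1", "P2", "P3"))
        assert s.totals() == (0.0, 1.0, 0.0)
        s = site_pattern_sums(table_from_freqs([[1, 1, 0, 0]]), ("P1", "P2", "P3"))
        assert s.totals() == (0.0, 0.0, 1.0)

    def test_two_site_hand_sum(self):
        s = site_pattern_sums(
            table_from_freqs([[0, 1, 1, 0], [1, 0, 1, 0]]), ("P1", "P2", "P3")
        )
        assert s.totals() == (1.0, 1.0, 0.0)

    def test_invariant_site_contributes_nothing(self):
        s = site_pattern_sums(table_from_freqs([[0, 0, 0, 0]]), ("P1", "P2", "P3"))
        assert s.totals() == (0.0, 0.0, 0.0)

    def test_outgroup_downweights(self):
        s = site_pattern_sums(table_from_freqs([[0, 1, 1, 0.5]]), ("P1", "P2", "P3"))
        assert s.abba == 0.5

    def test_unknown_population(self):
        with pytest.raises(MappingError):
            site_pattern_sums(table_from_freqs([[0, 1, 1, 0]]), ("P1", "P2", "PX"))
        with pytest.raises(InputError):
            site_pattern_sums(table_from_freqs([[0, 1, 1, 0]]), ("P1", "P2", "OUT"))

    def test_frequency_and_fixed_site_agreement(self):
        # oracle: direct pattern counting on fixed sites
        rng = np.random.default_rng(0)
        geno = rng.integers(0, 2, size=(500, 4)).astype(float)
        t = table_from_freqs(geno)
        s = site_pattern_sums(t, ("P1", "P2", "P3"))
        p1, p2, p3, po = geno.T
        abba = int(np.sum((p1 == 0) & (p2 == 1) & (p3 == 1) & (po == 0)))
        baba = int(np.sum((p1 == 1) & (p2 == 0) & (p3 == 1) & (po == 0)))
        bbaa = int(np.sum((p1 == 1) & (p2 == 1) & (p3 == 0) & (po == 0)))
        assert s.totals() == (abba, baba, bbaa)


class TestDStatistic:
    @pytest.mark.parametrize(
        "abba,baba,expected",
        [(120, 120, 0.0), (300, 100, 0.5), (0, 5, -1.0), (5, 0, 1.0)],
    )
    def test_arithmetic(self, abba, baba, expected):
        assert d_statistic((abba, baba)) == expected

    def test_zero_denominator_flagged_nan(self):
        assert np.isnan(d_statistic((0, 0)))

    @given(st.integers(1, 10_000), st.integers(0, 10_000))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_bounded_and_antisymmetric(self, a, b):
        d = d_statistic((a, b))
        assert -1.0 <= d <= 1.0
        assert d_statistic((b, a)) == pytest.approx(-d)


class TestArrangement:
    def test_bbaa_mode_hand_example(self):
        # base sums (ABBA, BABA, BBAA) = (300, 100, 200): the 300-pattern pair
        # plays BBAA, remaining D = (200 - 100) / 300
        arr, tie = arrange_trio(sums_from_totals(300, 100, 200), "BBAA")
        blk = arr["blocks"]
        assert not tie
        assert abs(d_statistic((blk["abba"].sum(), blk["baba"].sum())) - 1 / 3) < 1e-12

    def test_min_mode_hand_example(self):
        arr, _ = arrange_trio(sums_from_totals(300, 100, 200), "min")
        blk = arr["blocks"]
        d = d_statistic((blk["abba"].sum(), blk["baba"].sum()))
        assert abs(d - 0.2) < 1e-12  # min of (0.5, 0.2, 1/3)

    def test_min_never_exceeds_other_modes(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            a, b, c = rng.integers(1, 500, size=3).astype(float)
            s = sums_from_totals(a, b, c)
            d_min = d_statistic_of(arrange_trio(s, "min")[0])
            d_bbaa = d_statistic_of(arrange_trio(s, "BBAA")[0])
            assert abs(d_min) <= abs(d_bbaa) + 1e-12

    def test_tree_mode_follows_supplied_topology(self):
        tree = gen_tree(8, seed=1)
        a, b = sorted(
            [tree.tip_labels[i] for i in tree.children[tree.root] if i < tree.n_tips]
            or [tree.tip_labels[0], tree.tip_labels[1]]
        )[:2]
        # pick an actual cherry for determinism
        cherry = None
        for node in range(tree.n_tips, tree.n_nodes):
            kids = tree.children[node]
            if all(k < tree.n_tips for k in kids):
                cherry = sorted(tree.tip_labels[k] for k in kids)
                break
        other = next(t for t in tree.tip_labels if t not in cherry)
        s = sums_from_totals(999, 1, 1, trio=(cherry[0], other, cherry[1]))
        arr, _ = arrange_trio(s, "tree", species_tree=tree)
        assert set(arr["trio"][:2]) == set(cherry)  # regardless of the sums

    def test_tree_mode_requires_tree_and_taxa(self):
        s = sums_from_totals(1, 1, 1)
        with pytest.raises(InputError):
            arrange_trio(s, "tree")
        with pytest.raises(MappingError):
            arrange_trio(s, "tree", species_tree=gen_tree(4, seed=0))

    def test_three_way_tie_flagged(self):
        arr, tie = arrange_trio(sums_from_totals(100, 100, 100), "BBAA")
        assert tie


def d_statistic_of(arr):
    blk = arr["blocks"]
    return d_statistic((blk["abba"].sum(), blk["baba"].sum()))


class TestJackknife:
    def test_identical_blocks_degenerate(self):
        s = sums_from_totals(600, 400, 0, n_blocks=10)  # D = 0.2 in every block
        D, se, z, p, flag = jackknife_significance(s.blocks)
        assert D == pytest.approx(0.2)
        assert se == 0.0 and p == 0.0 and flag

    def test_insufficient_blocks(self):
        s = sums_from_totals(10, 5, 0, n_blocks=1)
        with pytest.raises(InsufficientBlocksError):
            jackknife_significance(s.blocks)

    def test_admixture_detected_with_large_z(self):
        g = sim_genotypes(
            TrioSimSpec(n_sites=100_000, baseline_discordance=0.1,
                        admixture_excess=0.1, concordant_prob=0.3,
                        block_size=5000, seed=9)
        )
        s = site_pattern_sums(g, ("P1", "P2", "P3"))
        D, se, z, p, _ = jackknife_significance(s.blocks)
        assert z > 3
        assert abs(D - 1 / 3) < 0.05

    def test_jackknife_depends_on_blocks_not_site_order(self):
        g = sim_genotypes(TrioSimSpec(n_sites=5000, admixture_excess=0.05,
                                      block_size=250, seed=3))
        s = site_pattern_sums(g, ("P1", "P2", "P3"))
        # permute sites, then restore block contiguity: per-block sums (and the
        # jackknife) must only depend on the block partition
        perm = np.random.default_rng(0).permutation(len(g.freqs))
        order = np.argsort(g.blocks[perm], kind="stable")
        t2 = GenotypeTable(g.freqs.iloc[perm].iloc[order].reset_index(drop=True),
                           np.sort(g.blocks[perm]), outgroup="OUT")
        s2 = site_pattern_sums(t2, ("P1", "P2", "P3"))
        r1 = jackknife_significance(s.blocks)
        r2 = jackknife_significance(s2.blocks)
        assert r1[0] == pytest.approx(r2[0])
        assert r1[1] == pytest.approx(r2[1])


class TestBH:
    def test_step_up_hand_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_saturated(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InputError):
            bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_adjusted_never_below_raw(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0)


class TestHeatmap:
    def _res(self, p2, p3, D, Z):
        return TrioDResult(P1="x", P2=p2, P3=p3, mode="BBAA", abba=1, baba=1,
                           bbaa=1, D=D, se=0.1, Z=Z, p=0.05, p_adj=0.1, blocks=5)

    def test_single_result_single_cell(self):
        Dm, Pm = heatmap_matrix([self._res("b", "c", 0.4, 4.0)])
        assert Dm.shape == (1, 1)
        assert Dm.loc["b", "c"] == 0.4

    def test_max_abs_z_wins(self):
        Dm, _ = heatmap_matrix(
            [self._res("b", "c", 0.1, 2.0), self._res("b", "c", 0.5, 5.0)]
        )
        assert Dm.loc["b", "c"] == 0.5

    def test_labels_sorted_and_missing_nan(self):
        Dm, _ = heatmap_matrix(
            [self._res("b", "c", 0.1, 2.0), self._res("a", "d", 0.2, 3.0)]
        )
        assert list(Dm.index) == ["a", "b"]
        assert list(Dm.columns) == ["c", "d"]
        assert np.isnan(Dm.loc["a", "c"])

    def test_mixed_modes_rejected(self):
        r1 = self._res("b", "c", 0.1, 2.0)
        r2 = self._res("b", "d", 0.1, 2.0)
        r2.mode = "min"
        with pytest.raises(InputError):
            heatmap_matrix([r1, r2])


class TestAntisymmetryAndModel:
    def test_swapping_p1_p2_negates_d(self):
        rng = np.random.default_rng(2)
        freqs = rng.random((300, 4))
        freqs[:, 3] = 0.0
        t = table_from_freqs(freqs)
        d12 = d_statistic(site_pattern_sums(t, ("P1", "P2", "P3")))
        d21 = d_statistic(site_pattern_sums(t, ("P2", "P1", "P3")))
        assert d12 == pytest.approx(-d21)

    def test_fit_produces_adjusted_table(self):
        g = sim_genotypes(TrioSimSpec(n_sites=20_000, admixture_excess=0.1,
                                      concordant_prob=0.3, block_size=1000, seed=4))
        res = DStatistics(g).fit(mode="BBAA")
        assert len(res.table) == 1
        row = res.table.iloc[0]
        assert row["p_adj"] >= row["p"] - 1e-15
        assert "significant" in res.summary()

    def test_long_csv_round_trip(self, tmp_path):
        g = sim_genotypes(TrioSimSpec(n_sites=500, n_individuals=2,
                                      admixture_excess=0.1, block_size=50, seed=6))
        path = tmp_path / "g.csv"
        g.to_long_csv(path)
        back = GenotypeTable.from_long_csv(path, outgroup="OUT", n_blocks=10)
        pd.testing.assert_frame_equal(
            back.freqs[g.freqs.columns].astype(float), g.freqs.astype(float),
            check_exact=False,
        )
        d1 = d_statistic(site_pattern_sums(g, ("P1", "P2", "P3")))
        d2 = d_statistic(site_pattern_sums(back, ("P1", "P2", "P3")))
        assert d1 == pytest.approx(d2)
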