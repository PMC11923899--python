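"""Cluster metrics, partnerships and coupling statistics."""

import numpy as np
import pandas as pd
import pytest

from cortexclust import (
    CellTable,
    class_balance_test,
    coupling_stats,
    coverage_stats,
    ei_ratio,
    find_partners,
    interregional_enrichment,
    interregional_flag,
    jaccard,
    layer_class_proportions,
    mean_nn_distance,
    nearest_opposite_cluster,
    summarize_clusters,
)
from cortexclust.cluster_props import adjacent_opposite_pairs, assigned_region
from cortexclust.synthetic_data import generate_coupled_pairs

from conftest import make_cells_df, make_cluster


class TestEIRatio:
    def test_basic_ratio(self):
        df = make_cells_df(
            [(i, 0) for i in range(15)],
            cls=["excitatory"] * 10 + ["inhibitory"] * 5,
        )
        assert ei_ratio(make_cluster(df, range(15), "excitatory")) == 2.0

    def test_pure_excitatory_is_undefined(self):
        df = make_cells_df([(i, 0) for i in range(7)])
        c = make_cluster(df, range(7), "excitatory")
        assert np.isnan(ei_ratio(c))
        summary = summarize_clusters([c])
        assert summary["pure"].iloc[0] == "excitatory"

    def test_pure_inhibitory_is_zero(self):
        df = make_cells_df([(i, 0) for i in range(4)], cls=["inhibitory"] * 4)
        assert ei_ratio(make_cluster(df, range(4), "inhibitory")) == 0.0


class TestMeanNNDistance:
    def test_collinear_cells(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        assert mean_nn_distance(xy) == pytest.approx(40.0 / 3)

    def test_two_cells(self):
        assert mean_nn_distance(np.array([[0.0, 0.0], [3.0, 4.0]])) == 5.0

    def test_single_cell_undefined(self):
        assert np.isnan(mean_nn_distance(np.array([[1.0, 1.0]])))

    def test_matches_brute_force_on_random_points(self):
        rng = np.random.default_rng(7)
        xy = rng.uniform(0, 100, (50, 2))
        d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        np.fill_diagonal(d, np.inf)
        assert mean_nn_distance(xy) == pytest.approx(d.min(axis=1).mean())

    def test_all_pairs_mode(self):
        xy = np.array([[0.0, 0.0], [10.0, 0.0], [30.0, 0.0]])
        assert mean_nn_distance(xy, all_pairs=True) == pytest.approx((10 + 30 + 20) / 3)


class TestRegions:
    def test_interregional_flag(self):
        df = make_cells_df([(0, 0), (1, 1)], region=["V1", "V1"])
        assert not interregional_flag(make_cluster(df, [0, 1], "excitatory"))
        df2 = make_cells_df([(0, 0), (1, 1), (2, 2), (3, 3)], region=["V1", "V1", "V2", "V4"])
        assert interregional_flag(make_cluster(df2, range(4), "excitatory"))

    def test_assigned_region_plurality_and_tie(self):
        df = make_cells_df([(i, 0) for i in range(5)], region=["B", "B", "A", "A", "A"])
        assert assigned_region(make_cluster(df, range(5), "excitatory")) == "A"
        df_tie = make_cells_df([(i, 0) for i in range(4)], region=["B", "B", "A", "A"])
        assert assigned_region(make_cluster(df_tie, range(4), "excitatory")) == "A"


class TestCoverage:
    def test_all_cells_in_clusters(self):
        df = make_cells_df([(i, 0) for i in range(4)])
        table = CellTable(df)
        cov = coverage_stats([make_cluster(df, range(4), "excitatory")], table)
        assert cov.overall == 1.0

    def test_no_clusters(self):
        table = CellTable(make_cells_df([(0, 0)]))
        assert coverage_stats([], table).overall == 0.0

    def test_two_section_toy_fraction_and_sem(self):
        # section A: 3 of 4 clustered; section B: 1 of 4 -> overall 0.5,
        # SEM over {0.75, 0.25} = 0.25.
        df = make_cells_df(
            [(i * 10.0, 0.0) for i in range(8)],
            section=["A"] * 4 + ["B"] * 4,
        )
        table = CellTable(df)
        clusters = [
            make_cluster(df, [0, 1, 2], "excitatory"),
            make_cluster(df, [4], "excitatory"),
        ]
        cov = coverage_stats(clusters, table)
        assert cov.overall == pytest.approx(0.5)
        assert cov.per_section == {"A": 0.75, "B": 0.25}
        assert cov.sem_overall == pytest.approx(0.25)


class TestLayerProportions:
    def test_eighty_twenty(self):
        df = make_cells_df(
            [(i, 0) for i in range(100)],
            cls=["excitatory"] * 80 + ["inhibitory"] * 20,
        )
        props, _ = layer_class_proportions(CellTable(df))
        row = props.iloc[0]
        assert (row["prop_exc"], row["prop_inh"]) == (0.8, 0.2)

    def test_proportional_counts_give_r_one(self):
        # E=(10,20,30), I=(1,2,3) across three regions -> Pearson r = 1.
        rows = []
        for region, ne, ni in [("A", 10, 1), ("B", 20, 2), ("C", 30, 3)]:
            rows += [("excitatory", region)] * ne + [("inhibitory", region)] * ni
        df = make_cells_df(
            [(i, 0) for i in range(len(rows))],
            cls=[r[0] for r in rows],
            region=[r[1] for r in rows],
        )
        _, corr = layer_class_proportions(CellTable(df))
        assert corr["r"].iloc[0] == pytest.approx(1.0)


class TestClassBalance:
    def test_observed_equals_expected(self):
        stat, p = class_balance_test(50, 50, 0.5)
        assert stat == 0.0 and p == 1.0

    def test_hand_computed_chi_square(self):
        stat, _ = class_balance_test(60, 40, 0.5)
        assert stat == pytest.approx(4.0)

    def test_zero_expected_rejected(self):
        with pytest.raises(ValueError):
            class_balance_test(10, 0, 0.0)


class TestPartnersAndJaccard:
    def test_jaccard_values(self):
        assert jaccard(4, 6, 2) == 0.25
        assert jaccard(5, 5, 5) == 1.0
        assert jaccard(3, 4, 0) == 0.0
        with pytest.raises(ValueError):
            jaccard(3, 4, 5)

    def test_single_shared_cell_pair(self):
        df = make_cells_df([(i * 10.0, 0.0) for i in range(5)])
        e = make_cluster(df, [0, 1, 2], "excitatory", cid="E:1")
        i = make_cluster(df, [2, 3], "inhibitory", cid="I:1")
        pairs, counts = find_partners([e, i])
        assert len(pairs) == 1
        row = pairs.iloc[0]
        assert row["shared"] == 1 and row["jaccard"] == 0.25
        assert dict(zip(counts["cluster_id"], counts["n_partners"])) == {
            "E:1": 1,
            "I:1": 1,
        }

    def test_disjoint_clusters_no_pair(self):
        df = make_cells_df([(i * 10.0, 0.0) for i in range(4)])
        e = make_cluster(df, [0, 1], "excitatory")
        i = make_cluster(df, [2, 3], "inhibitory")
        pairs, counts = find_partners([e, i])
        assert len(pairs) == 0
        assert (counts["n_partners"] == 0).all()

    def test_matches_brute_force_intersections(self):
        rng = np.random.default_rng(11)
        df = make_cells_df([(i * 5.0, 0.0) for i in range(60)])
        # same-type clusters must be disjoint: partition cells
        perm = rng.permutation(60)
        e_sets = [perm[0:12], perm[12:20], perm[20:30]]
        perm2 = rng.permutation(60)
        i_sets = [perm2[0:9], perm2[9:25], perm2[25:31], perm2[31:40]]
        clusters = [
            make_cluster(df, s, "excitatory", cid=f"E:{k}") for k, s in enumerate(e_sets)
        ] + [
            make_cluster(df, s, "inhibitory", cid=f"I:{k}") for k, s in enumerate(i_sets)
        ]
        pairs, _ = find_partners(clusters)
        got = {
            (r.exc_cluster_id, r.inh_cluster_id): r.shared for r in pairs.itertuples()
        }
        expect = {}
        for ke, se in enumerate(e_sets):
            for ki, si in enumerate(i_sets):
                ov = len(set(se) & set(si))
                if ov:
                    expect[(f"E:{ke}", f"I:{ki}")] = ov
        assert got == expect

    def test_jaccard_bounded_by_overlap_fractions(self):
        df = make_cells_df([(i * 5.0, 0.0) for i in range(30)])
        e = make_cluster(df, range(0, 20), "excitatory")
        i = make_cluster(df, range(15, 30), "inhibitory")
        pairs, _ = find_partners([e, i])
        row = pairs.iloc[0]
        assert row["jaccard"] <= min(row["frac_exc"], row["frac_inh"])


class TestNearestOpposite:
    def test_overlapping_clusters_distance_zero(self):
        df = make_cells_df([(i * 10.0, 0.0) for i in range(4)])
        e = make_cluster(df, [0, 1, 2], "excitatory")
        i = make_cluster(df, [2, 3], "inhibitory")
        _, d = nearest_opposite_cluster(e, [e, i])
        assert d == 0.0

    def test_singletons_hundred_apart(self):
        df = make_cells_df([(0.0, 0.0), (100.0, 0.0)], cls=["excitatory", "inhibitory"])
        e = make_cluster(df, [0], "excitatory")
        i = make_cluster(df, [1], "inhibitory")
        cid, d = nearest_opposite_cluster(e, [i])
        assert d == 100.0 and cid == i.cluster_id

    def test_matches_brute_force_min_pair_distance(self):
        rng = np.random.default_rng(2)
        df = make_cells_df(rng.uniform(0, 200, (30, 2)))
        e = make_cluster(df, range(0, 10), "excitatory")
        i1 = make_cluster(df, range(10, 20), "inhibitory", cid="I:a")
        i2 = make_cluster(df, range(20, 30), "inhibitory", cid="I:b")
        cid, d = nearest_opposite_cluster(e, [i1, i2])
        best = {}
        for c in (i1, i2):
            dd = np.sqrt(
                ((e.xy[:, None, :] - c.xy[None, :, :]) ** 2).sum(-1)
            ).min()
            best[c.cluster_id] = dd
        expect_id = min(best, key=lambda k: (best[k], k))
        assert cid == expect_id and d == pytest.approx(best[expect_id])

    def test_no_candidate_raises(self):
        df = make_cells_df([(0, 0)])
        e = make_cluster(df, [0], "excitatory")
        with pytest.raises(ValueError):
            nearest_opposite_cluster(e, [e])


class TestCouplingStats:
    def test_identical_ratios_give_r_one(self):
        summary, pairs, counts = generate_coupled_pairs(n_pairs=30, r=1.0, seed=0,
                                                        sd_ratio=(0.5, 0.5),
                                                        mean_ratio=(3.0, 3.0))
        out = coupling_stats(summary, pairs, counts)
        assert out["partner_ei_coupling"].r == pytest.approx(1.0, abs=0.02)

    def test_sampling_distribution_near_true_r(self):
        summary, pairs, counts = generate_coupled_pairs(n_pairs=500, r=0.5, seed=1)
        out = coupling_stats(summary, pairs, counts)
        assert abs(out["partner_ei_coupling"].r - 0.5) <= 0.1

    def test_fewer_than_three_pairs_undefined(self):
        summary, pairs, counts = generate_coupled_pairs(n_pairs=2, r=0.5, seed=2)
        out = coupling_stats(summary, pairs, counts)
        assert not out["partner_ei_coupling"].defined


class TestInterregionalEnrichment:
    @staticmethod
    def _summary(rows):
        df = pd.DataFrame(rows)
        return df.set_index("cluster_id", drop=False)

    def test_equal_fractions_give_or_one(self):
        rows = []
        k = 0
        for layer in (1, 2):
            for inter in [True] * 10 + [False] * 90:
                rows.append(
                    {"cluster_id": f"c{k}", "type": "excitatory", "layer": layer,
                     "interregional": inter}
                )
                k += 1
        out = interregional_enrichment(self._summary(rows))
        assert np.allclose(out["odds_ratio"], 1.0)

    def test_hand_computed_odds_ratio(self):
        # layer 1: 10/90 interregional; layer 2: 5/95 -> OR = (10*95)/(90*5).
        rows = []
        k = 0
        for layer, n_inter, n_intra in [(1, 10, 90), (2, 5, 95)]:
            for inter in [True] * n_inter + [False] * n_intra:
                rows.append(
                    {"cluster_id": f"c{k}", "type": "excitatory", "layer": layer,
                     "interregional": inter}
                )
                k += 1
        out = interregional_enrichment(self._summary(rows))
        row = out[out["layer"] == 1].iloc[0]
        assert row["odds_ratio"] == pytest.approx(10 * 95 / (90 * 5))
        assert not row["haldane_corrected"]
        assert row["ci_low"] < row["odds_ratio"] < row["ci_high"]

    def test_zero_cell_triggers_haldane_correction(self):
        rows = []
        k = 0
        for layer, n_inter, n_intra in [(1, 0, 50), (2, 5, 45)]:
            for inter in [True] * n_inter + [False] * n_intra:
                rows.append(
                    {"cluster_id": f"c{k}", "type": "excitatory", "layer": layer,
                     "interregional": inter}
                )
                k += 1
        out = interregional_enrichment(self._summary(rows))
        assert out[out["layer"] == 1].iloc[0]["haldane_corrected"]


class TestAdjacentOppositePairs:
    def test_nearest_non_partner_pairs_reported(self):
        df = make_cells_df(
            [(0, 0), (10, 0), (200, 0), (210, 0), (1000, 0), (1010, 0)],
            cls=["excitatory"] * 2 + ["inhibitory"] * 2 + ["excitatory"] * 2,
        )
        e1 = make_cluster(df, [0, 1], "excitatory", cid="E:a")
        i1 = make_cluster(df, [2, 3], "inhibitory", cid="I:a")
        e2 = make_cluster(df, [4, 5], "excitatory", cid="E:b")
        out = adjacent_opposite_pairs([e1, i1, e2])
        assert set(zip(out["exc_cluster_id"], out["inh_cluster_id"])) == {
            ("E:a", "I:a"),
            ("E:b", "I:a"),
        }
        d = out.set_index("exc_cluster_id")["distance"]
        assert d["E:a"] == pytest.approx(190.0)
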