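"""Composition vectors, grouping, enrichment and hierarchy correlations."""

import numpy as np
import pandas as pd
import pytest

from cortexclust import (
    CellTable,
    RegionAnnotation,
    adjacent_similarity_test,
    composition_vectors,
    functional_enrichment,
    hierarchical_groups,
    hierarchy_correlation,
)
from cortexclust.composition_analysis import group_system_summary
from cortexclust.io_model import RegionInfo
from scipy.stats import mannwhitneyu

from conftest import make_cells_df, make_cluster


def annotation(**info):
    return RegionAnnotation(
        {k: RegionInfo(None, frozenset(v.get("systems", ())), v.get("level")) for k, v in info.items()}
    )


class TestCompositionVectors:
    def test_proportions_and_presence(self):
        df = make_cells_df(
            [(i * 10.0, 0.0) for i in range(4)],
            cls=["excitatory", "excitatory", "excitatory", "inhibitory"],
            subclass=["L2", "L2", "L2.3", "PV_CHC"],
        )
        table = CellTable(df)
        props, presence = composition_vectors([make_cluster(df, range(4), "excitatory")], table)
        row = props.iloc[0]
        assert row["L2"] == 0.5 and row["L2.3"] == 0.25 and row["PV_CHC"] == 0.25
        assert props.sum(axis=1).iloc[0] == pytest.approx(1.0)
        assert presence.iloc[0].sum() == 3

    def test_single_subclass_is_one_hot(self):
        df = make_cells_df([(0, 0), (1, 1)], subclass=["L2", "L2"])
        table = CellTable(df)
        props, presence = composition_vectors([make_cluster(df, [0, 1], "excitatory")], table)
        assert props.iloc[0]["L2"] == 1.0
        assert presence.iloc[0].sum() == 1


class TestHierarchicalGroups:
    @staticmethod
    def _presence(rows, ids=None):
        ids = ids or [f"c{i}" for i in range(len(rows))]
        return pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(len(rows[0]))])

    def test_two_identical_blocks_recovered(self):
        rows = [[1, 1, 0, 0]] * 4 + [[0, 0, 1, 1]] * 3
        groups = hierarchical_groups(self._presence(rows), k=2)
        assert groups.nunique() == 2
        assert groups.iloc[:4].nunique() == 1 and groups.iloc[4:].nunique() == 1
        assert groups.iloc[0] == "h1"  # larger block labelled first

    def test_all_identical_single_group(self):
        rows = [[1, 0, 1]] * 5
        groups = hierarchical_groups(self._presence(rows), k=1)
        assert set(groups) == {"h1"}

    def test_noisy_three_block_recovery(self):
        rng = np.random.default_rng(0)
        base = {0: [1, 1, 0, 0, 0, 0], 1: [0, 0, 1, 1, 0, 0], 2: [0, 0, 0, 0, 1, 1]}
        rows, labels = [], []
        for i in range(12):
            b = i % 3
            v = list(base[b])
            if i == 5:  # one bit of noise
                v[0] ^= 1
            rows.append(v)
            labels.append(b)
        groups = hierarchical_groups(self._presence(rows), k=3)
        # majority ground-truth block per recovered group must cover >= 10/12
        correct = 0
        for g in groups.unique():
            members = [i for i in range(12) if groups.iloc[i] == g]
            block = max(set(labels[i] for i in members), key=lambda b: sum(labels[i] == b for i in members))
            correct += sum(labels[i] == block for i in members)
        assert correct >= 10

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_groups(self._presence([[1, 0]]), k=3)

    def test_deterministic_partition(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 2, (10, 5)).tolist()
        p = self._presence(rows)
        a = hierarchical_groups(p, k=3)
        b = hierarchical_groups(p, k=3)
        pd.testing.assert_series_equal(a, b)


class TestFunctionalEnrichment:
    @staticmethod
    def _summary(regions, ids=None):
        ids = ids or [f"c{i}" for i in range(len(regions))]
        df = pd.DataFrame(
            {"cluster_id": ids, "assigned_region": regions, "type": "excitatory",
             "layer": 2, "size": 10, "ei_ratio": 1.0}
        )
        return df.set_index("cluster_id", drop=False)

    def test_pure_system_group_flagged(self):
        regions = ["V1"] * 6 + ["BG"] * 6
        groups = pd.Series(["h1"] * 6 + ["h2"] * 6, index=[f"c{i}" for i in range(12)])
        ann = annotation(V1={"systems": {"visual"}})
        out = functional_enrichment(groups, self._summary(regions), ann)
        row = out[(out["group"] == "h1") & (out["system"] == "visual")].iloc[0]
        assert row["enriched"]
        assert row["p_adj"] < 0.05

    def test_background_matched_group_not_enriched(self):
        regions = (["V1", "BG"] * 3) + (["V1", "BG"] * 3)
        groups = pd.Series(["h1"] * 6 + ["h2"] * 6, index=[f"c{i}" for i in range(12)])
        ann = annotation(V1={"systems": {"visual"}})
        out = functional_enrichment(groups, self._summary(regions), ann)
        row = out[(out["group"] == "h1") & (out["system"] == "visual")].iloc[0]
        assert not row["enriched"]
        assert row["p"] > 0.5

    def test_bh_adjustment_monotone_and_at_least_raw(self):
        regions = ["V1"] * 4 + ["PG"] * 4 + ["BG"] * 4
        groups = pd.Series(
            ["h1"] * 4 + ["h2"] * 4 + ["h3"] * 4, index=[f"c{i}" for i in range(12)]
        )
        ann = annotation(V1={"systems": {"visual"}}, PG={"systems": {"somatosensory"}})
        out = functional_enrichment(groups, self._summary(regions), ann)
        assert (out["p_adj"] >= out["p"] - 1e-12).all()
        s = out.sort_values("p")
        assert s["p_adj"].is_monotonic_increasing

    def test_invariant_to_relabeling_background_regions(self):
        regions_a = ["V1"] * 4 + ["BG1"] * 8
        regions_b = ["V1"] * 4 + ["BG2"] * 8
        groups = pd.Series(["h1"] * 4 + ["h2"] * 8, index=[f"c{i}" for i in range(12)])
        ann = annotation(V1={"systems": {"visual"}})
        pa = functional_enrichment(groups, self._summary(regions_a), ann)["p"]
        pb = functional_enrichment(groups, self._summary(regions_b), ann)["p"]
        assert np.allclose(pa, pb)


class TestHierarchyCorrelation:
    @staticmethod
    def _summary(levels_sizes, ctype="excitatory"):
        rows = []
        for i, (region, size) in enumerate(levels_sizes):
            rows.append(
                {"cluster_id": f"c{i}", "type": ctype, "assigned_region": region,
                 "size": size, "ei_ratio": 1.0}
            )
        return pd.DataFrame(rows).set_index("cluster_id", drop=False)

    def test_decreasing_sizes_give_negative_r(self):
        ann = annotation(A={"level": 1}, B={"level": 2}, C={"level": 3})
        summary = self._summary([("A", 1000), ("B", 100), ("C", 10)])
        out = hierarchy_correlation(summary, ann)
        row = out[(out["type"] == "excitatory") & (out["metric"] == "log10_size")].iloc[0]
        assert row["r"] == pytest.approx(-1.0)

    def test_three_point_closed_form(self):
        # levels (1,2,3), log10 sizes (2, 1.7, 1.0): closed-form Pearson.
        ann = annotation(A={"level": 1}, B={"level": 2}, C={"level": 3})
        summary = self._summary([("A", 100), ("B", 50), ("C", 10)])
        x = np.array([1.0, 2.0, 3.0])
        y = np.log10([100.0, 50.0, 10.0])
        expect = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        out = hierarchy_correlation(summary, ann)
        row = out[(out["type"] == "excitatory") & (out["metric"] == "log10_size")].iloc[0]
        assert row["r"] == pytest.approx(expect)

    def test_constant_sizes_degenerate(self):
        ann = annotation(A={"level": 1}, B={"level": 2}, C={"level": 3})
        summary = self._summary([("A", 50), ("B", 50), ("C", 50)])
        out = hierarchy_correlation(summary, ann)
        row = out[(out["type"] == "excitatory") & (out["metric"] == "log10_size")].iloc[0]
        assert np.isnan(row["r"]) and row["n"] == 3

    def test_unleveled_regions_excluded(self):
        ann = annotation(A={"level": 1}, B={"level": 2})
        summary = self._summary([("A", 100), ("B", 10), ("X", 1000), ("Y", 2)])
        out = hierarchy_correlation(summary, ann)
        row = out[(out["type"] == "excitatory") & (out["metric"] == "log10_size")].iloc[0]
        assert row["n"] == 2


class TestAdjacentSimilarity:
    def test_planted_mixture_structure_detected(self):
        # 60 pairs; members of a pair sit together and share a subclass
        # mixture; different pairs use different mixtures.
        rng = np.random.default_rng(4)
        evoc = ["L2", "L2.3", "L2.3.4", "L3.4", "L3.4.5"]
        frames, clusters_spec = [], []
        cell_count = 0
        for k in range(60):
            mix = np.zeros(5)
            picks = rng.choice(5, 2, replace=False)
            mix[picks] = [0.7, 0.3]
            cx = (k % 10) * 5000.0
            cy = (k // 10) * 5000.0
            for side, dx in ((0, 0.0), (1, 400.0)):
                n = 20
                subs = rng.choice(evoc, n, p=mix)
                xy = np.column_stack(
                    [cx + dx + rng.uniform(0, 100, n), cy + rng.uniform(0, 100, n)]
                )
                df = make_cells_df(xy, subclass=subs, prefix=f"p{k}s{side}_")
                frames.append(df)
                clusters_spec.append((cell_count, n, f"E:S1:L2:p{k:02d}s{side}"))
                cell_count += n
        df_all = pd.concat(frames, ignore_index=True)
        table = CellTable(df_all)
        clusters = [
            make_cluster(df_all, range(start, start + n), "excitatory", cid=cid)
            for start, n, cid in clusters_spec
        ]
        props, _ = composition_vectors(clusters, table)
        report = adjacent_similarity_test(clusters, props, seed=0)
        assert report.median_adjacent_pearson > report.median_control_pearson
        assert report.p_pearson < 0.05

    def test_identical_vectors_similarity_one(self):
        df = make_cells_df(
            [(0, 0), (10, 0), (20, 0), (5000, 0), (5010, 0), (5020, 0)],
            subclass=["L2", "L2", "L2.3", "L2", "L2", "L2.3"],
        )
        table = CellTable(df)
        clusters = [
            make_cluster(df, [0, 1, 2], "excitatory", cid="E:a"),
            make_cluster(df, [3, 4, 5], "excitatory", cid="E:b"),
        ]
        props, _ = composition_vectors(clusters, table)
        report = adjacent_similarity_test(clusters, props, seed=0)
        assert report.adjacent["pearson"].iloc[0] == pytest.approx(1.0)


class TestGroupSummaryAndContrasts:
    def test_two_group_summary_matches_hand_values(self):
        rows = []
        for i, (size, ratio) in enumerate([(10, 2.0), (100, 4.0), (1000, np.nan)]):
            rows.append(
                {"cluster_id": f"c{i}", "type": "excitatory", "layer": 2,
                 "size": size, "ei_ratio": ratio, "assigned_region": "R"}
            )
        summary = pd.DataFrame(rows).set_index("cluster_id", drop=False)
        groups = pd.Series(["h1", "h1", "h2"], index=summary.index)
        presence = pd.DataFrame(
            [[1, 0], [1, 1], [0, 1]], index=summary.index, columns=["L2", "L2.3"]
        )
        table, freq = group_system_summary(groups, summary, presence)
        h1 = table.set_index("group").loc["h1"]
        assert h1["mean_log10_size"] == pytest.approx(1.5)
        assert h1["mean_ei_ratio"] == pytest.approx(3.0)
        h2 = table.set_index("group").loc["h2"]
        assert np.isnan(h2["mean_ei_ratio"]) and h2["n_ei_defined"] == 0
        assert freq.loc["h1", "L2"] == 1.0 and freq.loc["h1", "L2.3"] == 0.5

    def test_planted_system_size_contrast_recovered(self):
        # DMN clusters built smaller than visual clusters: rank-sum detects
        # the sign of the contrast from the summaries.
        rng = np.random.default_rng(8)
        rows = []
        for i in range(15):
            rows.append({"cluster_id": f"d{i}", "type": "excitatory", "layer": 2,
                         "size": int(rng.integers(10, 30)), "ei_ratio": 1.0,
                         "assigned_region": "PCC"})
        for i in range(15):
            rows.append({"cluster_id": f"v{i}", "type": "excitatory", "layer": 2,
                         "size": int(rng.integers(200, 400)), "ei_ratio": 1.0,
                         "assigned_region": "V1"})
        summary = pd.DataFrame(rows).set_index("cluster_id", drop=False)
        ann = annotation(PCC={"systems": {"DMN"}}, V1={"systems": {"visual"}})
        in_dmn = summary["assigned_region"].map(lambda r: "DMN" in ann.systems_of(r))
        dmn_sizes = summary.loc[in_dmn, "size"]
        other_sizes = summary.loc[~in_dmn, "size"]
        stat, p = mannwhitneyu(dmn_sizes, other_sizes, alternative="less")
        assert dmn_sizes.median() < other_sizes.median()
        assert p < 0.05
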