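"""Cluster composition vectors, grouping and functional-region association.

Each cluster is summarized by its subclass proportion vector and a binary
presence vector over the declared vocabulary. Within a layer and cluster
type, presence vectors are grouped by agglomerative hierarchical clustering
(Jaccard distance, average linkage — the natural choice for
presence/absence data; both configurable), groups are tested for enrichment
in annotated functional systems (one-sided Fisher 2x2, Benjamini-Hochberg
adjusted), and cluster size / E-I ratio are correlated against cortical
hierarchy levels. An adjacent-vs-non-adjacent composition similarity test
asks whether neighboring same-type clusters use similar cell types.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import fisher_exact, mannwhitneyu, pearsonr, spearmanr
from statsmodels.stats.multitest import multipletests

from .io_model import SYSTEMS, CellTable, RegionAnnotation
from .window_scan import NeuronCluster

__all__ = [
    "composition_vectors",
    "AdjacencyReport",
    "adjacent_similarity_test",
    "hierarchical_groups",
    "functional_enrichment",
    "hierarchy_correlation",
    "group_system_summary",
]


def composition_vectors(
    clusters: list[NeuronCluster], table: CellTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-cluster subclass proportions and binary presence vectors.

    Both frames are indexed by cluster_id with one column per subclass of the
    full declared vocabulary (absent subclasses are 0); proportions sum to 1
    per cluster.
    """
    vocab = table.full_vocab()
    sub_codes = {s: i for i, s in enumerate(vocab)}
    codes = table.df["subclass"].map(sub_codes).to_numpy(dtype=np.int64)
    rows = []
    index = []
    for c in sorted(clusters, key=lambda c: c.cluster_id):
        counts = np.bincount(codes[c.cell_idx], minlength=len(vocab))
        rows.append(counts / counts.sum())
        index.append(c.cluster_id)
    props = pd.DataFrame(rows, index=index, columns=vocab)
    props.index.name = "cluster_id"
    presence = (props > 0).astype(int)
    return props, presence


def _pair_similarity(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if np.std(a) == 0 or np.std(b) == 0:
        return float("nan")
    if method == "pearson":
        return float(pearsonr(a, b)[0])
    return float(spearmanr(a, b)[0])


def _nearest_same_type(
    clusters: list[NeuronCluster],
) -> list[tuple[str, str]]:
    """Unordered nearest-neighbor pairs (min inter-cell distance) per stratum."""
    from scipy.spatial import cKDTree

    pairs: set[tuple[str, str]] = set()
    by_stratum: dict[tuple, list[NeuronCluster]] = {}
    for c in clusters:
        by_stratum.setdefault((c.section_id, c.layer), []).append(c)
    for group in by_stratum.values():
        if len(group) < 2:
            continue
        group = sorted(group, key=lambda c: c.cluster_id)
        trees = [cKDTree(c.xy) for c in group]
        for i, c in enumerate(group):
            best_j, best_d = None, float("inf")
            for j, other in enumerate(group):
                if j == i:
                    continue
                d = float(np.min(trees[j].query(c.xy, k=1)[0]))
                if d < best_d:
                    best_j, best_d = j, d
            if best_j is not None:
                pairs.add(tuple(sorted((c.cluster_id, group[best_j].cluster_id))))
    return sorted(pairs)


@dataclass
class AdjacencyReport:
    adjacent: pd.DataFrame
    control: pd.DataFrame
    p_pearson: float
    p_spearman: float
    median_adjacent_pearson: float
    median_control_pearson: float


def adjacent_similarity_test(
    clusters: list[NeuronCluster],
    proportions: pd.DataFrame,
    seed: int = 0,
) -> AdjacencyReport:
    """Do adjacent same-type clusters use more similar subclass mixtures?

    Adjacent pairs are each cluster with its nearest same-type cluster in the
    same stratum; the control is an equal number of seeded random same-
    stratum pairs that are not nearest pairs. Similarity is the Pearson (and
    Spearman) correlation of the proportion vectors; the report compares the
    two samples with a one-sided Wilcoxon rank-sum test (adjacent greater).
    """
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    rng = np.random.default_rng(seed)
    adj_pairs = _nearest_same_type(clusters)
    adj_set = set(adj_pairs)
    by_stratum: dict[tuple, list[str]] = {}
    for c in clusters:
        by_stratum.setdefault((c.section_id, c.layer), []).append(c.cluster_id)
    candidates = []
    for ids in by_stratum.values():
        ids = sorted(ids)
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if (ids[i], ids[j]) not in adj_set:
                    candidates.append((ids[i], ids[j]))
    candidates.sort()
    n_ctrl = min(len(adj_pairs), len(candidates))
    chosen = (
        [candidates[k] for k in rng.choice(len(candidates), n_ctrl, replace=False)]
        if candidates
        else []
    )

    def sims(pairs: list[tuple[str, str]]) -> pd.DataFrame:
        rows = []
        for a, b in pairs:
            va = proportions.loc[a].to_numpy()
            vb = proportions.loc[b].to_numpy()
            rows.append(
                {
                    "a": a,
                    "b": b,
                    "pearson": _pair_similarity(va, vb, "pearson"),
                    "spearman": _pair_similarity(va, vb, "spearman"),
                }
            )
        return pd.DataFrame(rows, columns=["a", "b", "pearson", "spearman"])

    adjacent = sims(adj_pairs)
    control = sims(chosen)

    def rank_p(col: str) -> float:
        x = adjacent[col].dropna()
        y = control[col].dropna()
        if len(x) == 0 or len(y) == 0:
            return float("nan")
        return float(mannwhitneyu(x, y, alternative="greater")[1])

    return AdjacencyReport(
        adjacent=adjacent,
        control=control,
        p_pearson=rank_p("pearson"),
        p_spearman=rank_p("spearman"),
        median_adjacent_pearson=float(adjacent["pearson"].median()),
        median_control_pearson=float(control["pearson"].median()) if len(control) else float("nan"),
    )


def hierarchical_groups(
    presence: pd.DataFrame,
    k: int,
    metric: str = "jaccard",
    method: str = "average",
) -> pd.Series:
    """Cut an agglomerative tree on binary presence vectors into ``k`` groups.

    Groups are labelled ``h1..hk`` ordered by decreasing size (ties by first
    cluster id), so labels are deterministic for a fixed input.
    """
    n = len(presence)
    if k < 1 or k > n:
        raise ValueError(f"k must be in 1..{n}")
    if n == 1 or k == 1:
        return pd.Series(["h1"] * n, index=presence.index, name="group")
    mat = presence.to_numpy(dtype=bool)
    dist = pdist(mat, metric=metric)
    dist = np.nan_to_num(dist, nan=0.0)  # all-zero pairs: identical
    z = linkage(dist, method=method)
    raw = fcluster(z, t=k, criterion="maxclust")
    sizes: dict[int, int] = {}
    first: dict[int, int] = {}
    for i, g in enumerate(raw):
        sizes[g] = sizes.get(g, 0) + 1
        first.setdefault(int(g), i)
    order = sorted(sizes, key=lambda g: (-sizes[g], first[int(g)]))
    rename = {g: f"h{i + 1}" for i, g in enumerate(order)}
    return pd.Series([rename[g] for g in raw], index=presence.index, name="group")


def functional_enrichment(
    groups: pd.Series,
    summary: pd.DataFrame,
    annotation: RegionAnnotation,
    systems: tuple[str, ...] = SYSTEMS,
) -> pd.DataFrame:
    """One-sided Fisher enrichment of each group in each functional system.

    For every (group, system): a 2x2 table of group membership against
    whether a cluster's assigned region belongs to the system, tested with
    ``fisher_exact(alternative="greater")`` and BH-adjusted across all
    (group, system) pairs in this call. ``enriched`` flags adjusted p < 0.05.
    """
    regions = summary.reindex(groups.index)["assigned_region"]
    in_system = {
        s: regions.map(lambda r: s in annotation.systems_of(r)).to_numpy(dtype=bool)
        for s in systems
    }
    rows = []
    for g in sorted(groups.unique()):
        member = (groups == g).to_numpy(dtype=bool)
        for s in systems:
            ins = in_system[s]
            a = int((member & ins).sum())
            b = int((member & ~ins).sum())
            c = int((~member & ins).sum())
            d = int((~member & ~ins).sum())
            orat, p = fisher_exact([[a, b], [c, d]], alternative="greater")
            corrected = min(a, b, c, d) == 0
            if corrected:
                orat = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
            rows.append(
                {
                    "group": g,
                    "system": s,
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": float(orat),
                    "p": float(p),
                    "haldane_corrected": corrected,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["group", "system", "a", "b", "c", "d", "odds_ratio", "p", "haldane_corrected"],
    )
    if len(df):
        df["p_adj"] = multipletests(df["p"], method="fdr_bh")[1]
        df["enriched"] = df["p_adj"] < 0.05
    else:
        df["p_adj"] = []
        df["enriched"] = []
    return df


def hierarchy_correlation(
    summary: pd.DataFrame, annotation: RegionAnnotation
) -> pd.DataFrame:
    """Pearson r of cortical hierarchy level vs log10(size) and vs E-I ratio.

    Clusters whose assigned region carries no hierarchy level are excluded;
    per cluster type, degenerate inputs (constant, or fewer than 3 clusters)
    yield NaN with the count reported.
    """
    levels = summary["assigned_region"].map(annotation.level_of)
    rows = []
    for cls in ("excitatory", "inhibitory"):
        sub = summary[(summary["type"] == cls) & levels.notna()]
        lev = levels[sub.index].to_numpy(dtype=float)
        for metric, vals in (
            ("log10_size", np.log10(sub["size"].to_numpy(dtype=float))),
            ("ei_ratio", sub["ei_ratio"].to_numpy(dtype=float)),
        ):
            ok = np.isfinite(vals) & np.isfinite(lev)
            x, y = lev[ok], vals[ok]
            if len(x) >= 3 and np.std(x) > 0 and np.std(y) > 0:
                r, p = pearsonr(x, y)
            else:
                r, p = float("nan"), float("nan")
            rows.append(
                {"type": cls, "metric": metric, "r": float(r), "p": float(p), "n": int(len(x))}
            )
    return pd.DataFrame(rows, columns=["type", "metric", "r", "p", "n"])


def group_system_summary(
    groups: pd.Series,
    summary: pd.DataFrame,
    presence: pd.DataFrame,
    enrichment: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-group size/E-I summaries and the presence-frequency heatmap source.

    Returns ``(group_table, presence_freq)``: the first one row per group
    with member count, mean/median log10 size and mean E-I ratio over members
    with a defined ratio (NaN and flagged when none have one); the second the
    per-group frequency of presence of each subclass, the heatmap source.
    """
    sub = summary.reindex(groups.index)
    rows = []
    for g in sorted(groups.unique()):
        members = groups[groups == g].index
        msub = sub.loc[members]
        logsize = np.log10(msub["size"].to_numpy(dtype=float))
        ratios = msub["ei_ratio"].to_numpy(dtype=float)
        defined = ratios[np.isfinite(ratios)]
        rows.append(
            {
                "group": g,
                "n_clusters": len(members),
                "mean_log10_size": float(logsize.mean()),
                "median_log10_size": float(np.median(logsize)),
                "mean_ei_ratio": float(defined.mean()) if defined.size else float("nan"),
                "n_ei_defined": int(defined.size),
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "group", "n_clusters", "mean_log10_size", "median_log10_size",
            "mean_ei_ratio", "n_ei_defined",
        ],
    )
    if enrichment is not None and len(enrichment):
        best = (
            enrichment.sort_values("p_adj")
            .groupby("group", as_index=False)
            .first()[["group", "system", "odds_ratio", "p_adj", "enriched"]]
            .rename(columns={"system": "top_system", "odds_ratio": "top_system_or",
                             "p_adj": "top_system_p_adj", "enriched": "top_system_enriched"})
        )
        table = table.merge(best, on="group", how="left")
    freq = presence.groupby(groups).mean()
    freq.index.name = "group"
    return table, freq
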