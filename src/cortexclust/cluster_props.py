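"""Per-cluster metrics and cluster-pair relations.

Covers the descriptive layer on top of detection: the E-I ratio (excitatory
over inhibitory member count; undefined for pure-excitatory clusters, which
are analyzed separately rather than as infinities), KD-tree mean
nearest-neighbor distances, interregional status, in-cluster coverage with
SEM across sections, layer-wise class proportions, the chi-square test for
excess cells in inhibitory clusters, excitatory-inhibitory partnerships
(clusters of opposite type sharing cells) with Jaccard overlap, nearest
opposite-type clusters, coupling correlations and per-layer interregional
odds ratios with Woolf confidence intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import chisquare, pearsonr

from .io_model import CellTable, RegionAnnotation
from .window_scan import NeuronCluster

__all__ = [
    "ei_ratio",
    "mean_nn_distance",
    "interregional_flag",
    "assigned_region",
    "summarize_clusters",
    "CoverageStats",
    "coverage_stats",
    "layer_class_proportions",
    "class_balance_test",
    "find_partners",
    "jaccard",
    "nearest_opposite_cluster",
    "adjacent_opposite_pairs",
    "CorrelationResult",
    "coupling_stats",
    "interregional_enrichment",
]


def ei_ratio(cluster: NeuronCluster) -> float:
    """n_exc / n_inh; NaN (undefined) when the cluster has no inhibitory cells."""
    if cluster.n_inh == 0:
        return float("nan")
    return cluster.n_exc / cluster.n_inh


def mean_nn_distance(xy: np.ndarray, all_pairs: bool = False) -> float:
    """Mean distance from each cell to its nearest other member, µm.

    Uses a KD-tree (k=2 query, the nearest neighbor excluding self).
    ``all_pairs=True`` switches to the mean over all unordered member pairs
    instead. NaN for fewer than two members.
    """
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return float("nan")
    if all_pairs:
        from scipy.spatial.distance import pdist

        return float(pdist(xy).mean())
    dist, _ = cKDTree(xy).query(xy, k=2)
    return float(dist[:, 1].mean())


def interregional_flag(cluster: NeuronCluster) -> bool:
    """True iff member cells span two or more brain regions."""
    return len(cluster.regions) >= 2


def assigned_region(cluster: NeuronCluster) -> str:
    """Plurality region of the member cells; ties break lexicographically."""
    best = max(sorted(cluster.regions), key=lambda r: cluster.regions[r])
    return best


def _purity(cluster: NeuronCluster) -> str:
    if cluster.n_inh == 0 and cluster.n_exc > 0:
        return "excitatory"
    if cluster.n_exc == 0 and cluster.n_inh > 0:
        return "inhibitory"
    return ""


def summarize_clusters(
    clusters: list[NeuronCluster],
    annotation: RegionAnnotation | None = None,
) -> pd.DataFrame:
    """One row per cluster with its derived metrics, indexed by cluster_id."""
    rows = []
    for c in clusters:
        region = assigned_region(c)
        info = annotation.lookup(region) if annotation is not None else None
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "type": c.type,
                "section_id": c.section_id,
                "layer": c.layer,
                "size": c.size,
                "n_exc": c.n_exc,
                "n_inh": c.n_inh,
                "ei_ratio": ei_ratio(c),
                "pure": _purity(c),
                "mean_nn_dist": mean_nn_distance(c.xy),
                "n_regions": len(c.regions),
                "interregional": interregional_flag(c),
                "assigned_region": region,
                "regions": "|".join(sorted(c.regions)),
                "systems": "|".join(sorted(info.systems)) if info else "",
                "hierarchy_level": info.level if info else None,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "type", "section_id", "layer", "size", "n_exc",
            "n_inh", "ei_ratio", "pure", "mean_nn_dist", "n_regions",
            "interregional", "assigned_region", "regions", "systems",
            "hierarchy_level",
        ],
    )
    return df.set_index("cluster_id", drop=False)


@dataclass
class CoverageStats:
    """Fraction of all neurons lying inside any detected cluster."""

    overall: float
    per_layer: dict[int, float]
    per_section: dict[str, float]
    sem_overall: float
    per_layer_sem: dict[int, float]


def _sem(values: np.ndarray) -> float:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        return float("nan")
    return float(values.std(ddof=1) / math.sqrt(values.size))


def coverage_stats(clusters: list[NeuronCluster], table: CellTable) -> CoverageStats:
    """In-cluster coverage overall, per layer and per section.

    The numerator is the union of member cells over both cluster types; SEMs
    are taken over per-section fractions, mirroring per-chip error bars.
    """
    df = table.df
    covered = np.zeros(len(df), dtype=bool)
    for c in clusters:
        covered[c.cell_idx] = True
    overall = float(covered.mean()) if len(df) else float("nan")
    per_layer = {
        int(lay): float(covered[sub.index].mean())
        for lay, sub in df.groupby("layer", sort=True)
    }
    per_section = {
        str(sec): float(covered[sub.index].mean())
        for sec, sub in df.groupby("section_id", sort=True)
    }
    sec_layer = {}
    for (sec, lay), sub in df.groupby(["section_id", "layer"], sort=True):
        sec_layer.setdefault(int(lay), []).append(float(covered[sub.index].mean()))
    per_layer_sem = {lay: _sem(np.array(v)) for lay, v in sec_layer.items()}
    sem_overall = _sem(np.array(list(per_section.values())))
    return CoverageStats(overall, per_layer, per_section, sem_overall, per_layer_sem)


def layer_class_proportions(table: CellTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per (region, layer) class proportions and per-layer E-vs-I correlation.

    Returns ``(proportions, correlations)``: the first has counts and
    proportions per (region, layer) with at least one neuron; the second the
    Pearson r (and p) of per-region excitatory vs inhibitory counts within
    each layer (NaN with fewer than 3 regions or zero variance).
    """
    df = table.df
    counts = (
        df.groupby(["region", "layer", "class"], sort=True)
        .size()
        .unstack("class", fill_value=0)
        .reindex(columns=["excitatory", "inhibitory"], fill_value=0)
        .reset_index()
        .rename(columns={"excitatory": "n_exc", "inhibitory": "n_inh"})
    )
    total = counts["n_exc"] + counts["n_inh"]
    counts["prop_exc"] = counts["n_exc"] / total
    counts["prop_inh"] = counts["n_inh"] / total
    corr_rows = []
    for lay, sub in counts.groupby("layer", sort=True):
        r = p = float("nan")
        if len(sub) >= 3 and sub["n_exc"].std() > 0 and sub["n_inh"].std() > 0:
            r, p = pearsonr(sub["n_exc"], sub["n_inh"])
        corr_rows.append({"layer": int(lay), "r": r, "p": p, "n_regions": len(sub)})
    return counts, pd.DataFrame(corr_rows)


def class_balance_test(
    n_in_exc_clusters: int, n_in_inh_clusters: int, inhibitory_fraction: float
) -> tuple[float, float]:
    """Chi-square goodness of fit for cells in I-clusters vs the class balance.

    Observed counts are the cells inside excitatory vs inhibitory clusters;
    the expectation splits their total by the overall class fractions
    ``(1 - p_I, p_I)``. One degree of freedom.
    """
    total = n_in_exc_clusters + n_in_inh_clusters
    expected = np.array(
        [total * (1 - inhibitory_fraction), total * inhibitory_fraction], dtype=float
    )
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    stat, p = chisquare([n_in_exc_clusters, n_in_inh_clusters], expected)
    return float(stat), float(p)


def jaccard(size_a: int, size_b: int, shared: int) -> float:
    """|A ∩ B| / |A ∪ B| from set sizes and intersection size."""
    if shared < 0 or shared > min(size_a, size_b):
        raise ValueError("shared must be between 0 and min(|A|, |B|)")
    union = size_a + size_b - shared
    return shared / union if union else float("nan")


def find_partners(
    clusters: list[NeuronCluster],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Excitatory-inhibitory cluster pairs sharing at least one cell.

    Returns ``(pairs, partner_counts)``. ``pairs`` has one row per
    partnership with shared-cell count, Jaccard and per-cluster overlap
    fractions; ``partner_counts`` one row per cluster with its number of
    partners (0 for unpartnered clusters).
    """
    exc = [c for c in clusters if c.type == "excitatory"]
    inh = [c for c in clusters if c.type == "inhibitory"]
    cell_to_exc: dict[str, str] = {}
    sizes: dict[str, int] = {}
    for c in exc:
        sizes[c.cluster_id] = c.size
        for cid in c.cell_ids.tolist():
            cell_to_exc[cid] = c.cluster_id
    shared: dict[tuple[str, str], int] = {}
    for c in inh:
        sizes[c.cluster_id] = c.size
        for cid in c.cell_ids.tolist():
            e = cell_to_exc.get(cid)
            if e is not None:
                key = (e, c.cluster_id)
                shared[key] = shared.get(key, 0) + 1
    rows = []
    for (e, i), s in sorted(shared.items()):
        rows.append(
            {
                "exc_cluster_id": e,
                "inh_cluster_id": i,
                "shared": s,
                "jaccard": jaccard(sizes[e], sizes[i], s),
                "frac_exc": s / sizes[e],
                "frac_inh": s / sizes[i],
            }
        )
    pairs = pd.DataFrame(
        rows,
        columns=[
            "exc_cluster_id", "inh_cluster_id", "shared", "jaccard",
            "frac_exc", "frac_inh",
        ],
    )
    counts = {c.cluster_id: 0 for c in clusters}
    for (e, i), _ in shared.items():
        counts[e] += 1
        counts[i] += 1
    partner_counts = pd.DataFrame(
        {
            "cluster_id": list(counts),
            "n_partners": list(counts.values()),
        }
    ).sort_values("cluster_id", ignore_index=True)
    return pairs, partner_counts


def nearest_opposite_cluster(
    cluster: NeuronCluster, candidates: list[NeuronCluster]
) -> tuple[str, float]:
    """Closest opposite-type cluster by minimum inter-cell distance.

    Distance 0 when the clusters share cells; ties break toward the smaller
    cluster id. Candidates of the same type or from another stratum are
    ignored; raises if none remain.
    """
    best_id, best_d = None, float("inf")
    for other in sorted(candidates, key=lambda c: c.cluster_id):
        if (
            other.type == cluster.type
            or other.section_id != cluster.section_id
            or other.layer != cluster.layer
        ):
            continue
        d, _ = cKDTree(other.xy).query(cluster.xy, k=1)
        dmin = float(np.min(d))
        if dmin < best_d:
            best_id, best_d = other.cluster_id, dmin
    if best_id is None:
        raise ValueError("no opposite-type cluster in the same stratum")
    return best_id, best_d


def adjacent_opposite_pairs(
    clusters: list[NeuronCluster], exclude_partners: bool = True
) -> pd.DataFrame:
    """Nearest opposite-type cluster per cluster, optionally non-overlapping only.

    One row per (excitatory, inhibitory) unordered pair retained; used for
    the adjacent (as opposed to overlapping) coupling analysis.
    """
    pairs, _ = find_partners(clusters)
    partnered = set(
        zip(pairs["exc_cluster_id"], pairs["inh_cluster_id"])
    )
    seen = {}
    for c in clusters:
        try:
            other_id, d = nearest_opposite_cluster(c, clusters)
        except ValueError:
            continue
        e, i = (c.cluster_id, other_id) if c.type == "excitatory" else (other_id, c.cluster_id)
        if exclude_partners and (e, i) in partnered:
            continue
        key = (e, i)
        if key not in seen or d < seen[key]:
            seen[key] = d
    return pd.DataFrame(
        [{"exc_cluster_id": e, "inh_cluster_id": i, "distance": d} for (e, i), d in sorted(seen.items())],
        columns=["exc_cluster_id", "inh_cluster_id", "distance"],
    )


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int

    @property
    def defined(self) -> bool:
        return self.n >= 3 and np.isfinite(self.r)


def _pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return CorrelationResult(float("nan"), float("nan"), int(len(x)))
    r, p = pearsonr(x, y)
    return CorrelationResult(float(r), float(p), int(len(x)))


def coupling_stats(
    summary: pd.DataFrame,
    pairs: pd.DataFrame,
    partner_counts: pd.DataFrame,
    adjacent: pd.DataFrame | None = None,
) -> dict[str, CorrelationResult]:
    """Coupling correlations between partnered/adjacent clusters and sizes.

    Keys of the returned mapping:

    - ``partner_ei_coupling``: Pearson r of E-I ratios across partner pairs
      (pairs with an undefined ratio on either side are excluded).
    - ``adjacent_ei_coupling``: same across nearest non-overlapping pairs.
    - ``size_partners_<type>``: log10(size) vs number of partners.
    - ``ei_partners_<type>``: E-I ratio vs number of partners.
    - ``size_propensity_<type>``: log10(size) vs having at least one partner.
    """
    ratio = summary["ei_ratio"]
    out: dict[str, CorrelationResult] = {}

    def pair_coupling(df: pd.DataFrame) -> CorrelationResult:
        if len(df) == 0:
            return CorrelationResult(float("nan"), float("nan"), 0)
        re = ratio.reindex(df["exc_cluster_id"]).to_numpy()
        ri = ratio.reindex(df["inh_cluster_id"]).to_numpy()
        return _pearson(re, ri)

    out["partner_ei_coupling"] = pair_coupling(pairs)
    if adjacent is not None:
        out["adjacent_ei_coupling"] = pair_coupling(adjacent)

    merged = summary.reset_index(drop=True).merge(partner_counts, on="cluster_id", how="left")
    merged["n_partners"] = merged["n_partners"].fillna(0)
    for cls in ("excitatory", "inhibitory"):
        sub = merged[merged["type"] == cls]
        logsize = np.log10(sub["size"].to_numpy(dtype=float))
        np_partners = sub["n_partners"].to_numpy(dtype=float)
        out[f"size_partners_{cls}"] = _pearson(logsize, np_partners)
        out[f"ei_partners_{cls}"] = _pearson(sub["ei_ratio"].to_numpy(), np_partners)
        out[f"size_propensity_{cls}"] = _pearson(logsize, (np_partners > 0).astype(float))
    return out


def interregional_enrichment(summary: pd.DataFrame) -> pd.DataFrame:
    """Per-layer, per-type odds ratio of being interregional vs other layers.

    The 2x2 table contrasts interregional status in one layer against all
    remaining layers; the CI is Woolf's normal interval on the log odds
    ratio, with the Haldane-Anscombe 0.5 correction (flagged) when any cell
    is zero.
    """
    rows = []
    for cls in ("excitatory", "inhibitory"):
        sub = summary[summary["type"] == cls]
        if len(sub) == 0:
            continue
        for lay in sorted(sub["layer"].unique()):
            in_layer = sub["layer"] == lay
            inter = sub["interregional"].astype(bool)
            a = int((in_layer & inter).sum())
            b = int((in_layer & ~inter).sum())
            c = int((~in_layer & inter).sum())
            d = int((~in_layer & ~inter).sum())
            corrected = min(a, b, c, d) == 0
            aa, bb, cc, dd = (
                (a + 0.5, b + 0.5, c + 0.5, d + 0.5) if corrected else (a, b, c, d)
            )
            orat = (aa * dd) / (bb * cc)
            se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
            rows.append(
                {
                    "type": cls,
                    "layer": int(lay),
                    "a": a,
                    "b": b,
                    "c": c,
                    "d": d,
                    "odds_ratio": orat,
                    "ci_low": math.exp(math.log(orat) - 1.96 * se),
                    "ci_high": math.exp(math.log(orat) + 1.96 * se),
                    "haldane_corrected": corrected,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "type", "layer", "a", "b", "c", "d", "odds_ratio", "ci_low",
            "ci_high", "haldane_corrected",
        ],
    )
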