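"""Subclass enrichment within clusters and co-occurrence testing.

Cluster memberships are held fixed while subclass labels are shuffled among
all neurons of the stratum (both classes pooled); each (cluster, subclass)
pair gets a one-sided enrichment p-value with the add-one estimator. Two
subclasses co-occur in a cluster when both are individually enriched at
``alpha``; clusters enriched for two or more subclasses are classified by
the classes of their enriched subclasses (EE, EI, II). A meta-permutation
reshuffles the subclass labels globally and reruns the whole enrichment to
ask whether the observed multi-enriched fraction exceeds chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import CellTable
from .window_scan import NeuronCluster

__all__ = [
    "subclass_enrichment",
    "CooccurrenceReport",
    "classify_combinations",
    "MetaPermutationResult",
    "meta_permutation",
]


def _stratum_key(c: NeuronCluster, stratify: str) -> tuple:
    return (c.section_id, c.layer) if stratify == "section_layer" else (c.layer,)


def _stratum_cells(table: CellTable, key: tuple, stratify: str) -> pd.DataFrame:
    df = table.df
    if stratify == "section_layer":
        sec, lay = key
        return df[(df["section_id"] == sec) & (df["layer"] == lay)]
    (lay,) = key
    return df[df["layer"] == lay]


def subclass_enrichment(
    clusters: list[NeuronCluster],
    table: CellTable,
    n_perm: int = 10000,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    stratify: str = "section_layer",
    batch_size: int = 256,
    subclass_codes: np.ndarray | None = None,
) -> pd.DataFrame:
    """One-sided subclass enrichment p per (cluster, subclass).

    ``p = (1 + #{perm count >= observed}) / (1 + n_perm)`` with subclass
    labels permuted among all cells of the cluster's stratum. A subclass
    absent from the stratum (observed count 0) gets p = 1. Returns a long
    frame: cluster_id, cluster_type, subclass, subclass_class, observed, p,
    enriched.

    ``subclass_codes`` optionally overrides the table's subclass column with
    integer codes into ``table.full_vocab()`` (used by the meta-permutation
    to rerun the analysis on shuffled labels without rebuilding tables).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vocab = table.full_vocab()
    sub_to_code = {s: i for i, s in enumerate(vocab)}
    sub_class = table.subclass_class()
    K = len(vocab)
    if subclass_codes is None:
        codes_all = table.df["subclass"].map(sub_to_code).to_numpy(dtype=np.int64)
    else:
        codes_all = np.asarray(subclass_codes, dtype=np.int64)

    by_stratum: dict[tuple, list[NeuronCluster]] = {}
    for c in clusters:
        by_stratum.setdefault(_stratum_key(c, stratify), []).append(c)

    rows = []
    for key in sorted(by_stratum, key=str):
        cl_list = sorted(by_stratum[key], key=lambda c: c.cluster_id)
        cells = _stratum_cells(table, key, stratify)
        pool_pos = cells.index.to_numpy()
        codes = codes_all[pool_pos]
        n = codes.size
        pos = pd.Index(cells.index)
        mems = [pos.get_indexer(c.cell_idx) for c in cl_list]
        obs = np.stack([np.bincount(codes[m], minlength=K) for m in mems])
        C = len(cl_list)
        mem_concat = np.concatenate(mems)
        offs = np.repeat(np.arange(C), [m.size for m in mems])
        exceed = np.zeros((C, K), dtype=np.int64)
        done = 0
        while done < n_perm:
            b = min(batch_size, n_perm - done)
            perm = rng.permuted(np.tile(codes, (b, 1)), axis=1)
            # one bincount per batch over (perm, cluster, subclass) cells
            flat = (
                np.arange(b, dtype=np.int64)[:, None] * (C * K)
                + offs[None, :] * K
                + perm[:, mem_concat]
            )
            counts = np.bincount(flat.ravel(), minlength=b * C * K).reshape(b, C, K)
            exceed += (counts >= obs[None, :, :]).sum(axis=0)
            done += b
        for c, o, e in zip(cl_list, obs, exceed):
            p = (1.0 + e) / (1.0 + n_perm)
            for s_i, s in enumerate(vocab):
                rows.append(
                    {
                        "cluster_id": c.cluster_id,
                        "cluster_type": c.type,
                        "subclass": s,
                        "subclass_class": sub_class[s],
                        "observed": int(o[s_i]),
                        "p": float(p[s_i]),
                        "enriched": bool(p[s_i] < alpha),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "cluster_type", "subclass", "subclass_class",
            "observed", "p", "enriched",
        ],
    )


@dataclass
class CooccurrenceReport:
    """Enriched-subclass sets per cluster and combination composition.

    ``combination`` per cluster is ``none`` (no enriched subclass),
    ``single`` (one), or for multi-enriched clusters ``EE``/``EI``/``II``
    by the classes of the enriched subclasses. Fractions and percentages are
    reported per cluster type.
    """

    per_cluster: pd.DataFrame
    multi_fraction: dict[str, float]
    combination_percentages: dict[str, dict[str, float]]

    def enriched_sets(self) -> dict[str, set[str]]:
        return {
            r.cluster_id: set(r.enriched_subclasses.split("|")) if r.enriched_subclasses else set()
            for r in self.per_cluster.itertuples()
        }


def classify_combinations(
    enrichment: pd.DataFrame, alpha: float | None = None
) -> CooccurrenceReport:
    """Classify clusters by the classes of their enriched subclasses."""
    df = enrichment
    if alpha is not None:
        df = df.assign(enriched=df["p"] < alpha)
    rows = []
    for (cid, ctype), sub in df.groupby(["cluster_id", "cluster_type"], sort=True):
        enr = sub[sub["enriched"]]
        subs = sorted(enr["subclass"])
        classes = set(enr["subclass_class"])
        if len(subs) == 0:
            combo = "none"
        elif len(subs) == 1:
            combo = "single"
        elif classes == {"excitatory"}:
            combo = "EE"
        elif classes == {"inhibitory"}:
            combo = "II"
        else:
            combo = "EI"
        rows.append(
            {
                "cluster_id": cid,
                "cluster_type": ctype,
                "n_enriched": len(subs),
                "enriched_subclasses": "|".join(subs),
                "combination": combo,
            }
        )
    per_cluster = pd.DataFrame(
        rows,
        columns=[
            "cluster_id", "cluster_type", "n_enriched", "enriched_subclasses",
            "combination",
        ],
    )
    multi_fraction: dict[str, float] = {}
    combo_pct: dict[str, dict[str, float]] = {}
    for ctype, sub in per_cluster.groupby("cluster_type"):
        multi = sub[sub["n_enriched"] >= 2]
        multi_fraction[ctype] = len(multi) / len(sub) if len(sub) else float("nan")
        if len(multi):
            combo_pct[ctype] = (
                multi["combination"].value_counts(normalize=True) * 100.0
            ).to_dict()
        else:
            combo_pct[ctype] = {}
    return CooccurrenceReport(per_cluster, multi_fraction, combo_pct)


def _multi_fractions(
    clusters: list[NeuronCluster],
    table: CellTable,
    n_perm: int,
    rng: np.random.Generator,
    alpha: float,
    stratify: str,
    codes: np.ndarray | None = None,
) -> dict[str, float]:
    enr = subclass_enrichment(
        clusters, table, n_perm, rng, alpha, stratify, subclass_codes=codes
    )
    return classify_combinations(enr).multi_fraction


@dataclass
class MetaPermutationResult:
    observed: dict[str, float]
    replicates: dict[str, np.ndarray]
    p: dict[str, float]
    n_rep: int


def meta_permutation(
    table: CellTable,
    clusters: list[NeuronCluster],
    n_rep: int = 500,
    inner_n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    stratify: str = "section_layer",
) -> MetaPermutationResult:
    """Empirical p for excess multi-subclass co-occurrence.

    Each replicate shuffles the subclass labels globally (within strata),
    reruns the subclass enrichment with ``inner_n_perm`` inner permutations
    and records the fraction of clusters enriched for two or more subclasses;
    ``p = (1 + #{replicate fraction >= observed}) / (1 + n_rep)``, per
    cluster type. The inner loop may be smaller than the headline analysis
    for tractability; calibration is unaffected because observed and
    replicate fractions use the same inner protocol.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    rng = np.random.default_rng(seed)
    observed = _multi_fractions(
        clusters, table, inner_n_perm, rng, alpha, stratify
    )
    vocab = table.full_vocab()
    sub_to_code = {s: i for i, s in enumerate(vocab)}
    codes = table.df["subclass"].map(sub_to_code).to_numpy(dtype=np.int64)
    strata = list(table.strata("section_layer" if stratify == "section_layer" else "layer"))
    reps: dict[str, list[float]] = {k: [] for k in observed}
    for _ in range(n_rep):
        shuffled = codes.copy()
        for _, sub in strata:
            posn = sub.index.to_numpy()
            shuffled[posn] = rng.permutation(shuffled[posn])
        frac = _multi_fractions(
            clusters, table, inner_n_perm, rng, alpha, stratify, codes=shuffled
        )
        for k in reps:
            reps[k].append(frac.get(k, float("nan")))
    replicates = {k: np.asarray(v, dtype=float) for k, v in reps.items()}
    p = {
        k: float((1 + np.sum(replicates[k] >= observed[k])) / (1 + n_rep))
        for k in observed
    }
    return MetaPermutationResult(observed, replicates, p, n_rep)
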