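"""Ground-truth validation experiments on synthetic scenes.

Each function runs one self-contained experiment against a known answer —
the hypergeometric limit of the permutation test, the type-I rate on a
complete-spatial-randomness scene, recovery of planted discs, the Poisson
nearest-neighbor closed form, co-occurrence calibration and power, and
recovery of planted qualitative contrasts — and returns plain numbers. The
test suite asserts on them and ``scripts/acceptance.py`` reports them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cluster_props import coupling_stats, mean_nn_distance
from .cooccurrence import meta_permutation
from .io_model import CellTable, preset
from .synthetic_data import (
    PlantedCluster,
    SceneConfig,
    expected_nn_distance,
    generate_background,
    generate_cooccurrence_scene,
    generate_coupled_pairs,
    generate_scene,
)
from .window_scan import (
    detect_clusters,
    enumerate_windows,
    exact_pvalue,
    membership_frame,
    permutation_pvalues,
)

__all__ = [
    "oracle_agreement",
    "csr_type1_rates",
    "planted_recovery",
    "poisson_nn_error",
    "cooccurrence_null_calibration",
    "cooccurrence_power",
    "detection_contrast",
    "coupling_recovery",
    "determinism_check",
]


def _child_seeds(seed: int, n: int) -> list[int]:
    return [int(s & 0x7FFFFFFF) for s in np.random.SeedSequence(seed).generate_state(n)]


def oracle_agreement(
    seed: int = 0,
    min_windows: int = 60,
    n_perm: int = 10_000,
    max_cells: int = 200,
) -> tuple[float, int]:
    """Fraction of windows whose permutation p agrees with the hypergeometric limit.

    Random strata of at most ``max_cells`` cells with random class balance are
    scanned; for every non-empty window the Monte-Carlo p (at ``n_perm``) is
    compared to :func:`exact_pvalue` with the three-sigma binomial tolerance
    (plus the add-one estimator offset). Returns ``(agreement_fraction, n)``.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    total = 0
    while total < min_windows:
        n = int(rng.integers(20, max_cells + 1))
        k = int(rng.integers(1, n))
        cls = np.array(["inhibitory"] * k + ["excitatory"] * (n - k), dtype=object)
        rng.shuffle(cls)
        df = pd.DataFrame(
            {
                "cell_id": [f"c{i:04d}" for i in range(n)],
                "x": rng.uniform(0, 1000, n),
                "y": rng.uniform(0, 1000, n),
                "section_id": "S1",
                "layer": 2,
                "region": "R1",
                "class": cls,
                "subclass": "L2",
            }
        )
        windows = enumerate_windows(df, 500, 250)
        stats = permutation_pvalues(
            df, windows, n_perm, seed=int(rng.integers(2**31))
        )
        for w in range(len(windows)):
            p_ex = exact_pvalue(n, k, int(stats.n_total[w]), int(stats.n_inh[w]))
            tol = 3 * np.sqrt(p_ex * (1 - p_ex) / n_perm) + 1 / (n_perm + 1)
            agree += abs(stats.p_inh[w] - p_ex) <= tol
            total += 1
    return agree / total, total


def csr_type1_rates(
    seed: int = 0,
    n_seeds: int = 5,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Per-class fraction of significant windows on CSR scenes.

    Scenes are homogeneous Poisson (about 20,000 cells at 500 cells/mm² over
    6.3 x 6.3 mm, 15% inhibitory) with no planted structure, scanned with the
    1000 µm / 100 µm window. Rates are averaged over ``n_seeds`` scenes.
    """
    rates_exc, rates_inh = [], []
    for s in _child_seeds(seed, n_seeds):
        cfg = SceneConfig(
            width=6300, height=6300, density=500, inhibitory_fraction=0.15
        )
        table = generate_background(cfg, s)
        windows = enumerate_windows(table.df, 1000, 100)
        stats = permutation_pvalues(table.df, windows, n_perm, seed=s + 1, alpha=alpha)
        rates_exc.append(float(stats.significant("excitatory").mean()))
        rates_inh.append(float(stats.significant("inhibitory").mean()))
    return {
        "excitatory": float(np.mean(rates_exc)),
        "inhibitory": float(np.mean(rates_inh)),
        "n_seeds": n_seeds,
    }


def planted_recovery(
    seed: int = 0, n_perm: int = 1000
) -> dict[str, float]:
    """Recovery of ten planted inhibitory-enriched discs.

    One 10 x 4 mm section at 1000 cells/mm² (15% inhibitory) with ten
    r = 500 µm discs of in-disc inhibitory fraction 0.5 on a 2 x 5 grid with
    2000 µm center spacing; detection uses the 400 µm / 100 µm window.
    Returns the number of discs intersecting a detected inhibitory cluster
    and the median cell-level Jaccard between each disc's members and its
    best-matching inhibitory cluster.
    """
    s_scene, s_scan = _child_seeds(seed, 2)
    cfg = SceneConfig(width=10_000, height=4000, density=1000, inhibitory_fraction=0.15)
    centers = [(1000.0 + 2000 * i, 1000.0) for i in range(5)] + [
        (1000.0 + 2000 * i, 3000.0) for i in range(5)
    ]
    discs = [PlantedCluster(c, 500, "inhibitory", 0.5) for c in centers]
    table, truth = generate_scene(cfg, discs, seed=s_scene)
    clusters = detect_clusters(table, preset("macaque-check", n_perm=n_perm, seed=s_scan))
    inh = [c for c in clusters if c.type == "inhibitory"]
    hits = 0
    jaccards = []
    for members in truth.members:
        truth_set = set(members.tolist())
        best = 0.0
        for c in inh:
            overlap = len(truth_set & c.member_set)
            if overlap:
                best = max(best, overlap / len(truth_set | c.member_set))
        hits += best > 0
        jaccards.append(best)
    return {
        "n_discs": len(discs),
        "hits": int(hits),
        "median_jaccard": float(np.median(jaccards)),
        "n_cells": len(table),
    }


def poisson_nn_error(seed: int = 0) -> dict[str, float]:
    """Relative error of the mean NN distance vs the 1/(2 sqrt(lambda)) closed form."""
    cfg = SceneConfig(width=3300, height=3300, density=1000, inhibitory_fraction=0.15)
    table = generate_background(cfg, seed)
    observed = mean_nn_distance(table.df[["x", "y"]].to_numpy())
    expected = expected_nn_distance(cfg.density)
    return {
        "observed_um": float(observed),
        "expected_um": float(expected),
        "rel_error": float(abs(observed - expected) / expected),
        "n_cells": len(table),
    }


def cooccurrence_null_calibration(
    seed: int = 0,
    n_seeds: int = 100,
    n_rep: int = 100,
    inner_n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rate of the co-occurrence meta-test on null scenes.

    Scenes have i.i.d. subclass labels (the null is exactly true) with 16
    frozen 50-cell clusters in an 800-cell stratum. The meta-p is valid by
    exchangeability; its discreteness (mass at 1) makes it conservative, so
    the rate should not exceed the nominal level beyond binomial noise.
    """
    seeds = _child_seeds(seed, 2 * n_seeds)
    ps = []
    for i in range(n_seeds):
        table, clusters = generate_cooccurrence_scene(seed=seeds[2 * i])
        meta = meta_permutation(
            table, clusters, n_rep=n_rep, inner_n_perm=inner_n_perm,
            seed=seeds[2 * i + 1],
        )
        ps.append(meta.p["excitatory"])
    ps_arr = np.asarray(ps)
    return {
        "rejection_rate": float((ps_arr < alpha).mean()),
        "min_p": float(ps_arr.min()),
        "n_seeds": n_seeds,
    }


def cooccurrence_power(
    seed: int = 0, n_rep: int = 100, inner_n_perm: int = 1000
) -> dict[str, float]:
    """Meta-permutation p on a scene with planted two-subclass clusters."""
    s_scene, s_meta = _child_seeds(seed, 2)
    table, clusters = generate_cooccurrence_scene(seed=s_scene, planted_pairs=True)
    meta = meta_permutation(
        table, clusters, n_rep=n_rep, inner_n_perm=inner_n_perm, seed=s_meta
    )
    return {
        "p": float(meta.p["excitatory"]),
        "observed_multi_fraction": float(meta.observed["excitatory"]),
        "n_rep": n_rep,
    }


def detection_contrast(seed: int = 0, n_perm: int = 500) -> dict[str, float]:
    """Recovery of a planted size/number asymmetry between cluster types.

    The scene plants three large excitatory-enriched discs (r = 700 µm,
    in-disc inhibitory fraction 0.02) and seven small inhibitory-enriched
    discs (r = 300 µm, fraction 0.5) in one 9 x 3.6 mm section. Detected
    clusters are matched to the planted inventory by shared cells; the
    pipeline should report more, and smaller, inhibitory clusters.
    """
    s_scene, s_scan = _child_seeds(seed, 2)
    cfg = SceneConfig(width=9000, height=3600, density=1000, inhibitory_fraction=0.15)
    e_discs = [
        PlantedCluster((x, 1200.0), 700, "excitatory", 0.98) for x in (1500.0, 4500.0, 7500.0)
    ]
    i_discs = [
        PlantedCluster((900.0 + 1200 * i, 2800.0), 300, "inhibitory", 0.5)
        for i in range(7)
    ]
    table, truth = generate_scene(cfg, e_discs + i_discs, seed=s_scene)
    clusters = detect_clusters(table, preset("macaque-check", n_perm=n_perm, seed=s_scan))
    matched: dict[str, list] = {"excitatory": [], "inhibitory": []}
    truth_sets = [set(m.tolist()) for m in truth.members]
    for c in clusters:
        discs = e_discs if c.type == "excitatory" else i_discs
        offset = 0 if c.type == "excitatory" else len(e_discs)
        for j in range(len(discs)):
            if truth_sets[offset + j] & c.member_set:
                matched[c.type].append(c)
                break
    exc_sizes = [c.size for c in matched["excitatory"]]
    inh_sizes = [c.size for c in matched["inhibitory"]]
    return {
        "n_exc_clusters": len(exc_sizes),
        "n_inh_clusters": len(inh_sizes),
        "median_exc_size": float(np.median(exc_sizes)) if exc_sizes else float("nan"),
        "median_inh_size": float(np.median(inh_sizes)) if inh_sizes else float("nan"),
    }


def coupling_recovery(seed: int = 0, n_pairs: int = 500, r: float = 0.5) -> dict[str, float]:
    """Partner E-I ratio coupling estimated on pairs with known correlation."""
    summary, pairs, counts = generate_coupled_pairs(n_pairs=n_pairs, r=r, seed=seed)
    out = coupling_stats(summary, pairs, counts)
    res = out["partner_ei_coupling"]
    return {"r_hat": float(res.r), "true_r": r, "n_pairs": res.n}


def determinism_check(seed: int = 0, n_perm: int = 200) -> bool:
    """True iff repeated detection under one seed yields byte-identical exports."""
    cfg = SceneConfig(width=2500, height=2500, density=800, inhibitory_fraction=0.15)
    disc = PlantedCluster((1250.0, 1250.0), 500, "inhibitory", 0.7)
    table, _ = generate_scene(cfg, [disc], seed=seed)
    blobs = []
    for _ in range(2):
        clusters = detect_clusters(table, preset("macaque-check", n_perm=n_perm, seed=seed + 1))
        blobs.append(
            membership_frame(clusters).to_csv(sep="\t", index=False, lineterminator="\n")
        )
    return blobs[0] == blobs[1]
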