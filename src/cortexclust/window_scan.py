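"""Sliding-window permutation enrichment and cluster merging.

The detection stage scans each (section, layer) stratum with a square window
of side ``W`` stepped on a grid of pitch ``step``, counts excitatory and
inhibitory neurons per window under the half-open membership rule
``[x0, x0+W) x [y0, y0+W)``, and tests each class for enrichment against a
label-permutation null: class labels are shuffled uniformly among the
stratum's fixed cell positions (equivalent to shuffling coordinates among
cells), which makes the in-window class count exactly hypergeometric.
:func:`exact_pvalue` exposes that closed form as an analytic oracle for the
Monte-Carlo estimate.

Windows significant for the same class are merged into neuron clusters via
shared-cell connectivity: overlapping significant windows that share at
least one cell fall into one connected component, and the cluster's members
are the union of its windows' cells (of both classes).
"""

from __future__ import annotations

import logging
import math
import zlib
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .io_model import CLASSES, AnalysisConfig, CellTable

__all__ = [
    "Window",
    "WindowStats",
    "NeuronCluster",
    "enumerate_windows",
    "exact_pvalue",
    "permutation_pvalues",
    "merge_significant_windows",
    "detect_clusters",
    "membership_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class Window:
    """One grid window; ``cell_idx`` are positional indices into the scene table."""

    x0: float
    y0: float
    size: float
    section_id: str | None
    layer: int
    cell_idx: np.ndarray

    @property
    def n_total(self) -> int:
        return int(self.cell_idx.size)


def _origin_range(vmin: float, vmax: float, window: float, step: float) -> range:
    # smallest integer i with i*step > vmin - window, through floor(vmax/step):
    # exactly the origins whose half-open window can contain a data point.
    start = math.floor((vmin - window) / step) + 1
    stop = math.floor(vmax / step)
    return range(start, stop + 1)


def enumerate_windows(
    cells: pd.DataFrame,
    window_size: float,
    step: float,
    min_cells: int = 1,
    section_id: str | None = None,
    layer: int | None = None,
) -> list[Window]:
    """Enumerate non-empty grid windows over one stratum.

    Origins are step-multiples, extended one window beyond the data hull on
    every side, so that each cell falls in exactly ``(W/step)**2`` windows
    when ``W`` is a multiple of ``step``. Windows holding fewer than
    ``min_cells`` cells are dropped.
    """
    if step > window_size:
        raise ValueError("step > window_size would leave unscanned gaps")
    if len(cells) == 0:
        return []
    x = cells["x"].to_numpy(dtype=float)
    y = cells["y"].to_numpy(dtype=float)
    idx = cells.index.to_numpy()
    if section_id is None:
        secs = cells["section_id"].unique()
        section_id = str(secs[0]) if len(secs) == 1 else None
    if layer is None:
        layer = int(cells["layer"].iloc[0])

    windows: list[Window] = []
    m = window_size / step
    aligned = abs(m - round(m)) < 1e-9
    if aligned:
        m = int(round(m))
        cx = np.floor(x / step).astype(np.int64)
        cy = np.floor(y / step).astype(np.int64)
        order = np.lexsort((cy, cx))
        cx_s, cy_s, idx_s = cx[order], cy[order], idx[order]
        # bin -> slice into the lexsorted arrays
        ny = int(cy.max() - cy.min() + 1)
        oy = int(cy.min())
        ox = int(cx.min())
        flat = (cx_s - ox) * ny + (cy_s - oy)
        uniq, starts = np.unique(flat, return_index=True)
        bounds = np.append(starts, flat.size)
        slices = {int(u): (int(bounds[i]), int(bounds[i + 1])) for i, u in enumerate(uniq)}
        nx = int(cx.max() - ox + 1)
        counts = np.zeros((nx, ny), dtype=np.int64)
        np.add.at(counts, (cx - ox, cy - oy), 1)
        # integral image for fast occupancy checks
        ii = np.zeros((nx + 1, ny + 1), dtype=np.int64)
        ii[1:, 1:] = counts.cumsum(0).cumsum(1)

        for ix in range(ox - m + 1, ox + nx):
            a0, a1 = max(ix - ox, 0), min(ix - ox + m, nx)
            if a1 <= a0:
                continue
            for iy in range(oy - m + 1, oy + ny):
                b0, b1 = max(iy - oy, 0), min(iy - oy + m, ny)
                if b1 <= b0:
                    continue
                n = ii[a1, b1] - ii[a0, b1] - ii[a1, b0] + ii[a0, b0]
                if n < min_cells:
                    continue
                parts = []
                for a in range(a0, a1):
                    for b in range(b0, b1):
                        sl = slices.get(a * ny + b)
                        if sl is not None:
                            parts.append(idx_s[sl[0] : sl[1]])
                member = np.sort(np.concatenate(parts))
                windows.append(
                    Window(ix * step, iy * step, window_size, section_id, layer, member)
                )
    else:
        xs_order = np.argsort(x, kind="stable")
        x_sorted = x[xs_order]
        for ix in _origin_range(x.min(), x.max(), window_size, step):
            x0 = ix * step
            lo = np.searchsorted(x_sorted, x0, side="left")
            hi = np.searchsorted(x_sorted, x0 + window_size, side="left")
            if hi <= lo:
                continue
            cand = xs_order[lo:hi]
            ysub = y[cand]
            for iy in _origin_range(y.min(), y.max(), window_size, step):
                y0 = iy * step
                mask = (ysub >= y0) & (ysub < y0 + window_size)
                if int(mask.sum()) < min_cells:
                    continue
                member = np.sort(idx[cand[mask]])
                windows.append(
                    Window(x0, y0, window_size, section_id, layer, member)
                )
    windows.sort(key=lambda w: (w.x0, w.y0))
    return windows


def exact_pvalue(N: int, K: int, n_w: int, k: int) -> float:
    """Upper-tail hypergeometric p: P[count >= k] for a window of ``n_w`` cells.

    Under label permutation among ``N`` stratum cells of which ``K`` carry
    the class, the in-window class count is Hypergeom(N, K, n_w); this is the
    analytic limit of the permutation p-value.
    """
    if not (0 <= K <= N and 0 <= n_w <= N and 0 <= k <= min(K, n_w)):
        raise ValueError(f"inconsistent arguments N={N}, K={K}, n_w={n_w}, k={k}")
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n_w))


@dataclass
class WindowStats:
    """Per-window counts, permutation p-values and significance flags."""

    windows: list[Window]
    n_total: np.ndarray
    n_exc: np.ndarray
    n_inh: np.ndarray
    p_exc: np.ndarray
    p_inh: np.ndarray
    alpha: float
    n_perm: int
    degenerate: dict[str, bool] = field(default_factory=dict)

    def p_values(self, cls: str) -> np.ndarray:
        return self.p_exc if cls == "excitatory" else self.p_inh

    def significant(self, cls: str) -> np.ndarray:
        return self.p_values(cls) < self.alpha

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x0": [w.x0 for w in self.windows],
                "y0": [w.y0 for w in self.windows],
                "section_id": [w.section_id for w in self.windows],
                "layer": [w.layer for w in self.windows],
                "n_total": self.n_total,
                "n_exc": self.n_exc,
                "n_inh": self.n_inh,
                "p_exc": self.p_exc,
                "p_inh": self.p_inh,
                "sig_exc": self.significant("excitatory"),
                "sig_inh": self.significant("inhibitory"),
            }
        )


def permutation_pvalues(
    cells: pd.DataFrame,
    windows: list[Window],
    n_perm: int,
    seed: int | np.random.Generator = 0,
    alpha: float = 0.05,
    batch_size: int = 128,
) -> WindowStats:
    """One-sided enrichment p-values under the label-permutation null.

    Class labels are permuted uniformly among the fixed cell positions of the
    stratum; for each window and class, ``p = (1 + #{perm count >= observed})
    / (1 + n_perm)`` (add-one estimator, so p is never 0). Because window
    totals are fixed under the permutation, excess of one class is deficit of
    the other: the excitatory p uses ``perm_inh <= observed_inh``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = (cells["class"].to_numpy() == "inhibitory").astype(np.uint8)
    n = labels.size
    pos = pd.Index(cells.index)
    mems = [pos.get_indexer(w.cell_idx) for w in windows]
    n_total = np.array([m.size for m in mems], dtype=np.int64)
    obs_inh = np.array([int(labels[m].sum()) for m in mems], dtype=np.int64)
    obs_exc = n_total - obs_inh

    ge = np.zeros(len(windows), dtype=np.int64)  # perm_inh >= obs_inh
    le = np.zeros(len(windows), dtype=np.int64)  # perm_inh <= obs_inh
    done = 0
    while done < n_perm:
        b = min(batch_size, n_perm - done)
        perm = rng.permuted(np.tile(labels, (b, 1)), axis=1)
        for w, mem in enumerate(mems):
            c = perm[:, mem].sum(axis=1)
            ge[w] += int((c >= obs_inh[w]).sum())
            le[w] += int((c <= obs_inh[w]).sum())
        done += b
    p_inh = (1.0 + ge) / (1.0 + n_perm)
    p_exc = (1.0 + le) / (1.0 + n_perm)
    degenerate = {
        "inhibitory": bool(labels.sum() == 0),
        "excitatory": bool(labels.sum() == n),
    }
    return WindowStats(
        windows=windows,
        n_total=n_total,
        n_exc=obs_exc,
        n_inh=obs_inh,
        p_exc=p_exc,
        p_inh=p_inh,
        alpha=alpha,
        n_perm=n_perm,
        degenerate=degenerate,
    )


@dataclass
class NeuronCluster:
    """Merged connected component of same-class significant windows.

    Members are the union of the constituent windows' cells, of both classes;
    ``type`` is the class every constituent window was enriched for.
    """

    cluster_id: str
    type: str
    section_id: str | None
    layer: int
    cell_idx: np.ndarray
    cell_ids: np.ndarray
    xy: np.ndarray
    n_exc: int
    n_inh: int
    regions: Counter
    window_origins: list[tuple[float, float]]

    @property
    def size(self) -> int:
        return int(self.cell_idx.size)

    @property
    def member_set(self) -> set[str]:
        return set(self.cell_ids.tolist())


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _components_shared_cells(sig_windows: list[Window]) -> list[list[int]]:
    uf = _UnionFind(len(sig_windows))
    first_seen: dict[int, int] = {}
    for wpos, w in enumerate(sig_windows):
        for c in w.cell_idx.tolist():
            prev = first_seen.setdefault(c, wpos)
            if prev != wpos:
                uf.union(prev, wpos)
    groups: dict[int, list[int]] = {}
    for wpos in range(len(sig_windows)):
        groups.setdefault(uf.find(wpos), []).append(wpos)
    return list(groups.values())


def _components_geometric(sig_windows: list[Window]) -> list[list[int]]:
    uf = _UnionFind(len(sig_windows))
    for i, a in enumerate(sig_windows):
        for j in range(i + 1, len(sig_windows)):
            b = sig_windows[j]
            if abs(a.x0 - b.x0) < a.size and abs(a.y0 - b.y0) < a.size:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for wpos in range(len(sig_windows)):
        groups.setdefault(uf.find(wpos), []).append(wpos)
    return list(groups.values())


def merge_significant_windows(
    stats: WindowStats,
    cells: pd.DataFrame,
    alpha: float | None = None,
    connectivity: str = "shared_cells",
) -> list[NeuronCluster]:
    """Merge same-class significant windows into clusters.

    For each class separately, significant windows sharing at least one cell
    (or geometrically overlapping, with ``connectivity="geometric"``) form a
    graph whose connected components are the clusters. Cluster ids embed the
    stratum, the class and the lexicographically smallest member cell id, so
    repeated runs produce identical identifiers.
    """
    a = stats.alpha if alpha is None else alpha
    clusters: list[NeuronCluster] = []
    for cls in CLASSES:
        short = "E" if cls == "excitatory" else "I"
        flags = stats.p_values(cls) < a
        sig = [w for w, f in zip(stats.windows, flags) if f]
        if not sig:
            continue
        comps = (
            _components_shared_cells(sig)
            if connectivity == "shared_cells"
            else _components_geometric(sig)
        )
        for comp in comps:
            member_idx = np.unique(np.concatenate([sig[i].cell_idx for i in comp]))
            sub = cells.loc[member_idx]
            ids = sub["cell_id"].to_numpy()
            n_inh = int((sub["class"] == "inhibitory").sum())
            w0 = sig[comp[0]]
            cid = f"{short}:{w0.section_id}:L{w0.layer}:{min(ids)}"
            clusters.append(
                NeuronCluster(
                    cluster_id=cid,
                    type=cls,
                    section_id=w0.section_id,
                    layer=w0.layer,
                    cell_idx=member_idx,
                    cell_ids=ids,
                    xy=sub[["x", "y"]].to_numpy(dtype=float),
                    n_exc=int(len(sub) - n_inh),
                    n_inh=n_inh,
                    regions=Counter(sub["region"].tolist()),
                    window_origins=sorted((sig[i].x0, sig[i].y0) for i in comp),
                )
            )
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def _stratum_seed(seed: int, section_id: str | None, layer: int) -> np.random.Generator:
    crc = zlib.crc32(f"{section_id}|{layer}".encode())
    return np.random.default_rng([seed, crc])


def detect_clusters(table: CellTable, config: AnalysisConfig) -> list[NeuronCluster]:
    """End-to-end detection: scan, permute and merge over every stratum.

    With ``stratify="section_layer"`` each (section, layer) is scanned and
    permuted on its own; with ``stratify="layer"`` windows are still
    enumerated per section (cross-section geometry is meaningless) but the
    label permutation pools all sections of the layer.
    """
    clusters: list[NeuronCluster] = []
    if len(table) == 0:
        return clusters
    if config.stratify == "section_layer":
        for (sec, lay), sub in table.strata("section_layer"):
            windows = enumerate_windows(
                sub, config.window_size, config.step, config.min_cells, sec, lay
            )
            if not windows:
                continue
            stats = permutation_pvalues(
                sub,
                windows,
                config.n_perm,
                _stratum_seed(config.seed, sec, lay),
                config.alpha,
            )
            cl = merge_significant_windows(
                stats, table.df, connectivity=config.connectivity
            )
            logger.info(
                "stratum (%s, L%d): %d cells, %d windows, %d clusters",
                sec, lay, len(sub), len(windows), len(cl),
            )
            clusters.extend(cl)
    else:
        for (_, lay), sub in table.strata("layer"):
            windows = []
            for sec, secsub in sub.groupby("section_id", sort=True):
                windows.extend(
                    enumerate_windows(
                        secsub,
                        config.window_size,
                        config.step,
                        config.min_cells,
                        str(sec),
                        lay,
                    )
                )
            if not windows:
                continue
            stats = permutation_pvalues(
                sub,
                windows,
                config.n_perm,
                _stratum_seed(config.seed, None, lay),
                config.alpha,
            )
            cl = merge_significant_windows(
                stats, table.df, connectivity=config.connectivity
            )
            logger.info(
                "layer L%d: %d cells, %d windows, %d clusters",
                lay, len(sub), len(windows), len(cl),
            )
            clusters.extend(cl)
    clusters.sort(key=lambda c: c.cluster_id)
    return clusters


def membership_frame(clusters: list[NeuronCluster]) -> pd.DataFrame:
    """Long-form (cluster_id, cell_id) membership table, deterministic order."""
    rows = [
        (c.cluster_id, cid)
        for c in sorted(clusters, key=lambda c: c.cluster_id)
        for cid in sorted(c.cell_ids.tolist())
    ]
    return pd.DataFrame(rows, columns=["cluster_id", "cell_id"])
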