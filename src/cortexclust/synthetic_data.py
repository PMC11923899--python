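"""Synthetic layer-stratified neuron scenes with known ground truth.

Scenes emulate the statistical skeleton of a cortical section: a homogeneous
Poisson background of neurons over a rectangular extent, i.i.d. class labels
(inhibitory with probability ``p_I``, about 0.15 in primate cortex), i.i.d.
subclass labels from per-class mixtures, horizontal layer bands and a region
tiling along x. Enriched neuron clusters are planted as discs in which class
labels are resampled to a target composition at fixed positions — the same
label-vs-position separation the permutation null relies on — with an
optional density multiplier that adds points.

Every generator is driven by a single :class:`numpy.random.Generator` seeded
explicitly; draws happen in a documented order (count, x, y, class,
subclass) so fixtures are stable across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import CLASSES, CellTable, DEFAULT_SUBCLASS_VOCAB

__all__ = [
    "SceneConfig",
    "PlantedCluster",
    "GroundTruth",
    "generate_background",
    "plant_clusters",
    "generate_scene",
    "generate_partner_scene",
    "expected_nn_distance",
]


def _default_mixture() -> dict[str, dict[str, float]]:
    return {
        c: {s: 1.0 / len(v) for s in v}
        for c, v in ((c, DEFAULT_SUBCLASS_VOCAB[c]) for c in CLASSES)
    }


@dataclass(frozen=True)
class SceneConfig:
    """Geometry and background statistics of one synthetic section.

    width, height
        Extent of the section frame, µm.
    density
        Background intensity λ in cells/mm². The default is a placeholder of
        the right order for 2-D cortical sections; no empirical per-layer
        figure is encoded.
    inhibitory_fraction
        Bernoulli probability that a background cell is inhibitory.
    layers
        Layer numbers assigned to equal horizontal bands, bottom to top.
    subclass_mixture
        ``{class: {subclass: probability}}``; defaults to uniform mixtures
        over the default vocabularies.
    regions
        ``((label, (x0, x1)), ...)`` intervals tiling ``[0, width]``.
    """

    width: float = 4000.0
    height: float = 4000.0
    density: float = 1000.0
    inhibitory_fraction: float = 0.15
    layers: tuple[int, ...] = (2,)
    subclass_mixture: Mapping[str, Mapping[str, float]] | None = None
    regions: tuple[tuple[str, tuple[float, float]], ...] | None = None
    section_id: str = "S1"

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("scene extent must have positive area")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if not (0 <= self.inhibitory_fraction <= 1):
            raise ValueError("inhibitory_fraction must be in [0, 1]")
        for c, mix in self.mixture().items():
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{c} subclass mixture sums to {total}, not 1")
        x1_prev = 0.0
        for label, (x0, x1) in self.region_tiling():
            if abs(x0 - x1_prev) > 1e-9 or x1 <= x0:
                raise ValueError("region intervals must partition [0, width]")
            x1_prev = x1
        if abs(x1_prev - self.width) > 1e-9:
            raise ValueError("region intervals must partition [0, width]")

    def mixture(self) -> dict[str, dict[str, float]]:
        if self.subclass_mixture is None:
            return _default_mixture()
        return {c: dict(self.subclass_mixture[c]) for c in CLASSES}

    def region_tiling(self) -> tuple[tuple[str, tuple[float, float]], ...]:
        if self.regions is None:
            return (("R1", (0.0, self.width)),)
        return tuple((str(r), (float(a), float(b))) for r, (a, b) in self.regions)

    @property
    def area_mm2(self) -> float:
        return self.width * self.height / 1e6

    def layer_of(self, y: np.ndarray) -> np.ndarray:
        band = self.height / len(self.layers)
        idx = np.clip((y / band).astype(int), 0, len(self.layers) - 1)
        return np.asarray(self.layers, dtype=int)[idx]

    def region_of(self, x: np.ndarray) -> np.ndarray:
        tiling = self.region_tiling()
        edges = np.array([b for _, (_, b) in tiling[:-1]])
        labels = np.array([r for r, _ in tiling], dtype=object)
        return labels[np.searchsorted(edges, x, side="right")]


@dataclass(frozen=True)
class PlantedCluster:
    """A disc of enriched class composition, the ground-truth cluster.

    ``enriched_fraction`` is the in-disc fraction of ``enriched_class``;
    ``density_multiplier > 1`` additionally thickens the disc with extra
    Poisson points.
    """

    center: tuple[float, float]
    radius: float
    enriched_class: str
    enriched_fraction: float
    density_multiplier: float = 1.0
    subclass_mixture: Mapping[str, Mapping[str, float]] | None = None

    def __post_init__(self) -> None:
        if self.enriched_class not in CLASSES:
            raise ValueError(f"enriched_class must be one of {CLASSES}")
        if not (0 < self.enriched_fraction <= 1):
            raise ValueError("enriched_fraction must be in (0, 1]")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.density_multiplier < 1:
            raise ValueError("density_multiplier must be >= 1")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return (x - cx) ** 2 + (y - cy) ** 2 <= self.radius**2


@dataclass
class GroundTruth:
    """Planted discs and, per disc, the cell ids inside it.

    Membership is stored per disc (not per cell) so that deliberately
    overlapping discs — partner scenes — remain unambiguous.
    """

    planted: list[PlantedCluster]
    members: list[np.ndarray]

    def membership_of(self, i: int) -> set[str]:
        return set(self.members[i].tolist())

    def to_json(self, path: str | Path) -> None:
        payload = [
            {
                "center": list(p.center),
                "radius": p.radius,
                "enriched_class": p.enriched_class,
                "enriched_fraction": p.enriched_fraction,
                "density_multiplier": p.density_multiplier,
                "members": m.tolist(),
            }
            for p, m in zip(self.planted, self.members)
        ]
        Path(path).write_text(json.dumps(payload, indent=1))


def _draw_subclasses(
    rng: np.random.Generator,
    cls: np.ndarray,
    mixture: Mapping[str, Mapping[str, float]],
) -> np.ndarray:
    """Subclass labels per cell, drawn class by class (excitatory first)."""
    sub = np.empty(len(cls), dtype=object)
    for c in CLASSES:
        mask = cls == c
        labels = list(mixture[c])
        probs = np.array([mixture[c][s] for s in labels], dtype=float)
        if mask.any():
            sub[mask] = rng.choice(labels, size=int(mask.sum()), p=probs)
    return sub


def generate_background(
    config: SceneConfig, seed: int | np.random.Generator = 0
) -> CellTable:
    """Homogeneous Poisson background over the scene extent.

    Cell count ~ Poisson(λ·area); positions uniform; class labels i.i.d.
    Bernoulli(``inhibitory_fraction``); subclasses i.i.d. from the per-class
    mixtures. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(rng.poisson(config.density * config.area_mm2))
    x = rng.uniform(0.0, config.width, n)
    y = rng.uniform(0.0, config.height, n)
    cls = np.where(
        rng.random(n) < config.inhibitory_fraction, "inhibitory", "excitatory"
    ).astype(object)
    sub = _draw_subclasses(rng, cls, config.mixture())
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "x": x,
            "y": y,
            "section_id": config.section_id,
            "layer": config.layer_of(y),
            "region": config.region_of(x),
            "class": cls,
            "subclass": sub,
        }
    )
    vocab = {c: tuple(config.mixture()[c]) for c in CLASSES}
    return CellTable(df, subclass_vocab=vocab)


def _check_discs(planted: Sequence[PlantedCluster], config: SceneConfig | None) -> None:
    for i, p in enumerate(planted):
        if config is not None:
            cx, cy = p.center
            if not (
                p.radius <= cx <= config.width - p.radius
                and p.radius <= cy <= config.height - p.radius
            ):
                raise ValueError(f"planted disc {i} extends outside the scene")
        for j in range(i):
            q = planted[j]
            if q.enriched_class != p.enriched_class:
                d = np.hypot(p.center[0] - q.center[0], p.center[1] - q.center[1])
                if d < p.radius + q.radius:
                    raise ValueError(
                        f"discs {j} and {i} of opposite enriched class overlap; "
                        "ground truth would be ambiguous"
                    )


def plant_clusters(
    table: CellTable,
    planted: Sequence[PlantedCluster],
    seed: int | np.random.Generator = 0,
    config: SceneConfig | None = None,
) -> tuple[CellTable, GroundTruth]:
    """Resample class labels inside each disc to its enriched composition.

    Positions of existing cells are never moved; enrichment is purely a label
    effect unless ``density_multiplier > 1``, in which case extra points are
    added inside the disc (this needs ``config`` for geometry bookkeeping).
    Cells outside every disc are untouched. Overlapping discs of opposite
    enriched class are rejected.
    """
    _check_discs(planted, config)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    df = table.df.copy()
    mixture = config.mixture() if config is not None else {
        c: {s: 1.0 / len(v) for s in v} for c, v in table.subclass_vocab.items() if v
    }
    members: list[np.ndarray] = []
    extra_frames: list[pd.DataFrame] = []
    x = df["x"].to_numpy()
    y = df["y"].to_numpy()
    all_ids = df["cell_id"].to_numpy()
    for i, p in enumerate(planted):
        inside = np.flatnonzero(p.contains(x, y))
        other = CLASSES[1] if p.enriched_class == CLASSES[0] else CLASSES[0]
        hit = rng.random(inside.size) < p.enriched_fraction
        new_cls = np.where(hit, p.enriched_class, other).astype(object)
        df.iloc[inside, df.columns.get_loc("class")] = new_cls
        mix = (
            {c: dict(p.subclass_mixture[c]) for c in CLASSES}
            if p.subclass_mixture is not None
            else mixture
        )
        df.iloc[inside, df.columns.get_loc("subclass")] = _draw_subclasses(
            rng, new_cls, mix
        )
        ids = all_ids[inside].tolist()
        if p.density_multiplier > 1:
            if config is None:
                raise ValueError("density_multiplier > 1 requires a SceneConfig")
            area_mm2 = np.pi * p.radius**2 / 1e6
            n_extra = int(
                rng.poisson((p.density_multiplier - 1) * config.density * area_mm2)
            )
            rad = p.radius * np.sqrt(rng.random(n_extra))
            theta = rng.uniform(0, 2 * np.pi, n_extra)
            ex = p.center[0] + rad * np.cos(theta)
            ey = p.center[1] + rad * np.sin(theta)
            ecls = np.where(
                rng.random(n_extra) < p.enriched_fraction, p.enriched_class, other
            ).astype(object)
            eids = [f"p{i}x{j:05d}" for j in range(n_extra)]
            extra_frames.append(
                pd.DataFrame(
                    {
                        "cell_id": eids,
                        "x": ex,
                        "y": ey,
                        "section_id": config.section_id,
                        "layer": config.layer_of(ey),
                        "region": config.region_of(ex),
                        "class": ecls,
                        "subclass": _draw_subclasses(rng, ecls, mix),
                    }
                )
            )
            ids = ids + eids
        members.append(np.array(sorted(ids), dtype=object))
    if extra_frames:
        df = pd.concat([df] + extra_frames, ignore_index=True)
    out = CellTable(df, subclass_vocab=table.subclass_vocab)
    return out, GroundTruth(list(planted), members)


def generate_scene(
    config: SceneConfig,
    planted: Sequence[PlantedCluster] = (),
    seed: int = 0,
) -> tuple[CellTable, GroundTruth]:
    """Background plus planted discs, from one seed (background drawn first)."""
    rng = np.random.default_rng(seed)
    table = generate_background(config, rng)
    return plant_clusters(table, planted, rng, config)


def generate_partner_scene(
    config: SceneConfig,
    radius: float,
    separation: float,
    seed: int = 0,
    exc_disc_inhibitory_fraction: float = 0.02,
    inh_disc_inhibitory_fraction: float = 0.6,
) -> tuple[CellTable, GroundTruth]:
    """Scene with an E-enriched disc and an I-enriched disc a known distance apart.

    Disc centers sit ``separation`` µm apart on the horizontal midline; with
    ``separation < 2*radius`` they overlap by a known cell set, the planted
    partnership. In the exclusive parts of each disc the inhibitory fraction
    is set to the disc's target; in the intersection it is the mean of the
    two targets. Ground truth records each disc's members, so the planted
    shared set is the intersection of the two member arrays.
    """
    rng = np.random.default_rng(seed)
    table = generate_background(config, rng)
    cx, cy = config.width / 2.0, config.height / 2.0
    ce = (cx - separation / 2.0, cy)
    ci = (cx + separation / 2.0, cy)
    disc_e = PlantedCluster(ce, radius, "excitatory", 1 - exc_disc_inhibitory_fraction)
    disc_i = PlantedCluster(ci, radius, "inhibitory", inh_disc_inhibitory_fraction)
    for p in (disc_e, disc_i):
        if not (
            p.radius <= p.center[0] <= config.width - p.radius
            and p.radius <= p.center[1] <= config.height - p.radius
        ):
            raise ValueError("partner discs extend outside the scene")

    df = table.df.copy()
    x, y = df["x"].to_numpy(), df["y"].to_numpy()
    in_e = disc_e.contains(x, y)
    in_i = disc_i.contains(x, y)
    p_inh = np.full(len(df), np.nan)
    p_inh[in_e & ~in_i] = exc_disc_inhibitory_fraction
    p_inh[in_i & ~in_e] = inh_disc_inhibitory_fraction
    p_inh[in_e & in_i] = 0.5 * (exc_disc_inhibitory_fraction + inh_disc_inhibitory_fraction)
    touched = np.flatnonzero(np.isfinite(p_inh))
    new_cls = np.where(
        rng.random(touched.size) < p_inh[touched], "inhibitory", "excitatory"
    ).astype(object)
    df.iloc[touched, df.columns.get_loc("class")] = new_cls
    df.iloc[touched, df.columns.get_loc("subclass")] = _draw_subclasses(
        rng, new_cls, config.mixture()
    )
    ids = df["cell_id"].to_numpy()
    members = [
        np.array(sorted(ids[in_e].tolist()), dtype=object),
        np.array(sorted(ids[in_i].tolist()), dtype=object),
    ]
    out = CellTable(df, subclass_vocab=table.subclass_vocab)
    return out, GroundTruth([disc_e, disc_i], members)


def generate_cooccurrence_scene(
    seed: int = 0,
    n_cells: int = 800,
    n_clusters: int = 16,
    cluster_size: int = 50,
    inhibitory_fraction: float = 0.15,
    planted_pairs: bool = False,
    extent: float = 4000.0,
):
    """One-stratum scene with fixed-membership clusters for co-occurrence tests.

    Returns ``(CellTable, clusters)`` where the clusters are consecutive
    blocks of ``cluster_size`` cells with frozen membership, so the subclass
    permutation null is exactly satisfiable: under the default the subclass
    labels are i.i.d. from the uniform mixtures (null true); with
    ``planted_pairs=True`` the excitatory cells of each cluster are resampled
    to an even mix of two designated excitatory subclasses, planting strong
    two-subclass co-occurrence.

    The clusters are returned as :class:`~cortexclust.window_scan.NeuronCluster`
    records (synthetic fixture clusters, not the output of detection).
    """
    from collections import Counter

    from .window_scan import NeuronCluster

    if n_clusters * cluster_size > n_cells:
        raise ValueError("clusters exceed the available cells")
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, extent, n_cells)
    y = rng.uniform(0, extent, n_cells)
    cls = np.where(
        rng.random(n_cells) < inhibitory_fraction, "inhibitory", "excitatory"
    ).astype(object)
    evoc = list(DEFAULT_SUBCLASS_VOCAB["excitatory"])
    ivoc = list(DEFAULT_SUBCLASS_VOCAB["inhibitory"])
    sub = np.empty(n_cells, dtype=object)
    exc_mask = cls == "excitatory"
    sub[exc_mask] = rng.choice(evoc, int(exc_mask.sum()))
    sub[~exc_mask] = rng.choice(ivoc, int((~exc_mask).sum()))
    if planted_pairs:
        for k in range(n_clusters):
            idx = np.arange(k * cluster_size, (k + 1) * cluster_size)
            pair = (evoc[2 * k % 4], evoc[2 * k % 4 + 1])
            in_cluster_exc = idx[exc_mask[idx]]
            sub[in_cluster_exc] = rng.choice(pair, in_cluster_exc.size)
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:05d}" for i in range(n_cells)],
            "x": x,
            "y": y,
            "section_id": "S1",
            "layer": 2,
            "region": "R1",
            "class": cls,
            "subclass": sub,
        }
    )
    clusters = []
    for k in range(n_clusters):
        idx = np.arange(k * cluster_size, (k + 1) * cluster_size)
        subdf = df.iloc[idx]
        clusters.append(
            NeuronCluster(
                cluster_id=f"E:S1:L2:k{k:02d}",
                type="excitatory",
                section_id="S1",
                layer=2,
                cell_idx=idx,
                cell_ids=subdf["cell_id"].to_numpy(),
                xy=subdf[["x", "y"]].to_numpy(dtype=float),
                n_exc=int((subdf["class"] == "excitatory").sum()),
                n_inh=int((subdf["class"] == "inhibitory").sum()),
                regions=Counter(subdf["region"].tolist()),
                window_origins=[],
            )
        )
    table = CellTable(
        df, subclass_vocab={"excitatory": tuple(evoc), "inhibitory": tuple(ivoc)}
    )
    return table, clusters


def generate_coupled_pairs(
    n_pairs: int = 500,
    r: float = 0.5,
    seed: int = 0,
    mean_ratio: tuple[float, float] = (3.0, 1.5),
    sd_ratio: tuple[float, float] = (0.5, 0.3),
    n_inh: int = 100,
):
    """Synthetic partner pairs whose E-I ratios have a prescribed correlation.

    Builds one excitatory and one inhibitory cluster summary per pair with
    ratios drawn from a bivariate normal of correlation ``r`` (means and SDs
    chosen to keep ratios positive), plus the matching partner-pair and
    partner-count frames, ready for
    :func:`~cortexclust.cluster_props.coupling_stats`. Used to calibrate the
    coupling estimator against a known ground-truth correlation.
    """
    rng = np.random.default_rng(seed)
    cov = [
        [sd_ratio[0] ** 2, r * sd_ratio[0] * sd_ratio[1]],
        [r * sd_ratio[0] * sd_ratio[1], sd_ratio[1] ** 2],
    ]
    draws = rng.multivariate_normal(mean_ratio, cov, size=n_pairs)
    draws = np.clip(draws, 0.05, None)
    rows = []
    pair_rows = []
    for i, (re_t, ri_t) in enumerate(draws):
        eid, iid = f"E:pair{i:04d}", f"I:pair{i:04d}"
        for cid, ctype, ratio in ((eid, "excitatory", re_t), (iid, "inhibitory", ri_t)):
            n_exc = max(1, int(round(ratio * n_inh)))
            rows.append(
                {
                    "cluster_id": cid,
                    "type": ctype,
                    "section_id": "S1",
                    "layer": 2,
                    "size": n_exc + n_inh,
                    "n_exc": n_exc,
                    "n_inh": n_inh,
                    "ei_ratio": n_exc / n_inh,
                    "interregional": False,
                }
            )
        pair_rows.append(
            {
                "exc_cluster_id": eid,
                "inh_cluster_id": iid,
                "shared": 1,
                "jaccard": 1.0 / (2 * (n_inh + 1)),
                "frac_exc": 0.0,
                "frac_inh": 0.0,
            }
        )
    summary = pd.DataFrame(rows).set_index("cluster_id", drop=False)
    pairs = pd.DataFrame(pair_rows)
    counts = pd.DataFrame(
        {"cluster_id": summary["cluster_id"].tolist(), "n_partners": 1}
    )
    return summary, pairs, counts


def expected_nn_distance(density_per_mm2: float) -> float:
    """Mean nearest-neighbor distance (µm) of a homogeneous Poisson process.

    For intensity λ per unit area the closed form is 1/(2·sqrt(λ)).
    """
    lam_um2 = density_per_mm2 / 1e6
    return 1.0 / (2.0 * np.sqrt(lam_um2))
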