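"""Shared data model and TSV interchange for layer-stratified neuron scenes.

A scene is a flat table of neurons. Each record carries per-section 2-D
coordinates in micrometres, a cortical layer (1-6), a brain-region label, a
neuron class (``excitatory`` or ``inhibitory``) and a finer subclass label
(e.g. layer-marker excitatory types ``L2``/``L2.3`` or inhibitory
``PV_CHC``/``RELN``). Coordinates live in a per-section frame: sections are
separate chips, so no geometry is ever computed across sections.

The module also holds :class:`RegionAnnotation` (region -> lobe, functional
systems, cortical hierarchy level) and :class:`AnalysisConfig`, the knobs of
the sliding-window scan, with species presets for window size and step.
"""

from __future__ import annotations

import dataclasses
import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CLASSES",
    "SYSTEMS",
    "REQUIRED_COLUMNS",
    "DEFAULT_SUBCLASS_VOCAB",
    "SchemaError",
    "ValidationError",
    "CellTable",
    "RegionInfo",
    "RegionAnnotation",
    "AnalysisConfig",
    "PRESETS",
    "preset",
    "read_cell_table",
    "write_cell_table",
    "read_region_annotation",
]

CLASSES = ("excitatory", "inhibitory")
SYSTEMS = ("DMN", "visual", "somatosensory")
REQUIRED_COLUMNS = (
    "cell_id",
    "x",
    "y",
    "section_id",
    "layer",
    "region",
    "class",
    "subclass",
)

#: Subclass vocabularies used when a scene does not declare its own.
DEFAULT_SUBCLASS_VOCAB: dict[str, tuple[str, ...]] = {
    "excitatory": ("L2", "L2.3", "L2.3.4", "L3.4", "L3.4.5"),
    "inhibitory": ("PV_CHC", "RELN", "OTHER_IN"),
}


class SchemaError(ValueError):
    """A table is missing required columns or is otherwise malformed."""


class ValidationError(ValueError):
    """One or more rows violate cell invariants.

    ``rows`` holds the offending 0-based row indices (relative to the input
    table, header excluded).
    """

    def __init__(self, message: str, rows: Sequence[int] = ()):  # noqa: D107
        super().__init__(message)
        self.rows = list(rows)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    df = df.loc[:, list(REQUIRED_COLUMNS)].copy()
    problems: dict[int, str] = {}

    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = ~np.isfinite(vals.to_numpy(dtype=float))
        for i in np.flatnonzero(bad):
            problems.setdefault(int(i), f"non-finite {col}")
        df[col] = vals.astype(float)

    layer = pd.to_numeric(df["layer"], errors="coerce")
    with np.errstate(invalid="ignore"):
        arr = layer.to_numpy(dtype=float)
        bad_layer = ~np.isfinite(arr) | (arr != np.round(arr)) | (arr < 1) | (arr > 6)
    for i in np.flatnonzero(bad_layer):
        problems.setdefault(int(i), "layer must be an integer in 1..6")
    df["layer"] = np.where(bad_layer, 1, np.nan_to_num(arr, nan=1.0)).astype(int)

    cls = df["class"].astype(str).str.lower()
    bad_cls = ~cls.isin(CLASSES)
    for i in np.flatnonzero(bad_cls.to_numpy()):
        problems.setdefault(int(i), "class must be excitatory or inhibitory")
    df["class"] = cls

    for col in ("cell_id", "section_id", "region", "subclass"):
        df[col] = df[col].astype(str)

    dup = df["cell_id"].duplicated(keep=False)
    for i in np.flatnonzero(dup.to_numpy()):
        problems.setdefault(int(i), "duplicate cell_id")

    if problems:
        shown = list(problems.items())[:5]
        detail = "; ".join(f"row {i}: {msg}" for i, msg in shown)
        raise ValidationError(
            f"{len(problems)} invalid row(s): {detail}", rows=sorted(problems)
        )
    return df.reset_index(drop=True)


@dataclass
class CellTable:
    """Validated, ordered table of neurons plus per-class subclass vocabularies.

    The underlying :class:`pandas.DataFrame` always carries the canonical
    columns of :data:`REQUIRED_COLUMNS` with a 0..n-1 integer index; stages
    downstream reference cells by that positional index.
    """

    df: pd.DataFrame
    subclass_vocab: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df)
        vocab: dict[str, list[str]] = {
            c: list(self.subclass_vocab.get(c, ())) for c in CLASSES
        }
        # Unknown subclass labels observed in the data are adopted into the
        # vocabulary of the class they occur under.
        for c in CLASSES:
            observed = self.df.loc[self.df["class"] == c, "subclass"].unique()
            for s in sorted(observed):
                if s not in vocab[c]:
                    vocab[c].append(s)
        overlap = set(vocab["excitatory"]) & set(vocab["inhibitory"])
        if overlap:
            raise ValidationError(
                f"subclass label(s) {sorted(overlap)} appear under both classes"
            )
        self.subclass_vocab = {c: tuple(v) for c, v in vocab.items()}

    def __len__(self) -> int:
        return len(self.df)

    @property
    def n_cells(self) -> int:
        return len(self.df)

    def class_counts(self) -> dict[str, int]:
        vc = self.df["class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def inhibitory_fraction(self) -> float:
        if len(self.df) == 0:
            return float("nan")
        return float((self.df["class"] == "inhibitory").mean())

    def full_vocab(self) -> list[str]:
        """All subclass labels, excitatory first, in declared order."""
        return list(self.subclass_vocab["excitatory"]) + list(
            self.subclass_vocab["inhibitory"]
        )

    def subclass_class(self) -> dict[str, str]:
        return {
            s: c for c in CLASSES for s in self.subclass_vocab[c]
        }

    def strata(
        self, by: str = "section_layer"
    ) -> Iterator[tuple[tuple[str, int], pd.DataFrame]]:
        """Yield ``((section_id, layer), sub-frame)`` strata.

        With ``by="layer"`` the key is ``(None, layer)`` and sections are
        pooled. Sub-frames keep the parent's positional index. Empty strata
        (agranular areas) simply do not appear.
        """
        if by == "section_layer":
            for (sec, lay), sub in self.df.groupby(
                ["section_id", "layer"], sort=True
            ):
                yield (str(sec), int(lay)), sub
        elif by == "layer":
            for lay, sub in self.df.groupby("layer", sort=True):
                yield (None, int(lay)), sub
        else:  # pragma: no cover - guarded by AnalysisConfig
            raise ValueError(f"unknown stratification {by!r}")


def read_cell_table(path: str | Path, sep: str | None = None) -> CellTable:
    """Read a TSV/CSV cell table; delimiter auto-detected unless ``sep`` given."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else None
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    return CellTable(df)


def write_cell_table(table: CellTable, path: str | Path) -> None:
    """Write a canonical, byte-deterministic TSV."""
    table.df.loc[:, list(REQUIRED_COLUMNS)].to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


# ---------------------------------------------------------------------------
# Region annotation


@dataclass(frozen=True)
class RegionInfo:
    lobe: str | None
    systems: frozenset[str]
    level: float | None


_EMPTY_INFO = RegionInfo(None, frozenset(), None)

_SYSTEM_ALIASES = {s.lower(): s for s in SYSTEMS}


def _parse_systems(token: str) -> frozenset[str]:
    out = set()
    for part in str(token).replace(";", "|").replace(",", "|").split("|"):
        part = part.strip()
        if not part or part.lower() in {"nan", "none", "-"}:
            continue
        key = part.lower()
        if key not in _SYSTEM_ALIASES:
            raise SchemaError(
                f"unknown functional system {part!r}; expected one of {SYSTEMS}"
            )
        out.add(_SYSTEM_ALIASES[key])
    return frozenset(out)


@dataclass
class RegionAnnotation:
    """Lookup from region label to lobe, functional systems and hierarchy level.

    Regions absent from the annotation resolve to "no lobe, no systems, no
    level" — they act as background in enrichment contrasts.
    """

    info: dict[str, RegionInfo] = field(default_factory=dict)

    def lookup(self, region: str) -> RegionInfo:
        return self.info.get(region, _EMPTY_INFO)

    def systems_of(self, region: str) -> frozenset[str]:
        return self.lookup(region).systems

    def level_of(self, region: str) -> float | None:
        return self.lookup(region).level

    def regions(self) -> list[str]:
        return sorted(self.info)


def read_region_annotation(path: str | Path, sep: str | None = None) -> RegionAnnotation:
    """Read a region annotation table.

    Required column: ``region``. Optional: ``lobe``; either a ``systems``
    column (tokens separated by ``|``/``,``/``;``) or boolean flag columns
    named after the systems (``dmn``, ``visual``, ``somatosensory``); and a
    ``hierarchy_level`` (or ``level``) column. Duplicate region rows must
    agree exactly.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else None
    if sep is None:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    else:
        df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    if "region" not in cols:
        raise SchemaError("missing required column(s): region")
    level_col = cols.get("hierarchy_level") or cols.get("level")
    flag_cols = {s: cols[s.lower()] for s in SYSTEMS if s.lower() in cols}

    truthy = {"1", "true", "yes", "y", "t"}
    info: dict[str, RegionInfo] = {}
    for _, row in df.iterrows():
        region = str(row[cols["region"]]).strip()
        lobe = None
        if "lobe" in cols and pd.notna(row[cols["lobe"]]):
            lobe = str(row[cols["lobe"]]).strip() or None
        systems: frozenset[str]
        if "systems" in cols and pd.notna(row[cols["systems"]]):
            systems = _parse_systems(row[cols["systems"]])
        elif flag_cols:
            systems = frozenset(
                s
                for s, c in flag_cols.items()
                if pd.notna(row[c]) and str(row[c]).strip().lower() in truthy
            )
        else:
            systems = frozenset()
        level = None
        if level_col and pd.notna(row[level_col]) and str(row[level_col]).strip():
            level = float(row[level_col])
        rec = RegionInfo(lobe, systems, level)
        if region in info and info[region] != rec:
            raise ValidationError(
                f"conflicting duplicate annotation rows for region {region!r}"
            )
        info[region] = rec
    return RegionAnnotation(info)


# ---------------------------------------------------------------------------
# Analysis configuration


#: (window_size µm, step µm) presets; the check preset re-runs the primate
#: analysis at finer resolution, the mouse preset matches the smaller cortex.
PRESETS: dict[str, tuple[float, float]] = {
    "macaque": (1000.0, 100.0),
    "macaque-check": (400.0, 100.0),
    "mouse": (400.0, 20.0),
}


@dataclass(frozen=True)
class AnalysisConfig:
    """Parameters of the sliding-window enrichment scan.

    window_size, step
        Square window side and grid step, µm. Must satisfy
        ``window_size >= step > 0`` (a step larger than the window would
        leave unscanned gaps).
    n_perm
        Label permutations per stratum for the enrichment null.
    alpha
        Per-window significance level; windows are flagged at ``p < alpha``
        (raw, no multiplicity correction at this stage).
    stratify
        ``"section_layer"`` (default) shuffles labels within each
        (section, layer); ``"layer"`` pools sections of a layer.
    min_cells
        Windows with fewer cells are not tested.
    connectivity
        ``"shared_cells"`` merges significant windows that share at least one
        cell; ``"geometric"`` merges on geometric overlap instead.
    """

    window_size: float = 1000.0
    step: float = 100.0
    n_perm: int = 10000
    alpha: float = 0.05
    seed: int = 0
    stratify: str = "section_layer"
    min_cells: int = 1
    connectivity: str = "shared_cells"

    def __post_init__(self) -> None:
        if not (self.window_size >= self.step > 0):
            raise ValueError("require window_size >= step > 0")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.stratify not in {"section_layer", "layer"}:
            raise ValueError("stratify must be 'section_layer' or 'layer'")
        if self.connectivity not in {"shared_cells", "geometric"}:
            raise ValueError("connectivity must be 'shared_cells' or 'geometric'")
        if self.min_cells < 1:
            raise ValueError("min_cells must be >= 1")


def preset(name: str, **overrides) -> AnalysisConfig:
    """Return the named species preset, optionally overriding fields."""
    key = name.replace("_", "-").lower()
    if key not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        )
    w, s = PRESETS[key]
    fields = dict(window_size=w, step=s)
    fields.update(overrides)
    return AnalysisConfig(**fields)
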