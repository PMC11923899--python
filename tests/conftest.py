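"""Shared fixtures: tiny hand-built tables and fixture clusters."""

from collections import Counter

import numpy as np
import pandas as pd
import pytest

from cortexclust import CellTable
from cortexclust.window_scan import NeuronCluster


def make_cells_df(
    xy,
    cls=None,
    subclass=None,
    section="S1",
    layer=2,
    region="R1",
    prefix="c",
):
    """Build a canonical cell frame from coordinate pairs and optional labels."""
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    cls = list(cls) if cls is not None else ["excitatory"] * n
    if subclass is None:
        subclass = ["L2" if c == "excitatory" else "PV_CHC" for c in cls]
    region = [region] * n if isinstance(region, str) else list(region)
    layer = [layer] * n if np.isscalar(layer) else list(layer)
    section = [section] * n if isinstance(section, str) else list(section)
    return pd.DataFrame(
        {
            "cell_id": [f"{prefix}{i:04d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "section_id": section,
            "layer": layer,
            "region": region,
            "class": cls,
            "subclass": subclass,
        }
    )


def make_cluster(df, idx, ctype, cid=None):
    """Fixture NeuronCluster over rows ``idx`` of a canonical cell frame."""
    idx = np.asarray(sorted(idx))
    sub = df.loc[idx]
    n_inh = int((sub["class"] == "inhibitory").sum())
    return NeuronCluster(
        cluster_id=cid or f"{'E' if ctype == 'excitatory' else 'I'}:{sub['section_id'].iloc[0]}:L{int(sub['layer'].iloc[0])}:{sub['cell_id'].min()}",
        type=ctype,
        section_id=str(sub["section_id"].iloc[0]),
        layer=int(sub["layer"].iloc[0]),
        cell_idx=idx,
        cell_ids=sub["cell_id"].to_numpy(),
        xy=sub[["x", "y"]].to_numpy(dtype=float),
        n_exc=int(len(sub) - n_inh),
        n_inh=n_inh,
        regions=Counter(sub["region"].tolist()),
        window_origins=[],
    )


@pytest.fixture
def three_cell_table():
    df = make_cells_df(
        [(10.0, 20.0), (30.0, 40.0), (50.0, 60.0)],
        cls=["excitatory", "inhibitory", "excitatory"],
        subclass=["L2", "PV_CHC", "L2.3"],
    )
    return CellTable(df)
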