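"""Group clusters by subclass presence and test functional-system enrichment.

Cluster composition is reduced to a binary presence vector over the subclass
vocabulary; agglomerative clustering (Jaccard distance, average linkage)
groups the clusters of a layer; each group is then tested for enrichment in
annotated functional systems (one-sided Fisher 2x2, BH-adjusted) and
correlated against cortical hierarchy levels.

For clarity the clusters here are constructed directly with controlled
composition (detection-derived clusters plug in the same way): eight
clusters drawing only shallow-layer subclasses sit in visual regions, eight
clusters using the full vocabulary sit in unannotated regions.
"""

import numpy as np
import pandas as pd

from cortexclust import (
    CellTable,
    RegionAnnotation,
    composition_vectors,
    functional_enrichment,
    hierarchical_groups,
    hierarchy_correlation,
    summarize_clusters,
)
from cortexclust.io_model import RegionInfo
from cortexclust.window_scan import NeuronCluster
from collections import Counter

rng = np.random.default_rng(13)
frames, clusters_spec = [], []
cell_rows = []
k_cell = 0
for k in range(16):
    visual = k < 8
    region = ["V1", "V2", "V4", "MT"][k % 4] if visual else f"BG{k % 4}"
    subs = (["L2", "L2.3"] if visual else ["L2", "L2.3", "L2.3.4", "L3.4", "L3.4.5", "PV_CHC"])
    # visual clusters shrink with hierarchy level (early pathways larger)
    n = 60 - 12 * (k % 4) + int(rng.integers(0, 5)) if visual else int(rng.integers(8, 20))
    cx, cy = (k % 4) * 3000.0, (k // 4) * 3000.0
    idx = []
    for i in range(n):
        cell_rows.append(
            {"cell_id": f"c{k_cell:05d}", "x": cx + rng.uniform(0, 300),
             "y": cy + rng.uniform(0, 300), "section_id": "S1", "layer": 2,
             "region": region, "class": "inhibitory" if subs[i % len(subs)] == "PV_CHC" else "excitatory",
             "subclass": subs[i % len(subs)]}
        )
        idx.append(k_cell)
        k_cell += 1
    clusters_spec.append((idx, f"I:S1:L2:g{k:02d}"))

df = pd.DataFrame(cell_rows)
table = CellTable(df)
clusters = []
for idx, cid in clusters_spec:
    sub = df.loc[idx]
    n_inh = int((sub["class"] == "inhibitory").sum())
    clusters.append(NeuronCluster(cid, "inhibitory", "S1", 2, np.array(idx),
                                  sub["cell_id"].to_numpy(),
                                  sub[["x", "y"]].to_numpy(float),
                                  len(sub) - n_inh, n_inh,
                                  Counter(sub["region"]), []))

summary = summarize_clusters(clusters)
_, presence = composition_vectors(clusters, table)
groups = hierarchical_groups(presence, k=2)
print("group sizes:", groups.value_counts().to_dict())

annotation = RegionAnnotation({
    "V1": RegionInfo("occipital", frozenset({"visual"}), 1.0),
    "V2": RegionInfo("occipital", frozenset({"visual"}), 2.0),
    "V4": RegionInfo("occipital", frozenset({"visual"}), 3.0),
    "MT": RegionInfo("temporal", frozenset({"visual"}), 4.0),
})
enrich = functional_enrichment(groups, summary, annotation)
print("\nfunctional enrichment (one-sided Fisher, BH-adjusted):")
print(enrich[["group", "system", "a", "b", "c", "d", "odds_ratio", "p_adj",
              "enriched"]].to_string(index=False))

corr = hierarchy_correlation(summary, annotation)
print("\nhierarchy-level correlations over the annotated (visual) clusters:")
print(corr.to_string(index=False))
print("\n(the shallow-subclass group should be flagged visual-enriched; the "
      "cluster sizes were built larger in early visual regions, so the "
      "level-vs-size correlation comes out negative)")
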