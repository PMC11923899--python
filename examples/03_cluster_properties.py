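"""Summarize detected clusters: E-I ratios, distances, coverage.

After detection, each cluster is described by its excitatory/inhibitory
composition (the E-I ratio; undefined for pure-excitatory clusters), the
KD-tree mean nearest-neighbor distance of its members in µm, and whether it
spans several brain regions. Coverage is the fraction of all neurons lying
inside any cluster.
"""

from cortexclust import (
    PlantedCluster,
    SceneConfig,
    coverage_stats,
    detect_clusters,
    generate_scene,
    layer_class_proportions,
    preset,
    summarize_clusters,
)

config = SceneConfig(
    width=4000, height=4000, density=800, inhibitory_fraction=0.15,
    regions=(("V1", (0.0, 1000.0)), ("V2", (1000.0, 2200.0)),
             ("V4", (2200.0, 3600.0)), ("TEO", (3600.0, 4000.0))),
)
discs = [
    PlantedCluster((1000, 1000), 500, "inhibitory", 0.6),
    PlantedCluster((3000, 3000), 500, "inhibitory", 0.6),
]
table, _ = generate_scene(config, discs, seed=3)
clusters = detect_clusters(table, preset("macaque-check", n_perm=500, seed=4))

summary = summarize_clusters(clusters)
cols = ["type", "size", "n_exc", "n_inh", "ei_ratio", "mean_nn_dist",
        "assigned_region", "interregional"]
print(summary[cols].to_string())

cov = coverage_stats(clusters, table)
print(f"\nfraction of neurons inside clusters: {cov.overall:.3f}")

props, corr = layer_class_proportions(table)
print("\nper-region class proportions:")
print(props.to_string(index=False))
# the E vs I count correlation across regions mirrors the balance of the
# two classes over space
print("\nper-layer E-vs-I count correlation across regions:")
print(corr.to_string(index=False))
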