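# cortexclust

Spatial clustering analysis of excitatory and inhibitory neurons in
layer-stratified single-cell scenes.

Cortical neurons are not scattered uniformly within a layer: both excitatory
(E) and inhibitory (I) neurons form local spatial clusters, and the two
cluster types overlap into partnerships that balance local excitation and
inhibition. `cortexclust` is a library for detecting and characterizing that
organization in tables of neuron positions — the kind produced by
single-cell spatial transcriptomics of cortical sections — and for
validating every step on synthetic scenes with known ground truth. It is
aimed at computational neuroscientists and spatial-omics analysts who have
per-cell coordinates, layer and region annotations, and class/subclass
labels, and want tested, seeded, reproducible cluster statistics.

## Method

For each (section, layer) stratum, a square window of side *W* slides on a
grid of pitch *s* (presets: macaque 1000 µm/100 µm, finer check 400 µm/100
µm, mouse 400 µm/20 µm). Each window's class counts are tested for
one-sided enrichment against a label-permutation null: class labels are
shuffled uniformly over the stratum's fixed positions, and

&nbsp;&nbsp;&nbsp;&nbsp;p = (1 + #{permutations with count ≥ observed}) / (1 + n_perm).

For a window of *n* cells in a stratum of *N* cells, *K* of the class, the
permuted count is exactly hypergeometric, so p converges to
P[Hypergeom(N, K, n) ≥ k] — exposed as `exact_pvalue` and used as the
analytic oracle for the Monte-Carlo estimate. Windows with p < 0.05 for the
same class are merged into neuron clusters via shared-cell connectivity
(connected components of the "shares ≥ 1 cell" graph); cluster members are
the union of the merged windows' cells of both classes.

On top of detection the library computes: E–I ratios (n_exc/n_inh, undefined
for pure-E clusters), KD-tree mean nearest-neighbor distances, interregional
flags, per-layer coverage with SEM across sections, E–I partnerships
(opposite-type clusters sharing cells, with Jaccard = |A∩B|/|A∪B|),
subclass co-occurrence under a subclass-label permutation null with a
meta-permutation for excess co-occurrence, and composition analysis
(binary presence vectors, Jaccard/average-linkage hierarchical groups,
one-sided Fisher enrichment in DMN/visual/somatosensory systems with BH
adjustment, and correlations against cortical hierarchy levels).

## Worked example

```python
from cortexclust import (PlantedCluster, SceneConfig, detect_clusters,
                         generate_scene, preset, summarize_clusters)

config = SceneConfig(width=3000, height=3000, density=800,
                     inhibitory_fraction=0.15)
disc = PlantedCluster(center=(1500, 1500), radius=500,
                      enriched_class="inhibitory", enriched_fraction=0.6)
table, truth = generate_scene(config, [disc], seed=1)
clusters = detect_clusters(table, preset("macaque-check", n_perm=1000, seed=2))
for c in clusters:
    if c.type == "inhibitory":
        print(c.cluster_id, c.size, c.n_exc, c.n_inh)
```

prints

```
I:S1:L2:c000003 1461 964 497
```

one inhibitory cluster of 1461 neurons (964 excitatory + 497 inhibitory —
members keep both classes; the planted disc held ~595 cells at 59%
inhibitory against a 15% background, and the cluster extends a little past
the disc edge because boundary windows partially overlapping the disc are
genuinely enriched too). The `examples/` directory has one short script per
capability (simulation, detection, cluster properties, partnerships,
co-occurrence, composition grouping); each prints the numbers it computes
and what they mean. A thin CLI wraps the same pipeline:
`cortexclust run --config cfg.yaml --out out/`.

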