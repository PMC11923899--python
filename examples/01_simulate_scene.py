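"""Generate a synthetic cortical scene with a planted inhibitory cluster.

Builds a 3 x 3 mm single-layer section of Poisson background neurons (15%
inhibitory), plants one disc whose in-disc inhibitory fraction is raised to
0.6, and prints the scene composition. The planted disc changes labels at
fixed positions only, so density stays homogeneous.
"""

from cortexclust import PlantedCluster, SceneConfig, generate_scene

config = SceneConfig(width=3000, height=3000, density=800, inhibitory_fraction=0.15)
disc = PlantedCluster(center=(1500, 1500), radius=500, enriched_class="inhibitory",
                      enriched_fraction=0.6)
table, truth = generate_scene(config, [disc], seed=1)

counts = table.class_counts()
print(f"cells: {len(table)} (expected ~{config.density * config.area_mm2:.0f})")
print(f"excitatory: {counts['excitatory']}  inhibitory: {counts['inhibitory']}")
print(f"overall inhibitory fraction: {table.inhibitory_fraction():.3f}")
print(f"planted disc members: {len(truth.members[0])} cells")
# the in-disc fraction should sit near the planted 0.6, far above background
ids = set(truth.members[0])
sub = table.df[table.df["cell_id"].isin(ids)]
print(f"in-disc inhibitory fraction: {(sub['class'] == 'inhibitory').mean():.3f}")
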