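# Methods

## Data model

A scene is a flat table of neurons: per-section 2-D coordinates in µm,
cortical layer 1–6, brain-region label, class (excitatory/inhibitory) and a
finer subclass (default vocabularies: excitatory L2, L2.3, L2.3.4, L3.4,
L3.4.5; inhibitory PV_CHC, RELN, OTHER_IN; unknown labels are adopted into
the vocabulary of the class they occur under). Coordinates live in
per-section frames; sections are independent chips and no geometry is ever
computed across them. Empty (section, layer) strata are legal — agranular
areas simply contribute nothing. Region annotations map region labels to a
lobe, to membership in functional systems (DMN, visual, somatosensory) and
to an optional cortical hierarchy level.

## Window scan and permutation null

Each stratum is scanned with a half-open square window [x0, x0+W) × [y0,
y0+W) on a grid of pitch `step`, anchored at step-multiples and extended one
window beyond the data hull, so that every cell falls in exactly (W/step)²
windows when W is a multiple of step. Presets: macaque (W=1000 µm,
step=100 µm), macaque-check (400/100) and mouse (400/20); default
n_perm=10,000, α=0.05.

The null shuffles class labels uniformly among the stratum's fixed cell
positions — equivalent to shuffling coordinates among cells — and the
one-sided enrichment p uses the add-one estimator, so p ∈ (0, 1]. Because
window totals are fixed under label permutation, the permuted in-window
count is exactly hypergeometric; `exact_pvalue` implements that upper tail
and serves as the analytic oracle in the tests (agreement within three
binomial standard errors). A corollary: excess of one class is deficit of
the other, so no window can be significant for both classes at α < 0.5.
Stratification is per (section, layer) by default; a layer-pooled mode
shuffles labels across sections of a layer while windows remain
per-section. Empty windows are never tested (minimum occupancy
configurable, default 1 cell); window flags use raw p < 0.05 with no
multiplicity correction — the multiplicity-guarded analyses are the
meta-permutation and the BH-adjusted composition enrichment, where stated.

Merging: significant same-class windows form a graph with edges between
windows sharing at least one cell (a geometric-overlap mode exists for
sensitivity analysis); connected components are the clusters, and members
are the union of the component windows' cells of both classes. Cluster ids
embed stratum, class and the lexicographically smallest member cell id, so
runs are reproducible byte-for-byte. Merging is order-independent and
idempotent; same-type clusters are pairwise disjoint by construction.

### Boundary dilation

A window that only partially overlaps an enriched disc is still genuinely
enriched relative to the stratum, so flagged windows extend roughly
200–300 µm past a planted disc's edge at W=400 µm. Detected clusters are
therefore slight dilations of the true enriched region: recall of planted
members is high (≥90% for strong discs), while the cell-level Jaccard
between a planted r=500 µm disc and its best-matching cluster plateaus
around 0.45–0.50. This is a property of union-of-windows membership, not of
the permutation test; sparser background (a null closer to the nominal
class fraction) flags more boundary windows and lowers the Jaccard further.

## Cluster metrics

- E–I ratio n_exc/n_inh; pure-excitatory clusters (n_inh = 0) are flagged
  and excluded from correlations rather than mapped to infinity, and
  pure-inhibitory clusters report 0.
- Mean nearest-neighbor distance: KD-tree k=2 query per member, averaged;
  an all-pairs-mean mode exists behind a flag. Undefined below two members.
- Interregional flag: members span ≥ 2 distinct regions. Assigned region:
  plurality of members, ties broken lexicographically (needed for
  system-enrichment tests; any reasonable tie-break works at the scales
  involved).
- Coverage: |union of member cells over both cluster types| / |all
  neurons|, per layer and overall, with the SEM taken across per-section
  fractions (sections are the replication unit).
- Cells-in-I-clusters excess: 1-df chi-square goodness of fit of (cells in
  E-clusters, cells in I-clusters) against the overall class split.
- Partnerships: every (E-cluster, I-cluster) pair sharing ≥ 1 cell, with
  shared count, Jaccard |A∩B|/|A∪B| (the standard denominator; the
  alternative |A|+|B| reading of "total number of cells in the clusters" is
  deliberately not used) and per-cluster overlap fractions.
- Nearest opposite-type cluster: minimum inter-cell Euclidean distance
  within the stratum, ties toward the smaller cluster id; used for the
  adjacent (non-overlapping) coupling analysis.
- Coupling report: Pearson correlations of partner E–I ratios, adjacent-pair
  ratios, log₁₀(size) vs partner count (sizes are analyzed on the log scale
  throughout), ratio vs partner count, and size vs having a partner.
  Undefined below three valid observations.
- Interregional enrichment: per layer and type, the 2×2 odds ratio of being
  interregional in that layer versus all other layers, with Woolf's normal
  CI on the log odds ratio and the Haldane–Anscombe 0.5 correction (flagged)
  when a cell is zero. The per-layer-vs-rest contrast is one of several
  defensible designs; it is fixed here and documented.

## Subclass co-occurrence

Cluster memberships stay fixed; subclass labels are shuffled among all
neurons of the stratum (both classes pooled, matching the class-label null).
Enrichment is one-sided excess with the add-one estimator; presence alone is
not enrichment. Two subclasses co-occur in a cluster when both are enriched
at α=0.05 (raw); clusters with ≥ 2 enriched subclasses are classified EE,
EI or II by the classes of those subclasses. The meta-permutation repeats
the whole procedure on globally shuffled labels n_rep times (default 500;
100 in the validation experiments) and reports
p = (1 + #{replicate fraction ≥ observed}) / (1 + n_rep) per cluster type.
The inner loop may use n_perm=1000 rather than 10,000; observed and
replicate fractions share the inner protocol, so the comparison is
calibrated regardless.

The meta statistic is discrete: with 16 clusters the multi-enriched
fraction takes few values and is usually exactly 0 under the null, so the
empirical p has large mass at 1. By exchangeability the test is valid
(P[p ≤ α] ≤ α), only conservative — the validation suite checks
non-inflation (rejection rate ≤ nominal + 3 binomial SD over 100 null
scenes) and power (planted two-subclass scenes reach the minimal attainable
p).

## Composition analysis

Each cluster yields a subclass proportion vector and a binary presence
vector over the full vocabulary. Adjacent-similarity: each cluster is
paired with its nearest same-type cluster (min inter-cell distance); the
control is an equal number of seeded random non-nearest same-stratum pairs;
pair similarity is the Pearson (and Spearman) correlation of proportion
vectors and the two samples are compared with a one-sided Wilcoxon rank-sum
test. Grouping: agglomerative clustering of presence vectors with Jaccard
distance and average linkage (both configurable; natural for binary data),
cut to k groups (default k=5, configurable — the granularity is a choice,
and a silhouette-style inspection of alternatives is left to the user),
labels h1..hk ordered by group size. System enrichment: one-sided Fisher
2×2 per (group, system) on assigned regions, BH-adjusted within each
(layer, type) family, enriched iff adjusted p < 0.05. Hierarchy
correlations: Pearson r of region hierarchy level against log₁₀(size) and
against E–I ratio, per cluster type, pooled across layers, clusters in
unleveled regions excluded.

## Synthetic scenes

The generator emulates the statistical skeleton of one cortical section: a
homogeneous Poisson background (default 1000 cells/mm² — a placeholder of
the right order, since no per-layer density is encoded), i.i.d. class
labels (default 15% inhibitory), i.i.d. subclass labels from per-class
mixtures (default uniform), equal-band layers and an interval region
tiling. Planted clusters are discs in which class labels are resampled at
fixed positions to a target composition — isolating composition effects
from density effects, mirroring the label-shuffle null — with an optional
density multiplier that adds points. Partner scenes plant one E- and one
I-enriched disc at a controlled separation; in the intersection the
inhibitory fraction is the mean of the two discs' targets, and ground truth
stores per-disc member lists so dual membership is explicit.

What the generator does not emulate: cortical curvature, laminar thickness
gradients, anisotropic or clustered backgrounds beyond the planted discs,
measurement noise in coordinates, or any transcript-level structure.
Passing tests therefore demonstrate statistical correctness of the
machinery (calibration, oracle agreement, ground-truth recovery), not that
any particular biological dataset will show the same effect sizes.

One RNG stream drives each scene with documented draw order (count, x, y,
class, subclass; planted discs in list order), so fixtures are stable. All
pipeline seeds fan out from a single global seed via `SeedSequence`;
per-stratum child seeds mix the seed with a CRC of the stratum key so
results do not depend on iteration order.

## Validation experiment sizes

The validation suite (`cortexclust.validation`, asserted in
`tests/test_acceptance.py`, reported by `scripts/acceptance.py`) uses
desk-scale problem sizes chosen to keep the whole suite in minutes on one
CPU while leaving each check well-powered: ≥60 random windows at
n_perm=10,000 for the oracle; five ~20,000-cell CSR scenes at n_perm=1000
for type-I calibration; one 40,000-cell scene with ten planted discs for
recovery; 100 null scenes (800 cells, 16 clusters) for co-occurrence
calibration; 500 synthetic partner pairs for coupling recovery.

## Known limitations

- Union-of-windows membership dilates detected clusters by up to one window
  beyond the true enriched region (see boundary dilation above).
- With label totals fixed, strong enrichment of one class somewhere makes
  the rest of the stratum relatively enriched for the other class, so
  heavily planted scenes produce complementary background clusters; this is
  inherent to the fixed-total null, not an artifact.
- The meta-permutation p is conservative at small cluster counts (discrete
  statistic).
- The pipeline treats subclass labels as exchangeable within a stratum
  under the null; spatially autocorrelated label noise would inflate
  enrichment and is not modeled.
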