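# Methods

This note records the models, defaults and design decisions behind the
package, and what the synthetic benchmarks do and do not demonstrate.

## Composition binning

**Profiles.** Contigs are profiled by sliding-window k-mer frequencies
(k = 4 by default). A k-mer and its reverse complement share a bin because
contig strand is arbitrary; windows containing non-ACGT characters are
skipped. Counts (plus a pseudocount of 1) receive a centered log-ratio
transform before embedding — compositional data live on a simplex, and CLR
removes the unit-sum constraint that would otherwise dominate the first
principal component.

**Embedding and clustering.** The default embedding is PCA to two
components; a seeded Barnes-Hut t-SNE is available
(`embedding_method: tsne`) but PCA is the default because it is exactly
reproducible and, for Markov sources of the divergence this package
targets (mean transition-matrix total variation ≥ 0.3), already separates
sources by far more than their within-source spread. Clusters come from
DBSCAN. The radius defaults to the 0.95 quantile of the
min_samples-nearest-neighbor distances: tetramer profiles of short contigs
(1–1.5 kb) are noisy and form a sparse halo around their source's core;
a tighter radius splits the halo off as a separate cluster or noise, which
costs recall with no precision benefit. Both radius and min_samples
(default 5) are configurable.

**Three rounds.** Round 1 filters transcriptome contigs at 1.5 kb
(inclusive — a contig exactly at the cutoff is kept), clusters them and
selects the cluster holding the most known-affinity seed contigs (ties go
to the smaller label, with a warning). Round 2 filters genome contigs at
1 kb, embeds them jointly with the round-1 seed contigs and keeps the
genome contigs co-clustering with them. Round 3 fragments reference
genomes into 3-kb spikes, co-embeds them, and discards every cluster
containing any spike (threshold 0 — the most conservative rule; a fraction
threshold is configurable), then applies the similarity rescue.

**Similarity rescue.** Alignment e-values are replaced by exact k-mer
containment (k = 15): a contig whose top hit (containment ≥ 0.05) is a
contaminant reference is removed unless its containment in the target
references reaches 0.3. Exact containment detects shared literal sequence,
not remote homology, so the reference sets must contain sequence from the
same genomes as the mixture: in the synthetic scenario the contaminant
references are the contaminant source genomes (the stand-in for a public
database that includes the contaminating organisms) and the target
references are a 40% sample of the target genome (the stand-in for the
organism's known coding sequence). An alignment-based scorer can be
plugged in by replacing `kmer_containment`.

## Synthetic data

**Metagenomes.** Source organisms are order-1 (configurable) Markov chains
with Dirichlet-random transition rows; `make_divergent_sources` rejects
draws until all pairwise mean total-variation distances clear a floor
(default 0.3). Contig lengths follow a truncated log-normal
(μ = 8, σ = 0.6, range 200–50,000) whose mass straddles the 1 kb and
1.5 kb filter thresholds. Contigs are pooled per multinomial source
proportions, shuffled and anonymized so binning cannot exploit input
order; a truth table keyed by contig id supports exact recall/precision
scoring. What this does *not* emulate: real assemblies' chimeric contigs,
coverage-correlated composition, repeats, or GC-dependent sequencing bias —
binning scores on this generator are upper bounds, not field estimates.

**Coalescent marker sets.** Gene trees are sampled under the multispecies
coalescent with msprime (`Demography.from_species_tree`, one haploid
lineage per taxon, population size 1, so species-tree branch lengths are
coalescent units). Species-tree builders place τ/2 on each rooted stem of
the symmetric quartet arrangement; the unrooted focal branch then has
total length τ, the quantity in the concordance formula
`1 − (2/3)e^(−τ)` (the two stems' failure-to-coalesce probabilities
multiply). τ = 0 produces simultaneous splits — a hard polytomy — which
msprime handles as stacked instantaneous events. Alignments evolve on the
gene trees under an equal-exchange model (JC for nucleotides, Poisson for
20-state amino acids) with branch lengths = coalescent lengths ×
`subst_scale` (default 0.3 substitutions per coalescent unit, a value that
keeps pendant paths around one substitution per site — informative but not
saturated) × a per-marker log-normal rate multiplier (σ = 0.5, mean 1).
Per-site rates are drawn from the discrete-gamma categories of the model.
Occupancy masking drops each taxon from each marker independently.

## Likelihood engine

Felsenstein pruning with site-pattern compression; per-site and
per-category log-likelihoods are exposed for the RELL/AU machinery and
rate estimation. Models are time-reversible with closed-form transition
probabilities in the equal-exchange case and spectral decomposition
otherwise; a 20×20 exchange matrix (e.g. LG) can be loaded — the default
amino-acid model is Poisson, keeping the engine free of hard-coded
empirical tables while every formula downstream is alphabet-generic.
Discrete gamma uses 4 equal-probability categories with conditional-mean
rates.

Point topologies come from neighbor joining (scikit-bio) on
multiple-hit-corrected distances `−((k−1)/k)·ln(1 − (k/(k−1))·p̂)`;
saturated pairs return a configurable ceiling (default 5.0) with a
warning. Branch lengths are optimized coordinate-wise by bounded Brent
(tolerance 1e-6, sweeps stop when the total log-likelihood improves by
less than 1e-8); the total is non-decreasing by construction because a
failed line search restores the previous value. Tree *search* is out of
scope: alternative topologies come from pruning a focal clade and
regrafting it on every backbone branch, which spans exactly the candidate
set the signal-dissection battery needs.

Bootstrap supports resample alignment columns (multinomial weights) and
re-estimate NJ trees; the support of a bipartition is its replicate
frequency. `bootstrap_supports` annotates the point tree;
`bootstrap_bipartition_support` tracks named bipartitions whether or not
the point tree displays them — the right quantity for support
trajectories, where at small matrix sizes the focal split is often absent
from the point estimate yet present in a minority of replicates.
Collapsing removes internal edges with support strictly below the
threshold (an edge exactly at the threshold survives); edges without a
support value count as 0, with a warning.

## Signal dissection

**Site rates.** The agreement score of site i is the mean, over other
sites j, of the fraction of j's state sets (taxa partitioned by character,
gaps excluded) that are subsets of some state set of i. Constant sites
attain the maximum; saturated sites fall to the bottom. Scores are binned
into 10 equal-width categories over the observed range (boundary ties go
to the slower category; an all-constant vector collapses to category 1;
all-gap sites are flagged and binned fastest). Equal-width binning over
the observed range is a declared choice — the original category
boundaries in this family of tools are not standardized. Sequential
stripping removes the fastest categories one at a time and re-estimates
focal-branch supports.

**Quartet mapping.** For each sampled quartet (one taxon per group;
exhaustive when the group product is small enough) the three topologies'
branch lengths are ML-optimized (coarse tolerance 1e-3, 2 sweeps — region
classification is insensitive to the last decimals) and the posterior is
the softmax of their log-likelihoods. Region rule (configurable): corner i
if p_i ≥ 0.7; edge ij if p_i + p_j ≥ 0.9 with neither at corner level;
else center. A dataset is flagged strongly resolved when a corner exceeds
0.75. The simplex partition is parameterized because no single canonical
seven-region geometry exists; the tested invariants (fractions sum to 1,
symmetry on star data) hold for any partition.

**AU test.** Bootstrap proportions at scales 0.5–1.4 (step 0.1) from
RELL resampling (winners of tied replicates split equally), clamped to
[1/(2B), 1 − 1/(2B)]; weighted least squares of
`z_r = Φ⁻¹(1 − BP_r)` on (√r, 1/√r) with binomial weights
`B·φ(z)²/(BP(1−BP))`; `p = 1 − Φ(d − c)`. A tree winning (or losing)
every replicate at every scale carries no curvature information; its p is
reported at the clamp limit and flagged. Markers whose constraint trees
cannot be built (missing taxa) are classified ineligible; otherwise a
marker is AU_similar when the reference topology survives at α and
AU_better when it is rejected while the marker's own best tree stands.

**Polytomy test.** One quartet per gene tree (one leaf per subtree around
the focal branch, seeded draw — sampling all quartets per tree would
pseudo-replicate) after collapsing weakly supported nodes; χ² against
equal thirds with df = 2, `p = exp(−χ²/2)` (cross-checked against the
generic survival function to 1e-12). Fewer than one informative gene tree
leaves the test undefined, flagged rather than forced.

**Informativeness.** Site rates are discrete-gamma posterior means on a
guide tree (NJ of the supermatrix), normalized to mean 1; marker PI at
depth t is `Σ λ·e^(−λt)`. This profile is the classical
rate-times-decay form; it is pluggable, and the tested contract is
rank-level (which markers come first), not value-level. The stepwise
series concatenates markers in rank order over a schedule
(default 5, 10, 20, 30, …) and records focal-branch bootstrap support.

## Benchmark scenarios and their calibration

Two bundled scenarios define the study conditions the test suite measures:

* `star_quartet_scenario` — a 40-taxon alignment simulated directly on a
  star topology (all internal branches zero, no coalescent discordance).
  This isolates the *absence-of-signal* geometry: posteriors hover near
  (1/3, 1/3, 1/3), the center region dominates, and corner occupancies are
  symmetric. Simulating instead under the coalescent at τ = 0 produces a
  different and equally real phenomenon — every quartet resolves sharply
  but equivocally, because gene-tree discordance is genuine signal shared
  across quartets — which is exactly what the polytomy test detects; the
  two scenarios are kept distinct on purpose. Group stems are zero in the
  star scenario because shared stem homoplasy would correlate the noise
  resolutions of different quartets.
* `graded_informativeness_scenario` — 100 markers × 80 sites on a
  12-taxon tree whose focal internal branch is 0.0035 substitutions/site;
  the top quintile of markers evolves at rate 1.0 and the rest at 0.25, so
  the focal signal is concentrated where the informativeness ranking
  should place it. The parameters were chosen so that five markers are
  genuinely insufficient (median support ≤ 50) while the full ranked set
  resolves the branch (median ≥ 95); the per-dataset support at m = 5 is
  bimodal — a handful of early substitutions on the focal branch either
  land or do not — so the median across replicate datasets is the stable
  summary, and single datasets legitimately fall on either side.

## Orchestration

Every stochastic stage derives its seed as
`(global_seed · 1000003 + crc32(stage)) mod (2³¹ − 1)`, making a run a
pure function of (config, seed); the end-to-end test asserts byte-identical
re-runs. Configuration is YAML; a config hash is embedded in the run
report. Default end-to-end sizes (1,000 contigs, 2 Mb per source genome,
60 markers × 120 sites, 100 quartets, 60 bootstrap replicates) keep a full
run around a minute while leaving every statistic in its informative
regime; all are configurable upward.

## Known limitations

* Distance-based NJ supports are not ML supports; trajectories are
  comparable within the package but not numerically to ML-based tools.
* The amino-acid default (Poisson) underfits real proteins; load an
  empirical exchange matrix for anything beyond synthetic checks.
* Exact k-mer containment cannot rescue by remote homology; with real
  data, plug in an aligner-backed scorer.
* The binning generator's sources are stationary Markov chains; real
  genomes have heterogeneous composition (horizontal transfers, repeats),
  so real-data recall will be lower than the synthetic benchmark's.
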