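# olpiphy

Desk-scale tools for two problems that arise when placing an uncultivable
organism in a phylogeny from mixed-origin sequence data:

1. **Composition binning** — extracting the target organism's contigs from a
   non-axenic assembly (e.g. DNA washed off co-cultured host tissue along
   with everything else living on it) by tetranucleotide-composition
   clustering, seeded by transcriptome contigs of known affinity, cleaned by
   co-embedding fragmented reference genomes ("spikes") and by a
   similarity-rescue filter.
2. **Signal dissection** — asking *why* a short internal branch resists
   resolution: is the signal conflicting, or simply absent (a near-polytomy)?
   The battery comprises quartet (likelihood) mapping, approximately-unbiased
   (AU) tests over per-site log-likelihoods, quartet-frequency polytomy
   tests, site-rate stripping, and stepwise concatenation ranked by
   phylogenetic informativeness.

A synthetic-data module generates metagenomic mixtures (Markov-chain source
genomes with known truth tables) and multispecies-coalescent marker sets
(via msprime) so that every stage runs and is tested entirely offline.

## The statistics at the core

* **Binning**: contigs are profiled by canonical tetramer frequencies,
  transformed by a centered log-ratio, embedded by PCA (seeded t-SNE
  optional) and clustered by density (DBSCAN). Contigs co-clustering with
  reference spikes are discarded; contigs whose best k-mer-containment hit
  is a contaminant reference are removed unless rescued by a target-reference
  hit.
* **MSC concordance**: for a quartet spanning an internal branch of length
  τ coalescent units, the probability that a gene tree matches the species
  tree is `1 − (2/3)·e^(−τ)`; τ = 0 is a hard polytomy with all three
  resolutions at 1/3.
* **Polytomy test**: resolution counts (n₁, n₂, n₃) over gene trees are
  tested against equal thirds with χ² (df = 2), where `p = exp(−χ²/2)`.
* **AU test**: per-site log-likelihoods are resampled at scales
  r ∈ {0.5, …, 1.4} (RELL); the bootstrap proportions are fitted as
  `Φ⁻¹(1 − BP_r) ≈ d·√r + c/√r` and `p_AU = 1 − Φ(d − c)`.
* **Quartet mapping**: the posterior weights of the three resolutions of a
  sampled quartet place it on the 2-simplex, partitioned into three corner
  (resolved), three edge and one center (unresolved) regions.
* **Informativeness**: a marker's PI at depth t is `Σ_sites λ·e^(−λt)` with
  per-site rates λ from discrete-gamma posterior means on a guide tree.

The likelihood engine is a Felsenstein pruning implementation (4-state
nucleotide or 20-state amino-acid equal-exchange models, arbitrary
reversible exchange matrices, discrete-gamma rates) with NJ point estimates,
coordinate-wise branch-length ML, nonparametric bootstrap supports,
weak-node collapsing and prune-regraft candidate enumeration.

## Worked example

Run the whole synthetic workflow (metagenome → binning → coalescent markers
→ supermatrix → bootstrap tree → quartet mapping → polytomy test):

```bash
olpiphy run --seed 5 --out demo/
```

prints

```
config bd629d13c105 seed 5
binning_precision      1.0000
binning_recall         0.9493
focal_support          100.0000
polytomy_p             0.0000
quartet_corner1        1.0000
reduction_ratio_bases  0.4044
reduction_ratio_contigs 0.4120
```

Reading the numbers: of 1,000 mixed contigs (45% from the target source),
binning recovered 94.9% of the target contigs with no contaminant carried
along, shrinking the assembly to 40% of its raw size. The marker set was
simulated with a focal internal branch of τ = 1 coalescent unit — a branch
that *is* resolvable — and the battery agrees: the concatenation tree gives
the focal split 100% bootstrap support, every sampled quartet falls in the
matching corner of the simplex, and the polytomy test rejects the
equal-thirds hypothesis (p ≈ 0). Re-running with `tau: 0` in a config file
flips all three readouts: gene-tree resolutions near 1/3 each, a
non-significant polytomy test, and equivocal quartet corners.

Intermediates (FASTA, Newick, partition file, TSV tables, a JSON run
report with a config hash) are written under `demo/`.

The same functionality is available as a library; see the module
docstrings in `src/olpiphy/` and `docs/methods.md` for the model details
and design choices.

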