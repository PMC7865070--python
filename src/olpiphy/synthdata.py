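"""Synthetic data with known ground truth.

Two generators:

* **Metagenomic mixtures** — several Markov-chain "source organisms" with
  distinct oligonucleotide composition, each contributing contigs whose
  lengths follow a truncated log-normal law straddling the 1 kb / 1.5 kb
  filter thresholds.  A truth table records every contig's source, so
  binning recall/precision can be scored exactly.

* **Coalescent marker sets** — gene trees sampled under the multispecies
  coalescent (via msprime) on an ultrametric species tree whose focal
  internal branch length tau (coalescent units) is controllable down to
  zero (a hard polytomy), plus per-marker alignments evolved on those
  gene trees with per-marker rate multipliers, discrete-gamma site rates
  and random taxon occupancy.

For the quartet spanning a focal internal branch of total length tau, the
probability that a gene tree is concordant with the species tree is
``1 - (2/3) exp(-tau)``; the simulators here are tested against that
closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import msprime
import numpy as np
from scipy.stats import norm

from .markerset import MarkerAlignment
from .treekit import SubstModel, Tree, read_tree

NUC = "ACGT"

__all__ = [
    "LabeledContig",
    "SourceModel",
    "LengthLaw",
    "MixtureSpec",
    "CoalescentSpec",
    "simulate_source_genome",
    "shred_genome",
    "make_metagenome_mixture",
    "transition_total_variation",
    "make_divergent_sources",
    "quartet_species_tree",
    "four_group_species_tree",
    "simulate_msc_gene_trees",
    "quartet_topology",
    "concordance_fraction",
    "simulate_alignment",
    "MarkerSimResult",
    "simulate_marker_dataset",
]


@dataclass
class LabeledContig:
    """A sequence with an identifier and (when synthetic) its true source."""

    id: str
    seq: str
    source: str | None = None
    is_target: bool = False

    def __len__(self) -> int:
        return len(self.seq)


# ---------------------------------------------------------------------------
# Markov sources and genome simulation
# ---------------------------------------------------------------------------


@dataclass
class SourceModel:
    """Order-k Markov nucleotide source.

    ``transition_probs`` has one row per k-mer context (lexicographic over
    ACGT, 4**order rows) and one column per successor nucleotide; each row
    sums to 1.
    """

    name: str
    transition_probs: np.ndarray
    order: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        tp = np.asarray(self.transition_probs, dtype=float)
        n_ctx = 4**self.order
        if self.order < 0:
            raise ValueError("Markov order must be non-negative")
        if tp.shape != (n_ctx, 4):
            raise ValueError(f"transition_probs must be ({n_ctx}, 4)")
        if not np.allclose(tp.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("each conditional distribution must sum to 1")
        self.transition_probs = tp

    @classmethod
    def random(
        cls, name: str, seed: int, order: int = 1, concentration: float = 0.35
    ) -> "SourceModel":
        """Dirichlet-random transition rows; small concentration gives
        compositionally distinct sources."""
        rng = np.random.default_rng(seed)
        tp = rng.dirichlet(np.full(4, concentration), size=4**order)
        return cls(name=name, transition_probs=tp, order=order, seed=seed)


def transition_total_variation(a: SourceModel, b: SourceModel) -> float:
    """Mean-over-contexts total variation between two transition matrices."""
    if a.order != b.order:
        raise ValueError("sources have different Markov orders")
    return float(
        0.5 * np.abs(a.transition_probs - b.transition_probs).sum(axis=1).mean()
    )


def make_divergent_sources(
    n: int,
    seed: int,
    min_tv: float = 0.3,
    order: int = 1,
    concentration: float = 0.35,
    max_tries: int = 500,
) -> list[SourceModel]:
    """Draw `n` random sources with all pairwise transition TV >= min_tv."""
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        subseeds = rng.integers(1, 2**31 - 1, size=n)
        sources = [
            SourceModel.random(f"source{i+1}", int(s), order, concentration)
            for i, s in enumerate(subseeds)
        ]
        tvs = [
            transition_total_variation(sources[i], sources[j])
            for i in range(n)
            for j in range(i + 1, n)
        ]
        if min(tvs) >= min_tv:
            return sources
    raise RuntimeError(
        f"could not draw {n} sources with pairwise TV >= {min_tv}"
    )


def simulate_source_genome(
    model: SourceModel, length: int, seed: int | None = None
) -> str:
    """Simulate a genome of exactly `length` bases from the Markov source."""
    if length < 1:
        raise ValueError("genome length must be positive")
    rng = np.random.default_rng(model.seed if seed is None else seed)
    cum = np.cumsum(model.transition_probs, axis=1)
    cum[:, -1] = 1.0
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    k = model.order
    if k == 0:
        out = np.searchsorted(cum[0], u)
    else:
        # seed the context uniformly, then walk the chain
        ctx_arr = rng.integers(0, 4, size=k)
        for i in range(min(k, length)):
            out[i] = ctx_arr[i]
        ctx = 0
        for i in range(k):
            ctx = ctx * 4 + int(ctx_arr[i])
        mask = 4 ** (k - 1)
        cum_list = cum  # local alias
        for i in range(k, length):
            row = cum_list[ctx]
            s = int(np.searchsorted(row, u[i]))
            out[i] = s
            ctx = (ctx % mask) * 4 + s if k > 1 else s
    return "".join(NUC[i] for i in out)


# ---------------------------------------------------------------------------
# contig length law and shredding
# ---------------------------------------------------------------------------


@dataclass
class LengthLaw:
    """Contig length distribution.

    ``family='lognormal'`` is a log-normal(mu, sigma) truncated to
    [min_len, max_len]; ``family='fixed'`` returns ``fixed_len`` always.
    """

    family: str = "lognormal"
    mu: float = 8.0
    sigma: float = 0.6
    min_len: int = 200
    max_len: int = 50_000
    fixed_len: int = 1000

    def __post_init__(self) -> None:
        if self.min_len < 1:
            raise ValueError("minimum contig length must be >= 1")
        if self.family not in ("lognormal", "fixed"):
            raise ValueError(f"unknown length law family: {self.family}")

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.family == "fixed":
            return np.full(n, self.fixed_len, dtype=np.int64)
        out = np.empty(0, dtype=np.int64)
        while out.size < n:
            draw = rng.lognormal(self.mu, self.sigma, size=2 * (n - out.size) + 8)
            draw = draw[(draw >= self.min_len) & (draw <= self.max_len)]
            out = np.concatenate([out, draw.astype(np.int64)])
        return out[:n]

    def mean(self) -> float:
        if self.family == "fixed":
            return float(self.fixed_len)
        mu, s = self.mu, self.sigma
        a, b = math.log(self.min_len), math.log(self.max_len)
        z_a, z_b = (a - mu) / s, (b - mu) / s
        mass = norm.cdf(z_b) - norm.cdf(z_a)
        raw = math.exp(mu + s**2 / 2) * (
            norm.cdf(z_b - s) - norm.cdf(z_a - s)
        )
        return raw / mass

    def tail_mass(self, cutoff: float) -> float:
        """P(length >= cutoff) under the (truncated) law."""
        if self.family == "fixed":
            return 1.0 if self.fixed_len >= cutoff else 0.0
        mu, s = self.mu, self.sigma
        a, b = math.log(self.min_len), math.log(self.max_len)
        z = (math.log(max(cutoff, self.min_len)) - mu) / s
        z_a, z_b = (a - mu) / s, (b - mu) / s
        mass = norm.cdf(z_b) - norm.cdf(z_a)
        if cutoff <= self.min_len:
            return 1.0
        if cutoff >= self.max_len:
            return 0.0
        return (norm.cdf(z_b) - norm.cdf(z)) / mass


def shred_genome(
    sequence: str,
    law: LengthLaw,
    seed: int,
    label: str | None = None,
    is_target: bool = False,
    id_prefix: str = "frag",
) -> list[LabeledContig]:
    """Cut the genome into a non-overlapping tiling of law-drawn lengths.

    The final partial fragment is kept, so the concatenation of the output
    equals the input.
    """
    rng = np.random.default_rng(seed)
    n_est = max(8, int(2 * len(sequence) / law.mean()) + 8)
    lengths = list(law.sample(rng, n_est))
    out: list[LabeledContig] = []
    pos = 0
    i = 0
    while pos < len(sequence):
        if i >= len(lengths):
            lengths.extend(law.sample(rng, n_est))
        ln = int(lengths[i])
        frag = sequence[pos : pos + ln]
        out.append(
            LabeledContig(
                id=f"{id_prefix}{i:05d}",
                seq=frag,
                source=label,
                is_target=is_target,
            )
        )
        pos += ln
        i += 1
    return out


# ---------------------------------------------------------------------------
# metagenome mixtures
# ---------------------------------------------------------------------------


@dataclass
class MixtureSpec:
    """Recipe for a synthetic metagenome.

    `proportions` are the expected fractions of contigs per source
    (realized counts are multinomial); `genome_lengths` bound the bases
    simulated per source (additional genome is simulated if the shred of
    the stated length yields too few contigs).  `target_index` marks the
    stand-in for the organism of interest.
    """

    sources: list[SourceModel]
    genome_lengths: list[int]
    contig_length_law: LengthLaw = field(default_factory=LengthLaw)
    proportions: Sequence[float] | None = None
    target_index: int = 0
    n_contigs: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.sources:
            raise ValueError("mixture needs at least one source")
        if len(self.genome_lengths) != len(self.sources):
            raise ValueError("genome_lengths must match sources")
        if self.proportions is None:
            self.proportions = [1.0 / len(self.sources)] * len(self.sources)
        p = np.asarray(self.proportions, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
            raise ValueError("proportions must be non-negative and sum to 1")
        if not (0 <= self.target_index < len(self.sources)):
            raise ValueError("target_index out of range")


def make_metagenome_mixture(spec: MixtureSpec):
    """Pool shredded source genomes into an anonymized contig set.

    Returns ``(contigs, truth)``: shuffled contigs with anonymous ids and
    a pandas truth table (contig_id, source, is_target, length).  The
    shuffle uses the spec seed so downstream binning cannot exploit input
    order.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    counts = rng.multinomial(spec.n_contigs, np.asarray(spec.proportions))
    pool: list[LabeledContig] = []
    for si, (src, n_want) in enumerate(zip(spec.sources, counts)):
        if n_want == 0:
            continue
        is_t = si == spec.target_index
        gseed = int(rng.integers(1, 2**31 - 1))
        genome = simulate_source_genome(src, spec.genome_lengths[si], seed=gseed)
        frags = shred_genome(
            genome,
            spec.contig_length_law,
            seed=int(rng.integers(1, 2**31 - 1)),
            label=src.name,
            is_target=is_t,
        )
        while len(frags) < n_want:
            extra_genome = simulate_source_genome(
                src, spec.genome_lengths[si], seed=int(rng.integers(1, 2**31 - 1))
            )
            extra = shred_genome(
                extra_genome,
                spec.contig_length_law,
                seed=int(rng.integers(1, 2**31 - 1)),
                label=src.name,
                is_target=is_t,
            )
            frags.extend(extra)
        idx = rng.choice(len(frags), size=n_want, replace=False)
        pool.extend(frags[i] for i in idx)
    order = rng.permutation(len(pool))
    contigs = []
    records = []
    for new_i, old_i in enumerate(order):
        c = pool[old_i]
        cid = f"ctg{new_i:06d}"
        contigs.append(
            LabeledContig(id=cid, seq=c.seq, source=c.source, is_target=c.is_target)
        )
        records.append(
            {
                "contig_id": cid,
                "source": c.source,
                "is_target": c.is_target,
                "length": len(c.seq),
            }
        )
    truth = pd.DataFrame.from_records(records).set_index("contig_id")
    return contigs, truth


# ---------------------------------------------------------------------------
# species trees and the multispecies coalescent
# ---------------------------------------------------------------------------


def quartet_species_tree(
    tau: float, tip_depth: float = 1.0, labels: Sequence[str] = ("A", "B", "C", "D")
) -> str:
    """Ultrametric 4-taxon species tree (coalescent units) whose unrooted
    internal branch has total length `tau` (tau/2 on each rooted stem)."""
    if tau < 0:
        raise ValueError("tau must be non-negative")
    a, b, c, d = labels
    h = tip_depth
    s = tau / 2.0
    return f"(({a}:{h},{b}:{h}):{s},({c}:{h},{d}:{h}):{s});"


def _ladder(labels: Sequence[str], crown: float) -> str:
    """Ladderized ultrametric clade with its MRCA at height `crown`."""
    if len(labels) == 1:
        return f"{labels[0]}:{crown:.15f}"
    heights = np.linspace(crown / len(labels), crown, len(labels) - 1)
    sub = f"({labels[0]}:{heights[0]:.15f},{labels[1]}:{heights[0]:.15f})"
    depth = heights[0]
    for i, lab in enumerate(labels[2:], start=1):
        h = heights[i]
        sub = f"({sub}:{h - depth:.15f},{lab}:{h:.15f})"
        depth = h
    return f"{sub}:{crown - depth:.15f}"


def four_group_species_tree(
    tau: float,
    n_per_group: int = 2,
    group_crown: float = 0.5,
    group_stem: float = 1.0,
    group_names: Sequence[str] = ("G1", "G2", "G3", "G4"),
) -> tuple[str, dict[str, list[str]]]:
    """Species tree of four clades arranged ((G1,G2),(G3,G4)) with the
    focal internal branch of total length `tau` between the two pairs.

    Returns (newick, group -> taxon labels).  Heights are in coalescent
    units; each group is an ultrametric ladder of `n_per_group` taxa.
    """
    if tau < 0:
        raise ValueError("tau must be non-negative")
    # letters, not underscores: newick dialects treat "_" as a space
    groups = {
        g: [f"{g}{chr(ord('a') + i)}" for i in range(n_per_group)]
        for g in group_names
    }
    clades = {g: _ladder(groups[g], group_crown) for g in group_names}
    # each pair of groups joins group_stem above the group crowns
    pair_h = group_crown + group_stem
    left = (
        f"({clades[group_names[0]]},{clades[group_names[1]]})"
        if n_per_group > 1
        else f"({clades[group_names[0]]},{clades[group_names[1]]})"
    )
    right = f"({clades[group_names[2]]},{clades[group_names[3]]})"
    # _ladder emits "subtree:stem" pieces whose stems reach group_crown;
    # extend them to pair height
    def lift(piece: str, extra: float) -> str:
        body, stem = piece.rsplit(":", 1)
        return f"{body}:{float(stem) + extra:.15f}"

    l1 = lift(clades[group_names[0]], group_stem)
    l2 = lift(clades[group_names[1]], group_stem)
    r1 = lift(clades[group_names[2]], group_stem)
    r2 = lift(clades[group_names[3]], group_stem)
    s = tau / 2.0
    newick = f"(({l1},{l2}):{s:.15f},({r1},{r2}):{s:.15f});"
    return newick, groups


def _species_labels(newick: str) -> list[str]:
    t = read_tree(newick)
    return [lf.taxon.label for lf in t.leaf_node_iter()]


@dataclass
class CoalescentSpec:
    """Recipe for a coalescent marker set.

    Branch lengths of `species_newick` are in coalescent units; gene trees
    are sampled under the multispecies coalescent (one lineage per taxon,
    no migration).  Alignment branch lengths are coalescent lengths times
    `subst_scale` times the per-marker rate multiplier (log-normal with
    ``sigma = rate_sigma``, mean 1).
    """

    species_newick: str
    n_genes: int = 100
    sites_per_gene: int = 200
    rate_sigma: float = 0.5
    gamma_shape: float | None = 1.0
    occupancy: float = 1.0
    subst_scale: float = 0.3
    n_states: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError("occupancy must lie in [0, 1]")
        if self.n_genes < 1 or self.sites_per_gene < 1:
            raise ValueError("n_genes and sites_per_gene must be positive")


def simulate_msc_gene_trees(spec: CoalescentSpec) -> list[Tree]:
    """Gene trees (coalescent units) under the MSC on the species tree."""
    demography = msprime.Demography.from_species_tree(
        spec.species_newick, initial_size=1.0
    )
    labels = _species_labels(spec.species_newick)
    samples = {lab: 1 for lab in labels}
    reps = msprime.sim_ancestry(
        samples=samples,
        demography=demography,
        ploidy=1,
        random_seed=(spec.seed % (2**31 - 2)) + 1,
        num_replicates=spec.n_genes,
    )
    pop_names = {p.id: p.name for p in demography.populations}
    ns = dendropy.TaxonNamespace(sorted(labels))
    out = []
    for ts in reps:
        t = ts.first()
        node_labels = {
            u: pop_names[ts.node(u).population] for u in ts.samples()
        }
        nwk = t.as_newick(node_labels=node_labels)
        out.append(read_tree(nwk, taxon_namespace=ns))
    return out


def quartet_topology(tree: Tree, quartet: Sequence[str]) -> int | None:
    """Which resolution of the 4 labels the tree displays.

    Returns 0 for (q0,q1)|(q2,q3), 1 for (q0,q2)|(q1,q3), 2 for
    (q0,q3)|(q1,q2), or None when the induced quartet is unresolved.
    """
    q = list(quartet)
    present = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not set(q) <= present:
        return None
    for code, partner in ((0, 1), (1, 2), (2, 3)):
        pair = [q[0], q[partner]]
        rest = [x for x in q if x not in pair]
        for side in (pair, rest):
            from .treekit import mrca as _mrca

            m = _mrca(tree, side)
            if m is None:
                continue
            sub = {lf.taxon.label for lf in m.leaf_iter()} & set(q)
            if sub == set(side):
                return code
    return None


def concordance_fraction(trees: Sequence[Tree], quartet: Sequence[str]) -> float:
    """Fraction of trees displaying the (q0,q1)|(q2,q3) resolution."""
    codes = [quartet_topology(t, quartet) for t in trees]
    codes = [c for c in codes if c is not None]
    if not codes:
        raise ValueError("no tree resolves the quartet")
    return sum(1 for c in codes if c == 0) / len(codes)


# ---------------------------------------------------------------------------
# sequence evolution on a tree
# ---------------------------------------------------------------------------


def simulate_alignment(
    tree: Tree,
    model: SubstModel,
    n_sites: int,
    seed: int,
    rate: float = 1.0,
    marker_id: str = "marker",
) -> MarkerAlignment:
    """Evolve i.i.d. sites along the tree under the model.

    Per-site rates are drawn uniformly from the model's discrete-gamma
    category rates (all 1 when ``gamma_shape`` is None); `rate` is a
    global multiplier applied to every branch.
    """
    rng = np.random.default_rng(seed)
    k = model.n_states
    cat_rates = model.category_rates()
    site_rates = cat_rates[rng.integers(0, len(cat_rates), size=n_sites)]
    root = tree.seed_node
    states: dict[int, np.ndarray] = {
        id(root): rng.choice(k, size=n_sites, p=model.freqs)
    }
    for nd in tree.preorder_node_iter():
        if nd is root:
            continue
        if nd.edge.length is None:
            raise ValueError("tree has missing branch lengths")
        parent_states = states[id(nd.parent_node)]
        child = parent_states.copy()
        t_eff = max(0.0, nd.edge.length) * rate * site_rates
        if model.is_equal_rates:
            e = np.exp(-k * t_eff / (k - 1))
            p_change = (k - 1) / k * (1.0 - e)
            mut = rng.random(n_sites) < p_change
            if mut.any():
                shift = rng.integers(1, k, size=int(mut.sum()))
                child[mut] = (child[mut] + shift) % k
        else:
            for ci, r in enumerate(cat_rates):
                sel = site_rates == r
                if not sel.any():
                    continue
                p = model.transition_matrix(max(0.0, nd.edge.length) * rate * r)
                cum = np.cumsum(p, axis=1)
                cum[:, -1] = 1.0
                u = rng.random(int(sel.sum()))
                rows = cum[parent_states[sel]]
                child[sel] = (rows < u[:, None]).sum(axis=1)
        states[id(nd)] = child
        if nd.is_leaf():
            pass
    alpha = model.alphabet
    rows = {}
    for lf in tree.leaf_node_iter():
        codes = states[id(lf)]
        rows[lf.taxon.label] = "".join(alpha[c] for c in codes)
    return MarkerAlignment(marker_id=marker_id, rows=rows)


# ---------------------------------------------------------------------------
# full marker-set simulation
# ---------------------------------------------------------------------------


# ---------------------------------------------------------------------------
# ready-made study scenarios
# ---------------------------------------------------------------------------


def star_quartet_scenario(
    seed: int,
    n_per_group: int = 10,
    tip_length: float = 0.08,
    n_sites: int = 4000,
):
    """Alignment simulated on a hard-polytomy (star) topology.

    The four groups radiate from a single point (internal branches exactly
    zero, no coalescent discordance), so quartets spanning the groups
    carry *no* resolving signal: their posterior weights hover near
    (1/3, 1/3, 1/3) and quartet mapping should place most of them in the
    center region with symmetric corner occupancies.  Group stems are
    zero so that noise resolutions of different quartets stay independent
    (shared stem homoplasy would correlate them).

    Returns (rows, groups).
    """
    names = ("G1", "G2", "G3", "G4")
    groups = {
        g: [f"{g}{chr(ord('a') + i)}" for i in range(n_per_group)] for g in names
    }

    def clade(g: str) -> str:
        tips = ",".join(f"{t}:{tip_length}" for t in groups[g])
        return f"({tips}):0.0"

    nwk = f"(({clade('G1')},{clade('G2')}):0.0,({clade('G3')},{clade('G4')}):0.0);"
    tree = read_tree(nwk)
    model = SubstModel(n_states=4)
    aln = simulate_alignment(tree, model, n_sites, seed=seed)
    return aln.rows, groups


def graded_informativeness_scenario(
    seed: int,
    n_markers: int = 100,
    n_top: int = 20,
    sites_per_marker: int = 80,
    rate_top: float = 1.0,
    rate_rest: float = 0.25,
    focal_length: float = 0.0035,
):
    """Marker set whose signal for a short focal branch sits in the
    fastest (top-informativeness) quintile.

    Twelve taxa in four groups of three; the focal internal branch
    (`focal_length` expected substitutions per site) separates groups
    g1+g2 from g3+g4.  The top `n_top` markers evolve at ``rate_top``
    and the remainder at ``rate_rest`` (nearly uninformative at this
    depth); marker order is shuffled so informativeness ranking has to
    recover the planted structure.

    Returns (alignments, focal_side, focal_time) where focal_time is the
    depth of the focal split on the generating tree.
    """
    rng = np.random.default_rng(seed)

    def clade(p: str) -> str:
        return f"(({p}a:0.03,{p}b:0.03):0.03,{p}c:0.06):0.04"

    b2 = focal_length / 2.0
    nwk = (
        f"(({clade('g1')},{clade('g2')}):{b2},"
        f"({clade('g3')},{clade('g4')}):{b2});"
    )
    tree = read_tree(nwk)
    model = SubstModel(n_states=4)
    rates = np.array(
        [rate_top] * n_top + [rate_rest] * (n_markers - n_top)
    )[rng.permutation(n_markers)]
    alignments = []
    for i, r in enumerate(rates):
        alignments.append(
            simulate_alignment(
                tree,
                model,
                sites_per_marker,
                seed=int(rng.integers(1, 2**31 - 1)),
                rate=float(r),
                marker_id=f"mk{i:03d}",
            )
        )
    focal_side = {f"g{k}{c}" for k in (1, 2) for c in "abc"}
    focal_time = 0.05  # depth of the focal split on the generating tree
    return alignments, focal_side, focal_time


@dataclass
class MarkerSimResult:
    gene_trees: list[Tree]
    rates: np.ndarray
    alignments: list[MarkerAlignment]
    species_newick: str


def simulate_marker_dataset(spec: CoalescentSpec) -> MarkerSimResult:
    """Gene trees + alignments + occupancy masking in one pass."""
    rng = np.random.default_rng(spec.seed)
    trees = simulate_msc_gene_trees(spec)
    mu = -(spec.rate_sigma**2) / 2.0
    rates = rng.lognormal(mu, spec.rate_sigma, size=spec.n_genes)
    model = SubstModel(n_states=spec.n_states, gamma_shape=spec.gamma_shape)
    alignments = []
    for gi, (tree, r) in enumerate(zip(trees, rates)):
        aln = simulate_alignment(
            tree,
            model,
            spec.sites_per_gene,
            seed=int(rng.integers(1, 2**31 - 1)),
            rate=float(r) * spec.subst_scale,
            marker_id=f"m{gi:04d}",
        )
        if spec.occupancy < 1.0:
            keep = {
                t: s
                for t, s in aln.rows.items()
                if rng.random() < spec.occupancy
            }
            aln = MarkerAlignment(marker_id=aln.marker_id, rows=keep)
        alignments.append(aln)
    return MarkerSimResult(
        gene_trees=trees,
        rates=rates,
        alignments=alignments,
        species_newick=spec.species_newick,
    )
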