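"""Minimal phylogenetic engine.

Distances with multiple-hit correction, neighbor joining, Felsenstein
pruning likelihoods with discrete-gamma rate heterogeneity, branch-length
optimization, nonparametric bootstrap supports, weak-node collapsing, and
prune-and-regraft candidate enumeration.

Trees are :class:`dendropy.Tree` objects throughout.  Unrooted trees are
represented with a trifurcating seed node; bootstrap supports live on the
``label`` of internal nodes (0-100 scale), the usual Newick dialect.

Tree *search* is deliberately absent: point estimates come from neighbor
joining (optionally refined by branch-length ML), and alternative
topologies from regraft enumeration around a focal clade.  Every question
this package asks (support, conflict, polytomy) is posed over fixed
topologies.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
from dendropy.calculate import treecompare
from scipy.optimize import minimize_scalar
from scipy.special import gammainc, logsumexp
from scipy.stats import gamma as gamma_dist
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

NT_ALPHABET = "ACGT"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

__all__ = [
    "SubstModel",
    "JC_NT",
    "POISSON_AA",
    "Tree",
    "read_tree",
    "read_trees",
    "write_tree",
    "encode_alignment",
    "ml_distance",
    "distance_matrix",
    "nj_tree",
    "PruningKernel",
    "loglik",
    "optimize_branch_lengths",
    "bootstrap_supports",
    "collapse_nodes",
    "regraft_candidates",
    "robinson_foulds",
]

Tree = dendropy.Tree


# ---------------------------------------------------------------------------
# substitution model
# ---------------------------------------------------------------------------


@dataclass
class SubstModel:
    """Time-reversible substitution model with optional discrete-gamma rates.

    With ``exchange=None`` the model is the equal-exchangeability,
    uniform-frequency model: Jukes-Cantor for 4 states, Poisson for 20.
    An arbitrary symmetric exchangeability matrix (e.g. LG loaded from a
    file) may be supplied; the rate matrix is always rescaled so branch
    lengths are expected substitutions per site.

    Parameters
    ----------
    n_states:
        4 (nucleotide) or 20 (amino acid).
    exchange:
        Optional symmetric (n, n) exchangeability matrix, zero diagonal.
    freqs:
        Equilibrium frequencies; uniform when omitted.
    gamma_shape:
        Shape of the discrete-gamma across-site rate distribution;
        ``None`` means rate homogeneity.
    n_rate_categories:
        Number of equal-probability gamma categories (category rates are
        the conditional category means).
    """

    n_states: int = 4
    exchange: np.ndarray | None = None
    freqs: np.ndarray | None = None
    gamma_shape: float | None = None
    n_rate_categories: int = 4
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.n_states not in (4, 20):
            raise ValueError("n_states must be 4 or 20")
        if self.freqs is None:
            self.freqs = np.full(self.n_states, 1.0 / self.n_states)
        else:
            self.freqs = np.asarray(self.freqs, dtype=float)
            if abs(self.freqs.sum() - 1.0) > 1e-8:
                raise ValueError("equilibrium frequencies must sum to 1")
        if self.exchange is not None:
            ex = np.asarray(self.exchange, dtype=float)
            if ex.shape != (self.n_states, self.n_states):
                raise ValueError("exchange matrix shape mismatch")
            if not np.allclose(ex, ex.T):
                raise ValueError("exchange matrix must be symmetric")
            self.exchange = ex

    @property
    def alphabet(self) -> str:
        return NT_ALPHABET if self.n_states == 4 else AA_ALPHABET

    @property
    def is_equal_rates(self) -> bool:
        if not hasattr(self, "_equal_rates"):
            object.__setattr__(
                self,
                "_equal_rates",
                self.exchange is None
                and bool(np.allclose(self.freqs, 1.0 / self.n_states)),
            )
        return self._equal_rates

    def rate_matrix(self) -> np.ndarray:
        """Normalized rate matrix Q (mean rate 1 at equilibrium)."""
        k = self.n_states
        ex = self.exchange
        if ex is None:
            ex = np.ones((k, k)) - np.eye(k)
        q = ex * self.freqs[np.newaxis, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -(self.freqs * np.diag(q)).sum()
        return q / mu

    def _eigen(self):
        if self._eig is None:
            pi = self.freqs
            q = self.rate_matrix()
            d_sqrt = np.sqrt(pi)
            b = q * d_sqrt[:, None] / d_sqrt[None, :]
            vals, vecs = np.linalg.eigh((b + b.T) / 2.0)
            self._eig = (vals, vecs, d_sqrt)
        return self._eig

    def transition_matrix(self, t: float) -> np.ndarray:
        """P(t) = exp(Qt); closed form for the equal-rates case."""
        if t < 0:
            raise ValueError("branch length must be non-negative")
        k = self.n_states
        if self.is_equal_rates:
            e = np.exp(-k * t / (k - 1))
            p_same = 1.0 / k + (k - 1) / k * e
            p_diff = (1.0 - e) / k
            p = np.full((k, k), p_diff)
            np.fill_diagonal(p, p_same)
            return p
        vals, vecs, d_sqrt = self._eigen()
        inner = (vecs * np.exp(vals * t)) @ vecs.T
        p = inner / d_sqrt[:, None] * d_sqrt[None, :]
        return np.clip(p, 0.0, None)

    def category_rates(self) -> np.ndarray:
        """Mean rate of each equal-probability discrete-gamma category."""
        if self.gamma_shape is None:
            return np.array([1.0])
        a = float(self.gamma_shape)
        k = self.n_rate_categories
        bounds = gamma_dist.ppf(np.linspace(0, 1, k + 1), a, scale=1.0 / a)
        upper = gammainc(a + 1.0, a * bounds[1:])
        lower = gammainc(a + 1.0, a * bounds[:-1])
        rates = k * (upper - lower)
        return rates / rates.mean()


JC_NT = SubstModel(n_states=4)
POISSON_AA = SubstModel(n_states=20)


# ---------------------------------------------------------------------------
# tree I/O
# ---------------------------------------------------------------------------


def mrca(tree: Tree, labels: Iterable[str]):
    """MRCA of the labels relative to the seed node (quietly, for trees we
    treat as rooted at their trifurcation)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        return tree.mrca(taxon_labels=sorted(labels))


def read_tree(source: str, taxon_namespace=None) -> Tree:
    """Parse one Newick tree (string or file path)."""
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    if "(" in source or source.strip().endswith(";"):
        return dendropy.Tree.get(data=source, **kwargs)
    return dendropy.Tree.get(path=source, **kwargs)


def read_trees(path: str, taxon_namespace=None) -> list[Tree]:
    """Parse a one-Newick-per-line file into a shared taxon namespace."""
    kwargs = dict(schema="newick", suppress_internal_node_taxa=True)
    if taxon_namespace is not None:
        kwargs["taxon_namespace"] = taxon_namespace
    tl = dendropy.TreeList.get(path=path, **kwargs)
    return list(tl)


def write_tree(tree: Tree, path: str | None = None) -> str:
    """Serialize with supports as internal node labels."""
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(s + "\n")
    return s


# ---------------------------------------------------------------------------
# sequence encoding and distances
# ---------------------------------------------------------------------------


def encode_sequence(seq: str, alphabet: str) -> np.ndarray:
    """Integer codes; characters outside the alphabet (gaps etc.) -> -1."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, c in enumerate(alphabet):
        lut[ord(c)] = i
        lut[ord(c.lower())] = i
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return lut[arr].astype(np.int64)


def encode_alignment(rows: dict[str, str], alphabet: str):
    """Return (taxa list, int matrix taxa x sites)."""
    taxa = list(rows)
    lengths = {len(rows[t]) for t in taxa}
    if len(lengths) > 1:
        raise ValueError("alignment rows have unequal lengths")
    mat = np.stack([encode_sequence(rows[t], alphabet) for t in taxa])
    return taxa, mat


def _mh_correct(p_hat: np.ndarray | float, k: int, ceiling: float) -> np.ndarray:
    """Multiple-hit corrected distance for the equal-rates k-state model."""
    p = np.atleast_1d(np.asarray(p_hat, dtype=float))
    arg = 1.0 - k / (k - 1) * p
    d = np.full_like(p, float(ceiling))
    ok = arg > 0
    d[ok] = -(k - 1) / k * np.log(arg[ok])
    if (~ok).any():
        warnings.warn(
            f"{int((~ok).sum())} saturated pair(s); distance set to ceiling "
            f"{ceiling}",
            stacklevel=2,
        )
    return np.minimum(d, ceiling)


def ml_distance(
    seq_a: str, seq_b: str, model: SubstModel = JC_NT, ceiling: float = 5.0
) -> float:
    """Pairwise corrected distance -((k-1)/k) ln(1 - (k/(k-1)) p).

    Sites where either sequence has a gap/ambiguity are ignored.
    Saturated pairs return `ceiling` with a warning.
    """
    a = encode_sequence(seq_a, model.alphabet)
    b = encode_sequence(seq_b, model.alphabet)
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths")
    valid = (a >= 0) & (b >= 0)
    n = int(valid.sum())
    if n == 0:
        raise ValueError("no comparable (non-gap) sites")
    p_hat = float((a[valid] != b[valid]).mean())
    return float(_mh_correct(p_hat, model.n_states, ceiling)[0])


def distance_matrix(
    rows: dict[str, str], model: SubstModel = JC_NT, ceiling: float = 5.0
) -> tuple[list[str], np.ndarray]:
    """All-pairs corrected distances (vectorized)."""
    taxa, mat = encode_alignment(rows, model.alphabet)
    n = len(taxa)
    valid = mat >= 0
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            nc = both.sum()
            if nc == 0:
                raise ValueError(f"no comparable sites for {taxa[i]}/{taxa[j]}")
            p = (mat[i, both] != mat[j, both]).mean()
            dm[i, j] = dm[j, i] = _mh_correct(p, model.n_states, ceiling)[0]
    return taxa, dm


def nj_tree(dm: np.ndarray, taxa: Sequence[str], taxon_namespace=None) -> Tree:
    """Neighbor joining; negative branch lengths clamped to zero."""
    dm = np.asarray(dm, dtype=float)
    if dm.shape[0] != dm.shape[1] or not np.allclose(dm, dm.T, atol=1e-10):
        raise ValueError("distance matrix must be square and symmetric")
    if dm.shape[0] < 4:
        raise ValueError("neighbor joining needs at least 4 taxa")
    skb = DistanceMatrix(dm, ids=list(taxa))
    newick = str(_skbio_nj(skb, neg_as_zero=True))
    tree = read_tree(newick, taxon_namespace=taxon_namespace)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


# ---------------------------------------------------------------------------
# pruning likelihood
# ---------------------------------------------------------------------------


class PruningKernel:
    """Felsenstein pruning over a fixed topology with pattern compression.

    Branch lengths are exposed as a flat vector (one entry per non-seed
    node, postorder) so an optimizer can perturb single branches without
    touching the tree object.  ``sync_tree`` writes a vector back.
    """

    def __init__(self, tree: Tree, rows: dict[str, str], model: SubstModel):
        self.model = model
        self.tree = tree
        leaf_labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        missing = [t for t in leaf_labels if t not in rows]
        if missing:
            raise ValueError(f"alignment lacks rows for leaves: {missing}")
        taxa, mat = encode_alignment(
            {t: rows[t] for t in leaf_labels}, model.alphabet
        )
        # pattern compression: unique site columns
        cols = mat.T
        patt, inverse = np.unique(cols, axis=0, return_inverse=True)
        self.n_sites = cols.shape[0]
        self._inverse = inverse
        self._weights = np.bincount(inverse, minlength=patt.shape[0]).astype(float)
        self._patt = patt.T  # taxa x patterns
        self._taxon_index = {t: i for i, t in enumerate(taxa)}
        self._cat_rates = model.category_rates()

        # postorder traversal structure
        self.nodes = list(tree.postorder_node_iter())
        self._node_index = {id(nd): i for i, nd in enumerate(self.nodes)}
        self.lengths = np.zeros(len(self.nodes))
        self._children: list[list[int]] = []
        self._is_leaf: list[bool] = []
        self._leaf_partials: list[np.ndarray | None] = []
        for i, nd in enumerate(self.nodes):
            kids = [self._node_index[id(c)] for c in nd.child_nodes()]
            self._children.append(kids)
            self._is_leaf.append(nd.is_leaf())
            if nd.is_leaf():
                row = self._patt[self._taxon_index[nd.taxon.label]]
                self._leaf_partials.append(self._leaf_partial(row))
            else:
                self._leaf_partials.append(None)
            if nd is not tree.seed_node:
                if nd.edge.length is None:
                    raise ValueError("tree has missing branch lengths")
                self.lengths[i] = max(0.0, nd.edge.length)

    @property
    def free_edges(self) -> list[int]:
        """Indices of optimizable branches (every non-seed node's edge)."""
        root = self._node_index[id(self.tree.seed_node)]
        return [i for i in range(len(self.nodes)) if i != root]

    def _leaf_partial(self, codes: np.ndarray) -> np.ndarray:
        k = self.model.n_states
        part = np.zeros((codes.shape[0], k))
        known = codes >= 0
        part[known, codes[known]] = 1.0
        part[~known, :] = 1.0  # gap/ambiguity: uninformative
        return part

    def per_pattern_category_loglik(
        self, lengths: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-rate-category, per-pattern log-likelihoods (n_cat, n_patterns)."""
        if lengths is None:
            lengths = self.lengths
        model = self.model
        rates = self._cat_rates
        n_pat = self._patt.shape[1]
        root = self._node_index[id(self.tree.seed_node)]
        cat_logl = np.empty((len(rates), n_pat))
        for ci, r in enumerate(rates):
            partials: list[np.ndarray | None] = [None] * len(self.nodes)
            scale = np.zeros(n_pat)
            for i in range(len(self.nodes)):
                if self._is_leaf[i]:
                    partials[i] = self._leaf_partials[i]
                    continue
                acc = np.ones((n_pat, model.n_states))
                for c in self._children[i]:
                    p = model.transition_matrix(lengths[c] * r)
                    acc *= partials[c] @ p.T
                    partials[c] = None
                mx = acc.max(axis=1)
                mx[mx == 0] = 1.0
                acc /= mx[:, None]
                scale += np.log(mx)
                partials[i] = acc
            site_l = partials[root] @ model.freqs
            cat_logl[ci] = np.log(np.maximum(site_l, 1e-300)) + scale
        return cat_logl

    def per_pattern_loglik(self, lengths: np.ndarray | None = None) -> np.ndarray:
        cat_logl = self.per_pattern_category_loglik(lengths)
        if cat_logl.shape[0] == 1:
            return cat_logl[0]
        return logsumexp(cat_logl, axis=0) - np.log(cat_logl.shape[0])

    def total_loglik(self, lengths: np.ndarray | None = None) -> float:
        """Pattern-weighted total (avoids per-site expansion)."""
        return float(self.per_pattern_loglik(lengths) @ self._weights)

    def per_site_category_loglik(self) -> np.ndarray:
        """(n_cat, n_sites) log-likelihoods, expanded from patterns."""
        return self.per_pattern_category_loglik()[:, self._inverse]

    def loglik(self, lengths: np.ndarray | None = None):
        per_pattern = self.per_pattern_loglik(lengths)
        per_site = per_pattern[self._inverse]
        return float(per_site.sum()), per_site

    def sync_tree(self) -> Tree:
        root = self._node_index[id(self.tree.seed_node)]
        for i, nd in enumerate(self.nodes):
            if i != root:
                nd.edge.length = float(self.lengths[i])
        return self.tree


def loglik(tree: Tree, rows: dict[str, str], model: SubstModel = JC_NT):
    """Total and per-site log-likelihood of the alignment on the tree."""
    return PruningKernel(tree, rows, model).loglik()


def optimize_branch_lengths(
    tree: Tree,
    rows: dict[str, str],
    model: SubstModel = JC_NT,
    tol: float = 1e-6,
    min_improvement: float = 1e-8,
    max_sweeps: int = 10,
    max_length: float = 10.0,
) -> Tree:
    """Coordinate-wise ML branch-length optimization (Brent per branch).

    Returns a new tree (same taxon namespace) with optimized lengths; the
    total log-likelihood is non-decreasing across sweeps.
    """
    work = tree.clone(depth=1)
    kern = PruningKernel(work, rows, model)
    lengths = kern.lengths.copy()
    best = kern.total_loglik(lengths)
    for _ in range(max_sweeps):
        before = best
        for ei in kern.free_edges:
            def neg(x, ei=ei):
                lengths[ei] = x
                return -kern.total_loglik(lengths)

            res = minimize_scalar(
                neg,
                bounds=(0.0, max_length),
                method="bounded",
                options={"xatol": tol, "maxiter": 60},
            )
            if -res.fun >= best:
                best = -res.fun
                lengths[ei] = res.x
            else:  # keep previous value
                lengths[ei] = kern.lengths[ei]
            kern.lengths = lengths.copy()
        if best - before < min_improvement:
            break
    kern.lengths = lengths
    return kern.sync_tree()


# ---------------------------------------------------------------------------
# bootstrap supports
# ---------------------------------------------------------------------------


def _bipartition_set(tree: Tree) -> set[frozenset]:
    """Non-trivial bipartitions as frozensets of leaf labels (smaller side
    by lexicographic tiebreak is irrelevant: store the side not containing
    the reference taxon)."""
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    out = set()
    for nd in tree.postorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            out.add(side)
    return out


class _BootstrapEngine:
    """Shared machinery: weighted distance matrices and NJ replicates."""

    def __init__(self, rows: dict[str, str], model: SubstModel, ceiling: float):
        self.model = model
        self.ceiling = ceiling
        self.taxa, mat = encode_alignment(rows, model.alphabet)
        self.n_sites = mat.shape[1]
        n = len(self.taxa)
        valid = mat >= 0
        self.pair_idx = [(i, j) for i in range(n) for j in range(i + 1, n)]
        self._mism = np.stack(
            [
                ((mat[i] != mat[j]) & valid[i] & valid[j]).astype(float)
                for i, j in self.pair_idx
            ]
        )
        self._comp = np.stack(
            [(valid[i] & valid[j]).astype(float) for i, j in self.pair_idx]
        )

    def dm(self, w: np.ndarray) -> np.ndarray:
        num = self._mism @ w
        den = self._comp @ w
        den[den == 0] = 1.0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            d = _mh_correct(num / den, self.model.n_states, self.ceiling)
        n = len(self.taxa)
        out = np.zeros((n, n))
        for p, (i, j) in enumerate(self.pair_idx):
            out[i, j] = out[j, i] = d[p]
        return out

    def point_tree(self) -> Tree:
        return nj_tree(self.dm(np.ones(self.n_sites)), self.taxa)

    def replicate_bipartitions(self, n_replicates: int, seed: int):
        rng = np.random.default_rng(seed)
        p = np.full(self.n_sites, 1.0 / self.n_sites)
        for _ in range(n_replicates):
            w = rng.multinomial(self.n_sites, p).astype(float)
            yield _bipartition_set(nj_tree(self.dm(w), self.taxa))


def bootstrap_supports(
    rows: dict[str, str],
    model: SubstModel = JC_NT,
    n_replicates: int = 100,
    seed: int = 0,
    ceiling: float = 5.0,
) -> Tree:
    """NJ point tree with nonparametric bootstrap support percentages.

    Sites are resampled with replacement; each replicate tree is NJ on the
    corrected distance matrix; the support of each bipartition of the point
    tree is the percentage of replicates displaying it.  Supports are
    stored as internal node labels (0-100) and ``node.support``.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    eng = _BootstrapEngine(rows, model, ceiling)
    point = eng.point_tree()
    point_bips = {b: 0 for b in _bipartition_set(point)}
    for bips in eng.replicate_bipartitions(n_replicates, seed):
        for b in bips:
            if b in point_bips:
                point_bips[b] += 1

    labels = sorted(rows)
    ref = labels[0]
    for nd in point.postorder_internal_node_iter():
        if nd is point.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in side:
            side = frozenset(labels) - side
        if 1 < len(side) < len(labels) - 1:
            sup = 100.0 * point_bips[side] / n_replicates
            nd.label = f"{sup:.0f}"
            nd.support = sup
    return point


def bootstrap_bipartition_support(
    rows: dict[str, str],
    bipartitions: dict[str, Iterable[str]],
    model: SubstModel = JC_NT,
    n_replicates: int = 100,
    seed: int = 0,
    ceiling: float = 5.0,
) -> dict[str, float]:
    """Bootstrap frequency (0-100) of named bipartitions.

    Unlike :func:`bootstrap_supports`, this counts how often each given
    bipartition appears among replicate NJ trees whether or not the point
    tree displays it — the right quantity for support trajectories of a
    focal split.
    """
    eng = _BootstrapEngine(rows, model, ceiling)
    labels = sorted(rows)
    ref = labels[0]
    wanted = {}
    for name, side in bipartitions.items():
        s = frozenset(side)
        if ref in s:
            s = frozenset(labels) - s
        wanted[name] = s
    counts = {name: 0 for name in wanted}
    for bips in eng.replicate_bipartitions(n_replicates, seed):
        for name, s in wanted.items():
            if s in bips:
                counts[name] += 1
    return {name: 100.0 * c / n_replicates for name, c in counts.items()}


def get_support(node) -> float | None:
    """Support of a node from its ``support`` attribute or label."""
    if hasattr(node, "support") and node.support is not None:
        return float(node.support)
    if node.label is not None:
        try:
            return float(node.label)
        except ValueError:
            return None
    return None


def collapse_nodes(tree: Tree, threshold: float = 30.0) -> Tree:
    """Contract internal edges with support strictly below `threshold`.

    An edge with support exactly at the threshold is retained.  Internal
    edges without a parsed support value are treated as support 0 with a
    warning.  Returns a new tree; polytomies are permitted.
    """
    work = tree.clone(depth=1)
    to_collapse = []
    for nd in work.postorder_internal_node_iter():
        if nd is work.seed_node or nd.is_leaf():
            continue
        sup = get_support(nd)
        if sup is None:
            warnings.warn(
                "internal edge without support value treated as support 0",
                stacklevel=2,
            )
            sup = 0.0
        if sup < threshold:
            to_collapse.append(nd.edge)
    for edge in to_collapse:
        edge.collapse()
    return work


def support_of_bipartition(tree: Tree, side: Iterable[str]) -> float | None:
    """Support of the bipartition separating `side` from the rest.

    Returns None when the tree does not display the bipartition.
    """
    labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    ref = labels[0]
    want = frozenset(side)
    if ref in want:
        want = frozenset(labels) - want
    for nd in tree.postorder_internal_node_iter():
        if nd is tree.seed_node:
            continue
        got = frozenset(lf.taxon.label for lf in nd.leaf_iter())
        if ref in got:
            got = frozenset(labels) - got
        if got == want:
            sup = get_support(nd)
            return sup if sup is not None else 0.0
    return None


# ---------------------------------------------------------------------------
# regraft enumeration and tree comparison
# ---------------------------------------------------------------------------


def _topology_key(tree: Tree) -> frozenset:
    return frozenset(_bipartition_set(tree))


def regraft_candidates(tree: Tree, focal_clade: str | Iterable[str]) -> list[Tree]:
    """Prune the focal clade and reattach it on every backbone branch.

    Returns the distinct unrooted topologies (the original topology is
    included exactly once).  Branch lengths of returned trees are set to a
    uniform placeholder (0.1); callers optimize them as needed.
    """
    if isinstance(focal_clade, str):
        clade_labels = {focal_clade}
    else:
        clade_labels = set(focal_clade)
    all_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if not clade_labels <= all_labels:
        raise ValueError("focal clade contains unknown taxa")
    backbone_labels = sorted(all_labels - clade_labels)
    if len(backbone_labels) < 3:
        raise ValueError("backbone after pruning must keep >= 3 leaves")

    base = tree.clone(depth=1)
    focal = mrca(base, clade_labels)
    if focal is None or {lf.taxon.label for lf in focal.leaf_iter()} != clade_labels:
        raise ValueError("focal taxa do not form a clade")
    # serialize focal subtree via a throwaway tree
    sub = dendropy.Tree(seed_node=focal.extract_subtree())
    clade_str = sub.as_string(schema="newick").strip()

    backbone = base
    parent = focal.parent_node
    parent.remove_child(focal)
    backbone.suppress_unifurcations()
    backbone_str = write_tree(backbone)

    out: list[Tree] = []
    seen: set[frozenset] = set()
    n_edges = sum(
        1 for nd in backbone.preorder_node_iter() if nd is not backbone.seed_node
    )
    for ei in range(n_edges):
        cand = read_tree(backbone_str, taxon_namespace=tree.taxon_namespace)
        nodes = [nd for nd in cand.preorder_node_iter() if nd is not cand.seed_node]
        target = nodes[ei]
        par = target.parent_node
        mid = dendropy.Node()
        par.remove_child(target)
        par.add_child(mid)
        mid.add_child(target)
        graft = read_tree(clade_str, taxon_namespace=tree.taxon_namespace)
        mid.add_child(graft.seed_node)
        for edge in cand.preorder_edge_iter():
            edge.length = 0.1
        cand.seed_node.edge.length = None
        key = _topology_key(cand)
        if key not in seen:
            seen.add(key)
            out.append(cand)
    return out


def robinson_foulds(t1: Tree, t2: Tree) -> int:
    """Unrooted symmetric (Robinson-Foulds) bipartition distance."""
    l1 = {lf.taxon.label for lf in t1.leaf_node_iter()}
    l2 = {lf.taxon.label for lf in t2.leaf_node_iter()}
    if l1 != l2:
        raise ValueError("trees have different leaf sets")
    ns = dendropy.TaxonNamespace(sorted(l1))
    a = read_tree(write_tree(t1), taxon_namespace=ns)
    b = read_tree(write_tree(t2), taxon_namespace=ns)
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(treecompare.symmetric_difference(a, b))
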