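"""Phylogenetic-signal dissection around a short internal branch.

When a deep internode receives equivocal support, the question is whether
the data carry *conflicting* signal (different markers favoring different
resolutions) or simply *insufficient* signal (a near-polytomy).  This
module implements the standard battery for telling the two apart:

* site-agreement rate scores (TIGER-style) binned into categories, with
  sequential removal of the fastest categories and re-estimation of
  branch supports;
* quartet (likelihood) mapping: posterior weights of the three unrooted
  resolutions of group-spanning quartets, partitioned on the 2-simplex
  into three corner, three edge and one center region;
* the approximately-unbiased (AU) topology test from multiscale RELL
  bootstrap of per-site log-likelihoods, and a per-marker AU
  classification against a reference topology;
* the quartet-frequency polytomy test: chi-square goodness of fit of
  gene-tree resolution counts against the equal thirds expected under a
  hard polytomy (df = 2, so p = exp(-chi2/2) exactly);
* phylogenetic-informativeness ranking of markers and stepwise
  concatenation following that ranking.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from .markerset import GAP, MarkerAlignment, SuperMatrix, concatenate
from .treekit import (
    PruningKernel,
    SubstModel,
    Tree,
    bootstrap_bipartition_support,
    collapse_nodes,
    distance_matrix,
    nj_tree,
    optimize_branch_lengths,
    read_tree,
)

__all__ = [
    "RateCategories",
    "tiger_site_scores",
    "bin_rates",
    "sequential_site_removal",
    "quartet_posteriors",
    "QuartetMapResult",
    "likelihood_mapping",
    "SiteLikelihoodTable",
    "compute_site_likelihoods",
    "rell_bootstrap",
    "AUResult",
    "au_test",
    "classify_markers_au",
    "four_groups_around_edge",
    "quartet_counts_around_branch",
    "PolytomyResult",
    "polytomy_test",
    "pi_rank",
    "PIRanking",
    "estimate_site_rates",
    "default_schedule",
    "stepwise_concat_series",
]


# ---------------------------------------------------------------------------
# TIGER-style site rates
# ---------------------------------------------------------------------------


def _site_partitions(rows: Mapping[str, str]) -> list[tuple[int, ...]]:
    """Per site, the set partition of taxa by character state, as sorted
    taxon bitmasks (gaps and non-alphabet characters excluded)."""
    taxa = list(rows)
    n_sites = len(next(iter(rows.values())))
    parts: list[tuple[int, ...]] = []
    for s in range(n_sites):
        by_state: dict[str, int] = {}
        for ti, t in enumerate(taxa):
            ch = rows[t][s].upper()
            if ch in (GAP, "?", "N", "X", "*", "."):
                continue
            by_state[ch] = by_state.get(ch, 0) | (1 << ti)
        parts.append(tuple(sorted(by_state.values())))
    return parts


def tiger_site_scores(aln: MarkerAlignment | SuperMatrix | Mapping[str, str]) -> np.ndarray:
    """Per-site agreement scores in [0, 1].

    The agreement of site i with site j is the fraction of site-j state
    sets that are subsets of some site-i state set; the score of site i
    is its mean agreement with every other site.  Constant sites (one
    all-taxa set) agree perfectly with everything, so they attain the
    maximum score; sites conflicting with everything score near 0.
    All-gap sites have no defined score and are returned as NaN with a
    warning.
    """
    rows = aln.rows if hasattr(aln, "rows") else dict(aln)
    if len(rows) < 3:
        raise ValueError("need at least 3 taxa")
    n_sites = len(next(iter(rows.values())))
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    parts = _site_partitions(rows)
    uniq: dict[tuple[int, ...], int] = {}
    inv = np.empty(n_sites, dtype=np.int64)
    for s, p in enumerate(parts):
        inv[s] = uniq.setdefault(p, len(uniq))
    patterns = list(uniq)
    weights = np.bincount(inv, minlength=len(patterns)).astype(float)

    m = len(patterns)
    agree = np.zeros((m, m))
    for i, pi in enumerate(patterns):
        if not pi:
            agree[i, :] = np.nan
            continue
        for j, pj in enumerate(patterns):
            if not pj:
                agree[i, j] = np.nan
                continue
            ok = 0
            for sj in pj:
                for si in pi:
                    if sj & ~si == 0:
                        ok += 1
                        break
            agree[i, j] = ok / len(pj)

    scores = np.empty(n_sites)
    # score(s) over all other sites: use pattern weights; a(i, j) is the
    # agreement of site i with site j, i.e. row i evaluated against j's sets
    for s in range(n_sites):
        i = inv[s]
        if not patterns[i]:
            scores[s] = np.nan
            continue
        total = np.nansum(agree[i] * weights) - agree[i, i]
        denom = n_sites - 1 - np.isnan(agree[i]).astype(float) @ weights
        scores[s] = total / denom if denom > 0 else np.nan
    if np.isnan(scores).any():
        warnings.warn(
            f"{int(np.isnan(scores).sum())} all-gap site(s) have undefined "
            "rate scores",
            stacklevel=2,
        )
    return scores


@dataclass
class RateCategories:
    scores: np.ndarray
    categories: np.ndarray  # 1 = slowest / highest agreement
    n_bins: int


def bin_rates(scores: np.ndarray, n_bins: int = 10) -> RateCategories:
    """Equal-width binning of agreement scores into rate categories.

    Category 1 holds the highest-agreement (slowest) sites; ties at bin
    boundaries go to the lower category index.  Constant score vectors
    collapse into category 1; NaN scores (all-gap sites) are binned into
    the fastest category with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    finite = scores[np.isfinite(scores)]
    if finite.size == 0:
        raise ValueError("no finite scores to bin")
    lo, hi = float(finite.min()), float(finite.max())
    cats = np.ones(scores.size, dtype=np.int64)
    if hi > lo:
        width = (hi - lo) / n_bins
        raw = (hi - scores) / width
        with np.errstate(invalid="ignore"):
            cats = np.ceil(raw).astype(float)
        cats[np.isfinite(scores) & (cats < 1)] = 1
        cats = np.where(np.isfinite(scores), cats, n_bins).astype(np.int64)
        cats = np.minimum(cats, n_bins)
    else:
        cats = np.where(np.isfinite(scores), 1, n_bins).astype(np.int64)
    if np.isnan(scores).any():
        warnings.warn(
            "sites with undefined scores binned to the fastest category",
            stacklevel=2,
        )
    return RateCategories(scores=scores, categories=cats, n_bins=n_bins)


def sequential_site_removal(
    sm: SuperMatrix,
    categories: RateCategories,
    model: SubstModel,
    focal_bipartitions: Mapping[str, Sequence[str]],
    n_replicates: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Strip rate categories from fastest to slowest, re-estimating
    bootstrap supports for the focal bipartitions each round.

    Row k drops categories > n_bins - k (k = 0 keeps everything); support
    is the bootstrap frequency of the bipartition among replicate trees,
    and a row is recorded as missing when no usable sites remain.
    """
    cats = categories.categories
    if cats.size != sm.n_sites:
        raise ValueError("categories not aligned to supermatrix columns")
    n_bins = categories.n_bins
    records = []
    for k in range(n_bins):
        keep_mask = cats <= (n_bins - k)
        n_left = int(keep_mask.sum())
        rec: dict = {"k": k, "sites_remaining": n_left}
        if n_left == 0:
            for name in focal_bipartitions:
                rec[name] = np.nan
            records.append(rec)
            continue
        sub = sm.columns(keep_mask)
        try:
            sup = bootstrap_bipartition_support(
                sub.rows,
                dict(focal_bipartitions),
                model,
                n_replicates=n_replicates,
                seed=seed + k,
            )
        except ValueError:
            sup = {name: np.nan for name in focal_bipartitions}
        rec.update(sup)
        records.append(rec)
    return pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# quartet posteriors and likelihood mapping
# ---------------------------------------------------------------------------


def _quartet_tree(order: Sequence[str], ns=None) -> Tree:
    a, b, c, d = order
    nwk = f"(({a}:0.1,{b}:0.1):0.1,{c}:0.1,{d}:0.1);"
    return read_tree(nwk, taxon_namespace=ns)


def quartet_posteriors(
    rows: Mapping[str, str],
    model: SubstModel,
    taxa: Sequence[str] | None = None,
    bl_tol: float = 1e-3,
    max_sweeps: int = 2,
) -> np.ndarray:
    """Posterior weights of the three unrooted quartet topologies.

    Branch lengths of each topology are ML-optimized; weights are
    exp(L_i - logsumexp(L)).  Order: (t1,t2)|(t3,t4), (t1,t3)|(t2,t4),
    (t1,t4)|(t2,t3) for taxa (t1,t2,t3,t4).
    """
    taxa = list(taxa) if taxa is not None else list(rows)
    if len(taxa) != 4:
        raise ValueError("quartet posteriors need exactly 4 taxa")
    sub = {t: rows[t] for t in taxa}
    if all(set(s) <= {GAP, "?"} for s in sub.values()):
        raise ValueError("degenerate all-gap quartet")
    t1, t2, t3, t4 = taxa
    orders = [(t1, t2, t3, t4), (t1, t3, t2, t4), (t1, t4, t2, t3)]
    logls = np.empty(3)
    for i, order in enumerate(orders):
        tree = _quartet_tree(order)
        tree = optimize_branch_lengths(
            tree, sub, model, tol=bl_tol, max_sweeps=max_sweeps
        )
        logls[i], _ = PruningKernel(tree, sub, model).loglik()
    return np.exp(logls - logsumexp(logls))


@dataclass
class QuartetMapResult:
    """Region occupancies of sampled quartets on the 2-simplex.

    ``corners[i]`` is the fraction of quartets resolved for topology i,
    ``edges`` holds the three pairwise-ambiguous regions (12, 13, 23) and
    ``center`` the fully unresolved region; the seven fractions sum to 1.
    """

    n_sampled: int
    corners: np.ndarray
    edges: np.ndarray
    center: float
    resolved: np.ndarray
    strongly_resolved_for: int | None = None

    @property
    def fractions(self) -> np.ndarray:
        return np.concatenate([self.corners, self.edges, [self.center]])


def likelihood_mapping(
    aln: MarkerAlignment | SuperMatrix | Mapping[str, str],
    groups: Mapping[str, Sequence[str]],
    n_quartets: int = 1000,
    model: SubstModel | None = None,
    seed: int = 0,
    corner_threshold: float = 0.7,
    edge_threshold: float = 0.9,
    strong_threshold: float = 0.75,
) -> QuartetMapResult:
    """Quartet mapping with one taxon drawn per group.

    Quartets are sampled uniformly (exhaustively when the total count is
    within ``n_quartets``); each quartet is classified by its posterior
    vector: corner i when p_i >= ``corner_threshold``, edge ij when
    p_i + p_j >= ``edge_threshold`` with neither at corner level, else
    center.  A dataset is flagged strongly resolved for topology i when
    its corner-i fraction exceeds ``strong_threshold``.
    """
    rows = aln.rows if hasattr(aln, "rows") else dict(aln)
    model = model or SubstModel(n_states=4)
    if len(groups) != 4:
        raise ValueError("need exactly four groups")
    gnames = list(groups)
    member_lists = []
    for g in gnames:
        present = [
            t
            for t in groups[g]
            if t in rows and any(ch != GAP for ch in rows[t])
        ]
        if not present:
            raise ValueError(f"group {g!r} has no taxa present in the alignment")
        member_lists.append(present)
    total = int(np.prod([len(m) for m in member_lists]))
    rng = np.random.default_rng(seed)
    if total <= n_quartets:
        combos = list(itertools.product(*member_lists))
    else:
        combos = [
            tuple(m[rng.integers(len(m))] for m in member_lists)
            for _ in range(n_quartets)
        ]
    corners = np.zeros(3)
    edges = np.zeros(3)  # (12, 13, 23)
    center = 0
    n_used = 0
    for quartet in combos:
        try:
            p = quartet_posteriors(rows, model, taxa=list(quartet))
        except ValueError:
            continue
        n_used += 1
        order = np.argsort(p)[::-1]
        if p[order[0]] >= corner_threshold:
            corners[order[0]] += 1
        elif p[order[0]] + p[order[1]] >= edge_threshold:
            i, j = sorted((order[0], order[1]))
            edge_idx = {(0, 1): 0, (0, 2): 1, (1, 2): 2}[(i, j)]
            edges[edge_idx] += 1
        else:
            center += 1
    if n_used == 0:
        raise ValueError("no scorable quartet")
    corners /= n_used
    edges /= n_used
    center /= n_used
    resolved = corners.copy()
    strong = int(np.argmax(resolved)) if resolved.max() > strong_threshold else None
    return QuartetMapResult(
        n_sampled=n_used,
        corners=corners,
        edges=edges,
        center=float(center),
        resolved=resolved,
        strongly_resolved_for=strong,
    )


# ---------------------------------------------------------------------------
# site likelihood tables, RELL, AU
# ---------------------------------------------------------------------------


@dataclass
class SiteLikelihoodTable:
    """Per-site log-likelihoods, one row per candidate tree."""

    tree_ids: list[str]
    matrix: np.ndarray  # (n_trees, n_sites)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.tree_ids):
            raise ValueError("matrix shape does not match tree ids")
        if not np.isfinite(self.matrix).all():
            raise ValueError("site log-likelihoods must be finite")

    @property
    def n_sites(self) -> int:
        return self.matrix.shape[1]

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.tree_ids)} {self.n_sites}\n")
            for tid, row in zip(self.tree_ids, self.matrix):
                fh.write(tid + " " + " ".join(f"{v:.6f}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str) -> "SiteLikelihoodTable":
        with open(path) as fh:
            header = fh.readline().split()
            n_trees, n_sites = int(header[0]), int(header[1])
            ids, rows = [], []
            for _ in range(n_trees):
                toks = fh.readline().split()
                ids.append(toks[0])
                rows.append([float(x) for x in toks[1 : n_sites + 1]])
        return cls(tree_ids=ids, matrix=np.array(rows))


def compute_site_likelihoods(
    trees: Mapping[str, Tree],
    rows: Mapping[str, str],
    model: SubstModel,
    optimize: bool = True,
    bl_tol: float = 1e-4,
    max_sweeps: int = 3,
) -> SiteLikelihoodTable:
    """Per-site log-likelihood of the alignment under each candidate tree
    (branch lengths optimized per topology by default)."""
    ids, mats = [], []
    for tid, tree in trees.items():
        t = tree
        if optimize:
            t = optimize_branch_lengths(
                tree, rows, model, tol=bl_tol, max_sweeps=max_sweeps
            )
        _, per_site = PruningKernel(t, rows, model).loglik()
        ids.append(tid)
        mats.append(per_site)
    return SiteLikelihoodTable(tree_ids=ids, matrix=np.stack(mats))


def rell_bootstrap(
    sitelh: SiteLikelihoodTable,
    scale: float = 1.0,
    B: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Bootstrap proportions from resampled per-site log-likelihoods.

    Each replicate resamples ceil(scale * n_sites) sites with replacement
    and awards the replicate to the tree with the highest resampled total
    (ties split equally).  Proportions sum to 1.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    if B < 1:
        raise ValueError("B must be >= 1")
    n_sites = sitelh.n_sites
    if n_sites == 0:
        raise ValueError("empty site-likelihood table")
    m = int(math.ceil(scale * n_sites))
    rng = np.random.default_rng(seed)
    w = rng.multinomial(m, np.full(n_sites, 1.0 / n_sites), size=B).astype(float)
    totals = w @ sitelh.matrix.T  # (B, n_trees)
    best = totals.max(axis=1, keepdims=True)
    is_winner = totals >= best - 1e-9
    props = (is_winner / is_winner.sum(axis=1, keepdims=True)).sum(axis=0) / B
    return props


@dataclass
class AUResult:
    """Approximately-unbiased test over a candidate tree set."""

    tree_ids: list[str]
    pvalues: np.ndarray
    d: np.ndarray
    c: np.ndarray
    scales: np.ndarray
    B: int
    bp: np.ndarray  # (n_trees, n_scales)
    clamped: np.ndarray  # bool per tree: all proportions at clamp limit

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "tree": self.tree_ids,
                "p_au": self.pvalues,
                "d": self.d,
                "c": self.c,
                "bp1": self.bp[:, np.argmin(np.abs(self.scales - 1.0))],
                "clamped": self.clamped,
            }
        )


def au_test(
    sitelh: SiteLikelihoodTable,
    scales: Sequence[float] | None = None,
    B: int = 10000,
    seed: int = 0,
) -> AUResult:
    """Multiscale-bootstrap AU test.

    For each tree the bootstrap proportion BP_r is measured at each scale
    r, converted to z_r = Phi^-1(1 - BP_r) (clamped to the resolution of
    B replicates), and the signed distance / curvature model
    z_r = d sqrt(r) + c / sqrt(r) is fitted by weighted least squares
    with binomial weights; p_AU = 1 - Phi(d - c).
    """
    if len(sitelh.tree_ids) < 2:
        raise ValueError("AU test needs at least 2 candidate trees")
    if scales is None:
        scales = np.round(np.arange(0.5, 1.41, 0.1), 10)
    scales = np.asarray(list(scales), dtype=float)
    rng = np.random.default_rng(seed)
    n_trees = len(sitelh.tree_ids)
    bp = np.empty((n_trees, scales.size))
    for si, r in enumerate(scales):
        bp[:, si] = rell_bootstrap(
            sitelh, scale=float(r), B=B, seed=int(rng.integers(1, 2**31 - 1))
        )
    lo, hi = 1.0 / (2 * B), 1.0 - 1.0 / (2 * B)
    bp_c = np.clip(bp, lo, hi)
    all_hi = np.all(bp >= hi, axis=1)
    all_lo = np.all(bp <= lo, axis=1)
    clamped = all_hi | all_lo
    z = norm.ppf(1.0 - bp_c)
    sq = np.sqrt(scales)
    X = np.stack([sq, 1.0 / sq], axis=1)  # (n_scales, 2)
    pvals = np.empty(n_trees)
    ds = np.empty(n_trees)
    cs = np.empty(n_trees)
    for ti in range(n_trees):
        phi = norm.pdf(z[ti])
        wts = B * phi**2 / (bp_c[ti] * (1.0 - bp_c[ti]))
        W = np.sqrt(wts)
        beta, *_ = np.linalg.lstsq(X * W[:, None], z[ti] * W, rcond=None)
        ds[ti], cs[ti] = beta
        pvals[ti] = 1.0 - norm.cdf(ds[ti] - cs[ti])
    # a tree winning (or losing) every replicate at every scale carries no
    # curvature information; report the clamp-limit value, flagged
    pvals[all_hi] = hi
    pvals[all_lo] = lo
    return AUResult(
        tree_ids=list(sitelh.tree_ids),
        pvalues=np.clip(pvals, lo, hi),
        d=ds,
        c=cs,
        scales=scales,
        B=B,
        bp=bp,
        clamped=clamped,
    )


def classify_markers_au(
    per_marker_sitelh: Mapping[str, SiteLikelihoodTable | None],
    reference_id: str = "reference",
    alpha: float = 0.05,
    B: int = 2000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-marker AU classification against a reference topology.

    A marker is *AU_similar* when the reference topology is not rejected
    (p_ref >= alpha), *AU_better* when the reference is rejected while
    the marker's own best tree stands, and *ineligible* when its table is
    None (constraints could not be applied, e.g. missing taxa).

    Returns a frame (marker, p_ref, p_best, best_tree, class).
    """
    rng = np.random.default_rng(seed)
    records = []
    for mid, table in per_marker_sitelh.items():
        if table is None:
            records.append(
                {
                    "marker": mid,
                    "p_ref": np.nan,
                    "p_best": np.nan,
                    "best_tree": None,
                    "class": "ineligible",
                }
            )
            continue
        if reference_id not in table.tree_ids:
            raise ValueError(f"marker {mid}: no {reference_id!r} row")
        res = au_test(table, B=B, seed=int(rng.integers(1, 2**31 - 1)))
        totals = table.matrix.sum(axis=1)
        best_i = int(np.argmax(totals))
        ref_i = table.tree_ids.index(reference_id)
        p_ref = float(res.pvalues[ref_i])
        p_best = float(res.pvalues[best_i])
        if p_ref >= alpha:
            cls = "AU_similar"
        else:
            cls = "AU_better"
            if p_best < alpha:
                warnings.warn(
                    f"marker {mid}: best tree itself rejected (p={p_best:.3g})",
                    stacklevel=2,
                )
        records.append(
            {
                "marker": mid,
                "p_ref": p_ref,
                "p_best": p_best,
                "best_tree": table.tree_ids[best_i],
                "class": cls,
            }
        )
    return pd.DataFrame.from_records(records).set_index("marker")


# ---------------------------------------------------------------------------
# polytomy test
# ---------------------------------------------------------------------------


def four_groups_around_edge(
    species_tree: Tree, side: Sequence[str]
) -> list[set[str]]:
    """The four taxon sets induced by an internal branch.

    `side` is one side of the focal bipartition; the groups are the two
    clades below the branch and the two subtrees on the far side.
    """
    side = set(side)
    all_taxa = {lf.taxon.label for lf in species_tree.leaf_node_iter()}
    if not side < all_taxa:
        raise ValueError("side must be a proper subset of the leaf set")
    from .treekit import mrca as _mrca

    nd = _mrca(species_tree, side)
    if nd is None or {lf.taxon.label for lf in nd.leaf_iter()} != side:
        raise ValueError("side does not correspond to a clade / internal branch")
    kids = nd.child_nodes()
    if len(kids) != 2:
        raise ValueError("focal node must be bifurcating")
    g1 = {lf.taxon.label for lf in kids[0].leaf_iter()}
    g2 = {lf.taxon.label for lf in kids[1].leaf_iter()}
    parent = nd.parent_node
    if parent is None:
        raise ValueError("focal branch must be internal")
    siblings = [c for c in parent.child_nodes() if c is not nd]
    if parent.parent_node is None and len(siblings) >= 2:
        g3 = {lf.taxon.label for lf in siblings[0].leaf_iter()}
        g4 = set().union(
            *({lf.taxon.label for lf in s.leaf_iter()} for s in siblings[1:])
        )
    elif siblings:
        g3 = {lf.taxon.label for lf in siblings[0].leaf_iter()}
        g4 = all_taxa - side - g3
    else:
        raise ValueError("cannot derive four groups around this branch")
    if not g4:
        raise ValueError("far side of the branch is not subdivided")
    return [g1, g2, g3, g4]


def quartet_counts_around_branch(
    gene_trees: Sequence[Tree],
    species_tree: Tree | None = None,
    focal_side: Sequence[str] | None = None,
    groups: Sequence[set[str]] | None = None,
    collapse_threshold: float | None = 30.0,
    seed: int = 0,
) -> tuple[int, int, int]:
    """Count gene-tree resolutions of the focal branch's quartet.

    Per gene tree (after collapsing weakly supported nodes when a
    threshold is given) one taxon is drawn from each of the four subtrees
    induced by the focal branch; the displayed resolution is tallied.
    Gene trees lacking representation in a group, or whose sampled
    quartet is unresolved after collapsing, are uninformative and
    skipped.

    Returns (n1, n2, n3): n1 counts the concordant resolution
    (g1,g2)|(g3,g4).
    """
    if groups is None:
        if species_tree is None or focal_side is None:
            raise ValueError("need either groups or species_tree + focal_side")
        groups = four_groups_around_edge(species_tree, focal_side)
    groups = [set(g) for g in groups]
    rng = np.random.default_rng(seed)
    counts = [0, 0, 0]
    for gt in gene_trees:
        work = gt
        if collapse_threshold is not None and any(
            nd.label is not None or getattr(nd, "support", None) is not None
            for nd in gt.postorder_internal_node_iter()
            if nd is not gt.seed_node
        ):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                work = collapse_nodes(gt, collapse_threshold)
        present = {lf.taxon.label for lf in work.leaf_node_iter()}
        picks = []
        ok = True
        for g in groups:
            avail = sorted(g & present)
            if not avail:
                ok = False
                break
            picks.append(avail[rng.integers(len(avail))])
        if not ok:
            continue
        from .synthdata import quartet_topology

        code = quartet_topology(work, picks)
        if code is None:
            continue
        counts[code] += 1
    return tuple(counts)


@dataclass
class PolytomyResult:
    counts: tuple[int, int, int]
    n_informative: int
    chi2: float
    pvalue: float
    alpha: float
    polytomy_not_rejected: bool | None
    insufficient: bool = False


def polytomy_test(
    counts: Sequence[int], alpha: float = 0.05
) -> PolytomyResult:
    """Chi-square goodness of fit of resolution counts against equal
    thirds (the hard-polytomy expectation).

    With df = 2 the survival function has the closed form
    p = exp(-chi2 / 2).  Zero informative gene trees leave the test
    undefined (flagged, p = NaN).
    """
    n1, n2, n3 = (int(x) for x in counts)
    n = n1 + n2 + n3
    if n == 0:
        return PolytomyResult(
            counts=(0, 0, 0),
            n_informative=0,
            chi2=float("nan"),
            pvalue=float("nan"),
            alpha=alpha,
            polytomy_not_rejected=None,
            insufficient=True,
        )
    e = n / 3.0
    chi2 = sum((x - e) ** 2 / e for x in (n1, n2, n3))
    p = math.exp(-chi2 / 2.0)
    return PolytomyResult(
        counts=(n1, n2, n3),
        n_informative=n,
        chi2=float(chi2),
        pvalue=float(p),
        alpha=alpha,
        polytomy_not_rejected=bool(p >= alpha),
    )


# ---------------------------------------------------------------------------
# phylogenetic informativeness
# ---------------------------------------------------------------------------


def estimate_site_rates(
    rows: Mapping[str, str],
    model: SubstModel,
    guide_tree: Tree | None = None,
) -> np.ndarray:
    """Posterior-mean per-site substitution rates, normalized to mean 1.

    Rates come from the discrete-gamma posterior on a guide tree (NJ on
    the corrected distance matrix unless one is supplied).  The model
    must carry a gamma shape, otherwise every site has rate 1.
    """
    rows = dict(rows)
    if guide_tree is None:
        taxa, dm = distance_matrix(rows, model)
        guide_tree = nj_tree(dm, taxa)
    if model.gamma_shape is None:
        n_sites = len(next(iter(rows.values())))
        return np.ones(n_sites)
    kern = PruningKernel(guide_tree, rows, model)
    cat_logl = kern.per_site_category_loglik()  # (n_cat, n_sites)
    cat_rates = model.category_rates()
    w = np.exp(cat_logl - logsumexp(cat_logl, axis=0, keepdims=True))
    rates = cat_rates @ w
    mean = rates.mean()
    return rates / mean if mean > 0 else rates


def townsend_rho(lam: np.ndarray, t: float) -> np.ndarray:
    """Default per-site informativeness profile: lambda * exp(-lambda t)."""
    return lam * np.exp(-lam * t)


@dataclass
class PIRanking:
    table: pd.DataFrame  # index marker, columns pi, rank
    focal_time: float

    @property
    def ranked_ids(self) -> list[str]:
        return list(self.table.sort_values("rank").index)


def pi_rank(
    marker_site_rates: Mapping[str, np.ndarray],
    focal_time: float,
    rho: Callable[[np.ndarray, float], np.ndarray] = townsend_rho,
) -> PIRanking:
    """Rank markers by phylogenetic informativeness at the focal depth.

    PI of a marker is the sum over its sites of rho(lambda_site, t);
    markers missing rate estimates are excluded with a warning.  Rank 1
    is the most informative; ties break lexicographically.
    """
    if focal_time <= 0:
        raise ValueError("focal time must be positive")
    records = []
    for mid, lam in marker_site_rates.items():
        if lam is None:
            warnings.warn(f"marker {mid} has no rate estimates; excluded",
                          stacklevel=2)
            continue
        lam = np.asarray(lam, dtype=float)
        records.append({"marker": mid, "pi": float(rho(lam, focal_time).sum())})
    if not records:
        raise ValueError("no marker with rate estimates")
    df = pd.DataFrame.from_records(records).set_index("marker")
    df = df.sort_values(["pi", "marker"], ascending=[False, True], kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return PIRanking(table=df, focal_time=focal_time)


def default_schedule(n_markers: int) -> list[int]:
    """5, 10, 20, 30, ... then the full set."""
    sched = [m for m in [5, 10] if m <= n_markers]
    sched += list(range(20, n_markers + 1, 10))
    if not sched or sched[-1] != n_markers:
        sched.append(n_markers)
    return sched


def stepwise_concat_series(
    ranked_markers: Sequence[MarkerAlignment],
    schedule: Sequence[int],
    model: SubstModel,
    focal_bipartitions: Mapping[str, Sequence[str]],
    seed: int = 0,
    n_replicates: int = 100,
) -> pd.DataFrame:
    """Bootstrap-support trajectory as markers are concatenated in rank
    order (highest informativeness first).

    Returns a frame with one row per focal bipartition and one column per
    schedule size; a cell is NaN when the round's tree does not display
    that bipartition.
    """
    if any(m > len(ranked_markers) for m in schedule):
        raise ValueError("schedule exceeds the number of markers")
    taxa = sorted({t for m in ranked_markers for t in m.rows})
    out: dict[int, dict[str, float]] = {}
    for m in schedule:
        sm = concatenate(ranked_markers[:m], taxon_universe=taxa)
        out[m] = bootstrap_bipartition_support(
            sm.rows,
            dict(focal_bipartitions),
            model,
            n_replicates=n_replicates,
            seed=seed + m,
        )
    return pd.DataFrame(out)
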