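"""Marker-occupancy bookkeeping and supermatrix construction.

Per-marker alignments are assigned, trimmed and filtered, then
concatenated into a gap-filled supermatrix with a 1-based inclusive
partition table — the usual phylogenomic matrix layout.  Filters mirror
standard practice for deep phylogenies: markers with byte-identical rows
for different taxa are flagged for exclusion from gene-tree inference,
and a broad-distribution filter keeps only markers present in an anchor
taxon plus at least one member of every required higher group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"

__all__ = [
    "MarkerAlignment",
    "SuperMatrix",
    "read_fasta_alignment",
    "write_fasta_alignment",
    "build_profile",
    "assign_markers",
    "trim_alignment",
    "find_identical_sequence_markers",
    "occupancy_matrix",
    "occupancy_stats",
    "broad_distribution_filter",
    "concatenate",
    "write_partition_file",
    "read_partition_file",
]


@dataclass
class MarkerAlignment:
    """One marker's alignment: taxon -> aligned sequence (uniform length)."""

    marker_id: str
    rows: dict[str, str]
    kept_columns: list[int] | None = None  # 0-based source coordinates

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError(f"{self.marker_id}: rows have unequal lengths")

    @property
    def taxa(self) -> list[str]:
        return list(self.rows)

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0


@dataclass
class SuperMatrix:
    """Concatenated alignment with a 1-based inclusive partition table."""

    rows: dict[str, str]
    partitions: list[tuple[str, int, int]]

    @property
    def n_sites(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    def slice(self, marker_id: str) -> MarkerAlignment:
        """Recover one marker's block (gap-filled rows included)."""
        for name, start, end in self.partitions:
            if name == marker_id:
                return MarkerAlignment(
                    marker_id=marker_id,
                    rows={t: s[start - 1 : end] for t, s in self.rows.items()},
                )
        raise KeyError(marker_id)

    def columns(self, mask: np.ndarray) -> "SuperMatrix":
        """Subset columns by a boolean mask; partitions are re-derived per
        marker from surviving columns (markers may shrink or vanish)."""
        mask = np.asarray(mask, dtype=bool)
        if mask.size != self.n_sites:
            raise ValueError("mask length must equal supermatrix width")
        keep_idx = np.flatnonzero(mask)
        new_rows = {
            t: "".join(s[i] for i in keep_idx) for t, s in self.rows.items()
        }
        new_parts = []
        cursor = 1
        for name, start, end in self.partitions:
            width = int(mask[start - 1 : end].sum())
            if width > 0:
                new_parts.append((name, cursor, cursor + width - 1))
                cursor += width
        return SuperMatrix(rows=new_rows, partitions=new_parts)


# ---------------------------------------------------------------------------
# FASTA I/O (Biopython-backed)
# ---------------------------------------------------------------------------


def read_fasta_alignment(path: str, marker_id: str | None = None) -> MarkerAlignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    return MarkerAlignment(marker_id=marker_id or str(path), rows=rows)


def write_fasta_alignment(aln: MarkerAlignment | SuperMatrix, path: str) -> None:
    recs = [
        SeqRecord(Seq(s), id=t, description="") for t, s in aln.rows.items()
    ]
    SeqIO.write(recs, path, "fasta")


# ---------------------------------------------------------------------------
# profile scoring marker assignment
# ---------------------------------------------------------------------------


def build_profile(
    aln: MarkerAlignment, alphabet: str, pseudocount: float = 1.0
) -> np.ndarray:
    """Position-specific log-odds profile (sites x alphabet) with Laplace
    pseudocounts against a uniform background."""
    k = len(alphabet)
    idx = {c: i for i, c in enumerate(alphabet)}
    counts = np.zeros((aln.n_sites, k))
    for s in aln.rows.values():
        for pos, ch in enumerate(s):
            j = idx.get(ch.upper())
            if j is not None:
                counts[pos, j] += 1
    probs = (counts + pseudocount) / (
        counts.sum(axis=1, keepdims=True) + pseudocount * k
    )
    return np.log2(probs * k)  # log-odds vs uniform background


def _score_against_profile(seq: str, profile: np.ndarray, alphabet: str) -> float:
    """Best ungapped-offset sum of per-position log-odds."""
    idx = {c: i for i, c in enumerate(alphabet)}
    codes = np.array([idx.get(c.upper(), -1) for c in seq])
    L, W = profile.shape[0], codes.size
    best = -np.inf
    if W >= L:
        offsets = range(0, W - L + 1)
        for off in offsets:
            window = codes[off : off + L]
            ok = window >= 0
            sc = profile[np.flatnonzero(ok), window[ok]].sum()
            best = max(best, float(sc))
    else:
        for off in range(0, L - W + 1):
            ok = codes >= 0
            sc = profile[off + np.flatnonzero(ok), codes[ok]].sum()
            best = max(best, float(sc))
    return best


def assign_markers(
    candidate_seqs: Mapping[str, str],
    marker_reference_alignments: Sequence[MarkerAlignment],
    alphabet: str,
    score_threshold: float | None = None,
    null_sd_factor: float = 5.0,
    n_shuffles: int = 20,
    seed: int = 0,
) -> dict[str, tuple[str, float]]:
    """Assign candidate sequences to markers by profile log-odds score.

    Each candidate is scored against every marker profile; the best-scoring
    marker wins if the score clears the threshold.  When no explicit
    threshold is given, one is calibrated per candidate from shuffled-
    sequence null scores (mean + `null_sd_factor` standard deviations).
    At most one candidate is kept per marker (highest score; the losing
    hit is logged with a warning).

    Returns marker_id -> (candidate_id, score).
    """
    if not marker_reference_alignments:
        raise ValueError("need at least one marker reference alignment")
    profiles = {
        aln.marker_id: build_profile(aln, alphabet)
        for aln in marker_reference_alignments
    }
    rng = np.random.default_rng(seed)
    winners: dict[str, tuple[str, float]] = {}
    for cid, seq in candidate_seqs.items():
        scores = {
            mid: _score_against_profile(seq, prof, alphabet)
            for mid, prof in profiles.items()
        }
        best_mid = max(scores, key=scores.get)
        best = scores[best_mid]
        thr = score_threshold
        if thr is None:
            null = []
            chars = list(seq)
            for _ in range(n_shuffles):
                rng.shuffle(chars)
                null.append(
                    _score_against_profile(
                        "".join(chars), profiles[best_mid], alphabet
                    )
                )
            thr = float(np.mean(null) + null_sd_factor * np.std(null))
        if best < thr:
            continue
        if best_mid in winners:
            prev_cid, prev_score = winners[best_mid]
            if best > prev_score:
                warnings.warn(
                    f"marker {best_mid}: candidate {prev_cid} "
                    f"(score {prev_score:.1f}) displaced by {cid} "
                    f"({best:.1f})",
                    stacklevel=2,
                )
                winners[best_mid] = (cid, best)
            else:
                warnings.warn(
                    f"marker {best_mid}: candidate {cid} (score {best:.1f}) "
                    f"lost to {prev_cid} ({prev_score:.1f})",
                    stacklevel=2,
                )
        else:
            winners[best_mid] = (cid, best)
    return winners


# ---------------------------------------------------------------------------
# trimming and exclusion filters
# ---------------------------------------------------------------------------


def trim_alignment(aln: MarkerAlignment, max_gap_fraction: float = 0.9) -> MarkerAlignment:
    """Drop columns whose gap fraction exceeds `max_gap_fraction`.

    Kept-column source coordinates (0-based) are recorded on the result.
    """
    if not (0.0 <= max_gap_fraction <= 1.0):
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    if not aln.rows:
        return aln
    mat = np.array([list(s) for s in aln.rows.values()])
    gap_frac = (mat == GAP).mean(axis=0)
    keep = np.flatnonzero(gap_frac <= max_gap_fraction)
    rows = {t: "".join(s[i] for i in keep) for t, s in aln.rows.items()}
    return MarkerAlignment(
        marker_id=aln.marker_id, rows=rows, kept_columns=[int(i) for i in keep]
    )


def find_identical_sequence_markers(aln: MarkerAlignment) -> list[list[str]]:
    """Groups of >= 2 taxa whose (trimmed) rows are byte-identical."""
    by_seq: dict[str, list[str]] = {}
    for taxon in sorted(aln.rows):
        by_seq.setdefault(aln.rows[taxon], []).append(taxon)
    return [grp for grp in by_seq.values() if len(grp) >= 2]


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------


def occupancy_matrix(
    markers: Sequence[MarkerAlignment], taxon_universe: Sequence[str] | None = None
) -> pd.DataFrame:
    """Boolean markers x taxa presence grid (a taxon is present when it has
    a row containing at least one non-gap character)."""
    if taxon_universe is None:
        taxon_universe = sorted({t for m in markers for t in m.rows})
    data = {
        m.marker_id: [
            t in m.rows and any(c != GAP for c in m.rows[t])
            for t in taxon_universe
        ]
        for m in markers
    }
    return pd.DataFrame(data, index=list(taxon_universe)).T


def occupancy_stats(occ: pd.DataFrame, flag_threshold: float = 0.8):
    """Per-marker taxon fractions and per-taxon marker fractions.

    Returns (marker_frac, taxon_frac, flagged_markers, flagged_taxa);
    entities strictly below `flag_threshold` are flagged.
    """
    marker_frac = occ.mean(axis=1)
    taxon_frac = occ.mean(axis=0)
    flagged_markers = list(marker_frac.index[marker_frac < flag_threshold])
    flagged_taxa = list(taxon_frac.index[taxon_frac < flag_threshold])
    return marker_frac, taxon_frac, flagged_markers, flagged_taxa


def broad_distribution_filter(
    occ: pd.DataFrame,
    required_groups: Mapping[str, Iterable[str]],
    anchor_taxon: str,
) -> list[str]:
    """Markers present in the anchor taxon and in >= 1 taxon of every
    required group."""
    all_taxa = set(occ.columns)
    if anchor_taxon not in all_taxa:
        raise ValueError(f"anchor taxon {anchor_taxon!r} not in occupancy grid")
    groups = {g: list(taxa) for g, taxa in required_groups.items()}
    for g, taxa in groups.items():
        unknown = set(taxa) - all_taxa
        if unknown:
            raise ValueError(f"group {g!r} has unknown taxa: {sorted(unknown)}")
    seen: set[str] = set()
    for g, taxa in groups.items():
        overlap = seen & set(taxa)
        if overlap:
            raise ValueError(f"groups are not disjoint: {sorted(overlap)}")
        seen |= set(taxa)
    kept = []
    for marker in occ.index:
        row = occ.loc[marker]
        if not row[anchor_taxon]:
            continue
        if all(row[taxa].any() for taxa in groups.values()):
            kept.append(marker)
    return kept


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------


def concatenate(
    markers: Sequence[MarkerAlignment], taxon_universe: Sequence[str] | None = None
) -> SuperMatrix:
    """Concatenate markers into a supermatrix, gap-filling absent taxa.

    The partition table is 1-based inclusive and tiles [1, total_width]
    in the given marker order.
    """
    ids = [m.marker_id for m in markers]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate marker ids in concatenation")
    if taxon_universe is None:
        taxon_universe = sorted({t for m in markers for t in m.rows})
    parts: list[tuple[str, int, int]] = []
    chunks: dict[str, list[str]] = {t: [] for t in taxon_universe}
    cursor = 1
    for m in markers:
        w = m.n_sites
        parts.append((m.marker_id, cursor, cursor + w - 1))
        cursor += w
        for t in taxon_universe:
            chunks[t].append(m.rows.get(t, GAP * w))
    rows = {t: "".join(chunks[t]) for t in taxon_universe}
    return SuperMatrix(rows=rows, partitions=parts)


def write_partition_file(
    sm: SuperMatrix, path: str, model_name: str = "LG"
) -> None:
    """'MODEL, name = start-end' partition dialect."""
    with open(path, "w") as fh:
        for name, start, end in sm.partitions:
            fh.write(f"{model_name}, {name} = {start}-{end}\n")


def read_partition_file(path: str) -> list[tuple[str, int, int]]:
    parts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            _, rhs = line.split(",", 1)
            name, rng = rhs.split("=")
            start, end = rng.strip().split("-")
            parts.append((name.strip(), int(start), int(end)))
    return parts
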