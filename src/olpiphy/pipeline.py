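"""End-to-end orchestration: synthesize -> bin -> markers -> trees -> signal.

Every stochastic stage derives its seed deterministically from the global
seed plus the stage name, so a run is a pure function of (config, seed).
Intermediates are persisted as plain text (FASTA / Newick / TSV) and a
run report records entity counts per stage plus a config hash.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compbin, markerset, signal, synthdata, treekit

log = logging.getLogger("olpiphy")

__all__ = [
    "RunConfig",
    "RunReport",
    "derive_seed",
    "make_binning_scenario",
    "run_end_to_end",
    "summarize_reduction",
]


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    """Tunables of a full synthetic run (see docs/methods.md for units)."""

    seed: int = 0
    # metagenome
    n_sources: int = 3
    min_source_tv: float = 0.3
    n_contigs: int = 1000
    genome_length: int = 2_000_000
    length_mu: float = 8.0
    length_sigma: float = 0.6
    target_proportion: float = 0.45
    # binning
    binning: compbin.BinningConfig = field(default_factory=compbin.BinningConfig)
    # markers
    tau: float = 1.0
    n_genes: int = 60
    sites_per_gene: int = 120
    occupancy: float = 0.95
    gamma_shape: float = 1.0
    rate_sigma: float = 0.5
    subst_scale: float = 0.3
    # signal
    n_quartets: int = 100
    bootstrap_replicates: int = 60

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        bin_raw = raw.pop("binning", {})
        cfg = cls(**raw)
        if bin_raw:
            cfg.binning = compbin.BinningConfig(**bin_raw)
        return cfg

    def hash(self) -> str:
        blob = json.dumps(
            {**asdict(self), "binning": asdict(self.binning)}, sort_keys=True
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    counts: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "counts": self.counts,
                    "metrics": self.metrics,
                },
                fh,
                indent=2,
                sort_keys=True,
            )


def make_binning_scenario(config: RunConfig):
    """Synthetic metagenome with everything binning needs.

    Returns a dict with transcriptome contigs, genome contigs, truth
    tables, seed ids, spike reference genomes, and the rescue reference
    sets.  The target-reference set for the similarity rescue is a
    partial (40%) sample of the target genome — the stand-in for the
    organism's known coding sequence — while the contaminant references
    are the contaminant genomes themselves, the stand-in for a public
    database containing the contaminating organisms.
    """
    seed = derive_seed(config.seed, "metagenome")
    rng = np.random.default_rng(seed)
    sources = synthdata.make_divergent_sources(
        config.n_sources, seed, min_tv=config.min_source_tv
    )
    law = synthdata.LengthLaw(mu=config.length_mu, sigma=config.length_sigma)
    other = (1.0 - config.target_proportion) / (config.n_sources - 1)
    props = [config.target_proportion] + [other] * (config.n_sources - 1)
    gspec = synthdata.MixtureSpec(
        sources=sources,
        genome_lengths=[config.genome_length] * config.n_sources,
        contig_length_law=law,
        proportions=props,
        target_index=0,
        n_contigs=config.n_contigs,
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    genome_contigs, genome_truth = synthdata.make_metagenome_mixture(gspec)

    # transcriptome: shorter contigs, same sources
    tlaw = synthdata.LengthLaw(mu=7.4, sigma=0.5, min_len=300, max_len=20_000)
    tspec = synthdata.MixtureSpec(
        sources=sources,
        genome_lengths=[config.genome_length // 4] * config.n_sources,
        contig_length_law=tlaw,
        proportions=props,
        target_index=0,
        n_contigs=max(200, config.n_contigs // 3),
        seed=int(rng.integers(1, 2**31 - 1)),
    )
    tr_contigs, tr_truth = synthdata.make_metagenome_mixture(tspec)
    # database-annotated seeds: a random 40% of the target transcriptome
    tgt_tr = [c.id for c in tr_contigs if c.is_target]
    n_seed = max(5, int(0.4 * len(tgt_tr)))
    seed_ids = list(rng.choice(tgt_tr, size=min(n_seed, len(tgt_tr)), replace=False))

    # spikes: fresh genomes from the non-target sources
    spikes = {
        f"spike_{src.name}": synthdata.simulate_source_genome(
            src, 120_000, seed=int(rng.integers(1, 2**31 - 1))
        )
        for src in sources[1:]
    }

    # rescue references
    target_genome = "".join(
        c.seq for c in genome_contigs if c.is_target
    )
    n_chunk = max(1, len(target_genome) // 5000)
    starts = rng.choice(
        max(1, len(target_genome) - 5000), size=max(1, int(0.4 * n_chunk)),
        replace=False,
    )
    target_refs = {
        f"target_ref{i}": target_genome[s : s + 5000]
        for i, s in enumerate(sorted(starts))
    }
    contam_refs = {}
    for src in sources[1:]:
        contam_refs[f"db_{src.name}"] = "".join(
            c.seq for c in genome_contigs if c.source == src.name
        )
    return {
        "sources": sources,
        "genome_contigs": genome_contigs,
        "genome_truth": genome_truth,
        "transcriptome_contigs": tr_contigs,
        "transcriptome_truth": tr_truth,
        "seed_ids": seed_ids,
        "spike_genomes": spikes,
        "target_refs": target_refs,
        "contaminant_refs": contam_refs,
    }


def _write_contigs(contigs, path: Path) -> None:
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n{c.seq}\n")


def run_end_to_end(config: RunConfig, out_dir: str | Path) -> RunReport:
    """Full synthetic workflow; writes intermediates under `out_dir`."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.hash(), seed=config.seed)

    # ---- binning ---------------------------------------------------------
    scen = make_binning_scenario(config)
    bin_cfg = config.binning
    bin_cfg.seed = derive_seed(config.seed, "binning")
    working, bin_report = compbin.binning_pipeline(
        scen["transcriptome_contigs"],
        scen["genome_contigs"],
        scen["spike_genomes"],
        scen["target_refs"],
        scen["contaminant_refs"],
        bin_cfg,
        seed_ids=scen["seed_ids"],
    )
    _write_contigs(scen["genome_contigs"], out / "genome_raw.fasta")
    _write_contigs(working, out / "working_assembly.fasta")
    scen["genome_truth"].to_csv(out / "genome_truth.tsv", sep="\t")
    bin_report.to_frame().to_csv(out / "binning_report.tsv", sep="\t", index=False)
    truth = scen["genome_truth"]
    kept = {c.id for c in working}
    tgt = set(truth.index[truth["is_target"]])
    recall = len(kept & tgt) / len(tgt) if tgt else float("nan")
    precision = len(kept & tgt) / len(kept) if kept else float("nan")
    report.counts["genome_contigs_raw"] = len(scen["genome_contigs"])
    report.counts["working_assembly"] = len(working)
    report.metrics["binning_recall"] = recall
    report.metrics["binning_precision"] = precision
    red = summarize_reduction(
        len(scen["genome_contigs"]),
        sum(len(c.seq) for c in scen["genome_contigs"]),
        len(working),
        sum(len(c.seq) for c in working),
    )
    report.metrics.update(red)
    log.info("binning: recall %.3f precision %.3f", recall, precision)

    # ---- markers + supermatrix ------------------------------------------
    nwk, groups = synthdata.four_group_species_tree(config.tau, n_per_group=2)
    cspec = synthdata.CoalescentSpec(
        species_newick=nwk,
        n_genes=config.n_genes,
        sites_per_gene=config.sites_per_gene,
        rate_sigma=config.rate_sigma,
        gamma_shape=config.gamma_shape,
        occupancy=config.occupancy,
        subst_scale=config.subst_scale,
        seed=derive_seed(config.seed, "markers"),
    )
    sim = synthdata.simulate_marker_dataset(cspec)
    usable = [a for a in sim.alignments if len(a.rows) >= 4]
    sm = markerset.concatenate(usable)
    markerset.write_fasta_alignment(sm, out / "supermatrix.fasta")
    markerset.write_partition_file(sm, out / "partitions.txt")
    with open(out / "gene_trees.nwk", "w") as fh:
        for t in sim.gene_trees:
            fh.write(treekit.write_tree(t) + "\n")
    report.counts["markers_simulated"] = len(sim.alignments)
    report.counts["markers_usable"] = len(usable)
    report.counts["supermatrix_sites"] = sm.n_sites

    # ---- trees -----------------------------------------------------------
    model = treekit.SubstModel(n_states=4, gamma_shape=config.gamma_shape)
    boot = treekit.bootstrap_supports(
        sm.rows,
        model,
        n_replicates=config.bootstrap_replicates,
        seed=derive_seed(config.seed, "bootstrap"),
    )
    treekit.write_tree(boot, str(out / "concat_tree.nwk"))
    focal_side = set(groups["G1"]) | set(groups["G2"])
    sup = treekit.support_of_bipartition(boot, focal_side)
    report.metrics["focal_support"] = float("nan") if sup is None else sup

    # ---- signal ----------------------------------------------------------
    qmap = signal.likelihood_mapping(
        sm,
        groups,
        n_quartets=config.n_quartets,
        model=model,
        seed=derive_seed(config.seed, "quartetmap"),
    )
    pd.DataFrame(
        {
            "region": ["corner1", "corner2", "corner3", "edge12", "edge13",
                        "edge23", "center"],
            "fraction": qmap.fractions,
        }
    ).to_csv(out / "quartet_map.tsv", sep="\t", index=False)
    report.metrics["quartet_corner1"] = float(qmap.corners[0])

    counts = signal.quartet_counts_around_branch(
        sim.gene_trees,
        groups=[set(groups[g]) for g in ("G1", "G2", "G3", "G4")],
        collapse_threshold=None,
        seed=derive_seed(config.seed, "polytomy"),
    )
    poly = signal.polytomy_test(counts)
    with open(out / "polytomy.tsv", "w") as fh:
        fh.write("n1\tn2\tn3\tchi2\tp\n")
        fh.write(
            f"{counts[0]}\t{counts[1]}\t{counts[2]}\t{poly.chi2:.4f}\t"
            f"{poly.pvalue:.4g}\n"
        )
    report.metrics["polytomy_p"] = poly.pvalue

    report.to_json(out / "run_report.json")
    return report


def summarize_reduction(
    raw_contigs: int, raw_bases: int, working_contigs: int, working_bases: int
) -> dict[str, float]:
    """Working/raw assembly reduction ratios (by count and by bases)."""
    if raw_contigs <= 0 or raw_bases <= 0:
        raise ValueError("raw assembly must be non-empty")
    return {
        "reduction_ratio_contigs": working_contigs / raw_contigs,
        "reduction_ratio_bases": working_bases / raw_bases,
    }
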