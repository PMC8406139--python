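"""End-to-end orchestration: mine -> trees -> clade logic -> ANI -> report.

Given a panel of annotated genomes and a role query set, the pipeline mines
every genome for cassettes, builds a diversity tree from the polyyne-family
calls' second desaturase (the protein the diversity phylogeny of polyyne
producers is anchored on), tests whether the polyyne producers form a
monophyletic clade on a companion anchor-desaturase tree spanning all
cassette-positive genomes, tabulates clade composition, and delimits
species by 95% ANI.  Outputs are deterministic given the configured seed
and invariant to the order genomes are supplied in.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .ani import ani_matrix, species_clusters, write_ani_tsv
from .cassette_mining import (CassetteCall, MiningConfig, POLYYNE_FAMILY,
                              mine_genome, write_calls_tsv)
from .io_formats import Genome, attach_translations, read_fasta, read_gff, Contig
from .io_formats import write_newick
from .phylogenetics import (bootstrap_support, clade_composition,
                            is_monophyletic, CompositionTable)
from .synthetic_data import RoleQuerySet

__all__ = ["PipelineConfig", "RunReport", "run_pipeline", "read_panel", "write_report"]

log = logging.getLogger("polyprospect")


@dataclass(frozen=True)
class PipelineConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    distance_model: str = "poisson"
    bootstrap_reps: int = 100
    ani_threshold: float = 95.0
    ani_frag_len: int = 1000
    tree_role: str = "DES_2"        # the diversity tree's anchor protein
    monophyly_role: str = "DES_B"   # companion tree spanning all calls
    seed: int = 0

    def digest(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "mining"}
        m = asdict(self.mining)
        m.pop("scheme", None)
        payload["mining"] = m
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """Everything one pipeline run produced, traceable to its inputs."""

    calls: dict[str, list[CassetteCall]]
    tree_sequences: dict[str, str]            # genome_id -> tree_role protein
    tree: object | None                       # DES_2 diversity tree (supports)
    monophyly_tree: object | None             # DES_B tree over all calls
    polyyne_genomes: list[str]
    polyyne_monophyletic: bool | None
    composition: CompositionTable | None
    ani: dict
    clusters: list[list[str]]
    manifest: dict


def read_panel(path) -> list[tuple[str, Genome, str]]:
    """Load a panel TSV: genome_id, fasta, gff, optional group label."""
    entries = []
    base = Path(path).parent
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"panel row needs >=3 columns: {line!r}")
            gid, fasta, gff = parts[:3]
            group = parts[3] if len(parts) > 3 else ""
            contigs = [Contig(cid, seq) for cid, seq in read_fasta(base / fasta)]
            genome = Genome(gid, contigs)
            read_gff(base / gff, genome)
            attach_translations(genome)
            entries.append((gid, genome, group))
    return entries


def _role_gene_protein(genome: Genome, call: CassetteCall, role: str) -> str | None:
    gene_id = call.roles.get(role)
    if gene_id is None:
        return None
    return genome.feature(gene_id).protein


def run_pipeline(config: PipelineConfig, panel, role_queries: RoleQuerySet,
                 outdir=None) -> RunReport:
    """Run all stages over ``panel`` = iterable of (genome_id, Genome, group).

    Fewer than 3 tree sequences skips the tree stages with a warning while
    mining/ANI results are still produced.
    """
    panel = sorted(panel, key=lambda e: e[0])  # order-invariance
    genomes = {gid: g for gid, g, _ in panel}
    groups = {gid: grp for gid, _, grp in panel}

    # --- stage 1: cassette mining -------------------------------------
    calls: dict[str, list[CassetteCall]] = {}
    for gid, genome, _ in panel:
        calls[gid] = mine_genome(genome, role_queries, config.mining)
        log.info("mined %s: %s", gid,
                 [c.classification for c in calls[gid]] or "no cassette")

    def best_call(gid: str, family=None) -> CassetteCall | None:
        for c in calls[gid]:
            if family is None or c.classification in family:
                return c
        return None

    polyyne_genomes = sorted(
        gid for gid in genomes if best_call(gid, POLYYNE_FAMILY) is not None)

    # --- stage 2: trees -----------------------------------------------
    tree_seqs: dict[str, str] = {}
    for gid in polyyne_genomes:
        prot = _role_gene_protein(genomes[gid], best_call(gid, POLYYNE_FAMILY),
                                  config.tree_role)
        if prot:
            tree_seqs[gid] = prot
    tree = None
    if len(tree_seqs) >= 3:
        tree = bootstrap_support(sorted(tree_seqs.items()),
                                 n_reps=config.bootstrap_reps,
                                 seed=config.seed, model=config.distance_model)
    else:
        log.warning("tree stage skipped: %d %s sequences (<3)",
                    len(tree_seqs), config.tree_role)

    mono_seqs: dict[str, str] = {}
    for gid in genomes:
        call = best_call(gid)
        if call is None or call.classification == "none":
            continue
        prot = _role_gene_protein(genomes[gid], call, config.monophyly_role)
        if prot:
            mono_seqs[gid] = prot
    monophyly_tree = None
    verdict: bool | None = None
    if len(mono_seqs) >= 3 and polyyne_genomes:
        monophyly_tree = bootstrap_support(sorted(mono_seqs.items()),
                                           n_reps=config.bootstrap_reps,
                                           seed=config.seed,
                                           model=config.distance_model)
        in_tree = [g for g in polyyne_genomes if g in mono_seqs]
        if 0 < len(in_tree) < len(mono_seqs):
            verdict = is_monophyletic(monophyly_tree, in_tree)
        elif in_tree:
            verdict = True  # every tip is a polyyne producer
    else:
        log.warning("monophyly stage skipped: %d cassette sequences (<3)",
                    len(mono_seqs))

    # --- stage 3: composition -----------------------------------------
    composition = None
    if polyyne_genomes:
        labels = {gid: (groups.get(gid) or
                        (best_call(gid, POLYYNE_FAMILY).classification))
                  for gid in polyyne_genomes}
        composition = clade_composition(labels, polyyne_genomes)

    # --- stage 4: ANI species clusters --------------------------------
    pair_ani = ani_matrix(genomes.values(), config.ani_frag_len)
    clusters = species_clusters(genomes.values(), config.ani_threshold,
                                config.ani_frag_len, pair_ani)

    manifest = {
        "polyprospect_version": __version__,
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_genomes": len(genomes),
        "genome_ids": sorted(genomes),
        "n_polyyne_genomes": len(polyyne_genomes),
        "polyyne_monophyletic": verdict,
        "n_species_clusters": len(clusters),
    }
    report = RunReport(calls, tree_seqs, tree, monophyly_tree, polyyne_genomes,
                       verdict, composition, pair_ani, clusters, manifest)
    if outdir is not None:
        write_report(report, outdir)
    return report


def write_report(report: RunReport, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_calls_tsv([c for gid in sorted(report.calls)
                     for c in report.calls[gid]], outdir / "calls.tsv")
    if report.tree is not None:
        (outdir / "tree.nwk").write_text(write_newick(report.tree) + "\n")
    if report.monophyly_tree is not None:
        (outdir / "cassette_tree.nwk").write_text(
            write_newick(report.monophyly_tree) + "\n")
    if report.composition is not None:
        report.composition.to_tsv(outdir / "composition.tsv")
    write_ani_tsv(report.ani, outdir / "ani_matrix.tsv")
    with open(outdir / "clusters.tsv", "w") as fh:
        fh.write("cluster_id\tgenome_id\n")
        for cluster in report.clusters:
            for gid in cluster:
                fh.write(f"{cluster[0]}\t{gid}\n")
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, sort_keys=True) + "\n")
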