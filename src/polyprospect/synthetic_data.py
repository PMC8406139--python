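"""Synthetic genomes, protein families and genome pairs with known truth.

This module is the stand-in for the public assembly collections the mining
procedure is normally run on.  It plants alkyne/polyyne gene cassettes of
each observed variant class into random multi-contig genomes, emits matching
FASTA/GFF3/truth files, and produces protein homologs and genome pairs at
controlled divergence so that every downstream threshold can be exercised
against construction-time ground truth.

Role proteins are random sequences (pairwise identity between roles ~6%,
far below the 30% ceiling the generator promises), reverse-translated with
the bacterial code so that annotated CDS translation reproduces the planted
protein exactly.  All randomness flows from explicit integer seeds; there is
no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Data import CodonTable

from .io_formats import Contig, GeneFeature, Genome, write_fasta, write_gff

__all__ = [
    "ROLE_LENGTHS",
    "ROLES",
    "TRIAD",
    "POLYYNE_EXTRAS",
    "CassetteSpec",
    "TruthLabel",
    "RoleQuerySet",
    "make_role_queries",
    "mutate_protein",
    "plant_cassette",
    "genome_pair",
    "make_divergent_families",
    "make_panel",
    "write_genome",
    "write_role_queries",
]

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_NT = np.array(list("ACGT"))

#: typical lengths (aa) of each cassette role
ROLE_LENGTHS = {
    "FAAL": 600,   # fatty acyl-AMP ligase (JamA-like)
    "DES_B": 350,  # anchor desaturase (JamB/CcnK-like)
    "ACP": 80,     # acyl carrier protein (JamC-like)
    "DES_2": 350,  # polyyne-specific desaturase (CnnN/PgnH-like)
    "DES_3": 350,  # polyyne-specific desaturase
    "TE": 250,     # thioesterase
    "RUB": 60,     # rubredoxin
    "P450": 400,   # cytochrome P450 (actinobacterial variant)
}
ROLES = tuple(ROLE_LENGTHS)
TRIAD = ("FAAL", "DES_B", "ACP")
POLYYNE_EXTRAS = ("DES_2", "DES_3", "TE", "RUB")

#: gene content planted for each cassette variant, in cluster order
VARIANT_ROLES = {
    "polyyne_full": ("FAAL", "DES_B", "ACP", "DES_2", "DES_3", "TE", "RUB"),
    "alkyne_only": TRIAD,
    "polyyne_p450": ("FAAL", "DES_B", "ACP", "DES_2", "DES_3", "P450"),
    "polyyne_norub": ("FAAL", "DES_B", "ACP", "DES_2", "DES_3", "TE"),
    "split": ("FAAL", "DES_B", "ACP", "DES_2", "DES_3", "TE", "RUB"),
    "none": (),
}

#: classification the miner must produce for each variant
VARIANT_EXPECTED = {
    "polyyne_full": "polyyne",
    "alkyne_only": "alkyne",
    "polyyne_p450": "polyyne_p450_variant",
    "polyyne_norub": "polyyne_norub",
    "split": "polyyne_split",
    "none": "none",
}


@dataclass(frozen=True)
class CassetteSpec:
    """What to plant: variant class, homolog divergence and layout."""

    variant: str
    identity: float = 0.80          # planted-gene identity to the role query
    intergenic_bp: int = 150
    strand: str = "+"               # single strand for the whole cassette
    split_roles: tuple[str, ...] = ("TE", "RUB")  # far-contig roles (variant="split")
    n_decoys: int = 10

    def __post_init__(self):
        if self.variant not in VARIANT_ROLES:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.variant == "split" and not self.split_roles:
            raise ValueError("split variant needs at least one far-contig role")

    @property
    def roles(self) -> tuple[str, ...]:
        return VARIANT_ROLES[self.variant]


@dataclass(frozen=True)
class TruthLabel:
    genome_id: str
    expected: str
    role_genes: dict[str, str]  # planted role -> gene_id


@dataclass(frozen=True)
class RoleQuerySet:
    """Reference protein per role plus unrelated decoy queries."""

    roles: dict[str, str]
    decoys: dict[str, str] = field(default_factory=dict)

    def items(self):
        return {**self.roles, **self.decoys}.items()


# ---------------------------------------------------------------------------
# proteins
# ---------------------------------------------------------------------------

def _random_protein(rng: np.random.Generator, length: int) -> str:
    aa = rng.choice(list(AA20), size=length)
    aa[0] = "M"
    return "".join(aa)


def make_role_queries(seed: int, n_decoys: int = 5) -> RoleQuerySet:
    """One reference protein per role plus ``n_decoys`` unrelated proteins."""
    rng = np.random.default_rng([int(seed), 101])
    roles = {role: _random_protein(rng, n) for role, n in ROLE_LENGTHS.items()}
    decoys = {
        f"decoy{i+1}": _random_protein(rng, int(rng.integers(150, 401)))
        for i in range(n_decoys)
    }
    return RoleQuerySet(roles, decoys)


def mutate_protein(protein: str, target_identity: float, seed: int) -> str:
    """Substitute positions so the output matches *protein* at ~target_identity.

    Substitutions are drawn uniformly from the 19 alternatives and never
    restore the original residue, so realized identity is exactly
    ``1 - round(L*(1-target))/L`` (no indels).
    """
    if target_identity <= 0:
        raise ValueError("target_identity must be positive")
    if target_identity > 1:
        raise ValueError("target_identity cannot exceed 1")
    rng = np.random.default_rng([int(seed), 211])
    n = len(protein)
    n_sub = int(round(n * (1.0 - target_identity)))
    if n_sub == 0:
        return protein
    pos = rng.choice(n, size=n_sub, replace=False)
    out = list(protein)
    for p in pos:
        alternatives = [a for a in AA20 if a != out[p]]
        out[p] = alternatives[int(rng.integers(len(alternatives)))]
    return "".join(out)


# ---------------------------------------------------------------------------
# reverse translation
# ---------------------------------------------------------------------------

def _codon_choices() -> dict[str, list[str]]:
    table = CodonTable.unambiguous_dna_by_id[11]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        by_aa.setdefault(aa, []).append(codon)
    return by_aa

_CODONS = _codon_choices()
_STOPS = ("TAA", "TGA", "TAG")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_translate(protein: str, rng: np.random.Generator) -> str:
    """Protein -> CDS (random synonymous codons, bacterial code, TAA stop)."""
    codons = [
        _CODONS[aa][int(rng.integers(len(_CODONS[aa])))] for aa in protein
    ]
    codons.append("TAA")
    return "".join(codons)


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NT, size=length))


# ---------------------------------------------------------------------------
# cassette planting
# ---------------------------------------------------------------------------

def plant_cassette(spec: CassetteSpec, genome_size: int = 120_000,
                   n_contigs: int = 2, seed: int = 0,
                   queries: RoleQuerySet | None = None,
                   genome_id: str | None = None,
                   role_proteins: dict[str, str] | None = None,
                   ) -> tuple[Genome, TruthLabel]:
    """Build a synthetic genome with the cassette variant of *spec* planted.

    Role genes are placed contiguously (well under the 20-kbp cassette span
    of characterised polyyne BGCs); decoy genes are scattered elsewhere.
    For ``variant="split"`` the cassette is cut at a contig boundary: the
    ``split_roles`` land at the start of the second contig.  Supplying
    ``role_proteins`` overrides the per-genome homolog generation (used by
    the panel builder to impose clade structure).
    """
    rng = np.random.default_rng([int(seed), 307])
    queries = queries or make_role_queries(seed=0)
    gid = genome_id or f"syn_{spec.variant}_s{seed}"
    contig_len = genome_size // n_contigs
    if contig_len < 2000:
        raise ValueError("contigs too short to hold genes")

    # planted proteins: controlled-divergence homologs of the role queries
    proteins = {}
    for k, role in enumerate(spec.roles):
        if role_proteins and role in role_proteins:
            proteins[role] = role_proteins[role]
        else:
            proteins[role] = mutate_protein(
                queries.roles[role], spec.identity, int(rng.integers(2**31)))

    if spec.variant == "split":
        near = [r for r in spec.roles if r not in spec.split_roles]
        far = [r for r in spec.roles if r in spec.split_roles]
        if not far:
            raise ValueError("split variant: split_roles not in cassette")
        layouts = [(0, near, "end"), (1, far, "start")]
        if n_contigs < 2:
            raise ValueError("split variant needs at least 2 contigs")
    elif spec.roles:
        layouts = [(0, list(spec.roles), "middle")]
    else:
        layouts = []

    contig_seqs = [list(_random_dna(rng, contig_len)) for _ in range(n_contigs)]
    features: list[GeneFeature] = []
    occupied: dict[int, list[tuple[int, int]]] = {i: [] for i in range(n_contigs)}
    role_genes: dict[str, str] = {}

    for ci, roles_here, where in layouts:
        genes_nt = [reverse_translate(proteins[r], rng) for r in roles_here]
        block_len = sum(len(g) for g in genes_nt) + spec.intergenic_bp * len(genes_nt)
        if block_len > contig_len:
            raise ValueError(
                f"cassette block ({block_len} bp) exceeds contig length {contig_len}")
        if where == "end":
            offset = contig_len - block_len
        elif where == "start":
            offset = 0
        else:
            offset = int(rng.integers(contig_len // 4, contig_len // 2))
        pos = offset
        for role, gene_nt in zip(roles_here, genes_nt):
            start, end = pos + 1, pos + len(gene_nt)  # 1-based inclusive
            placed = gene_nt if spec.strand == "+" else gene_nt.translate(_COMPLEMENT)[::-1]
            contig_seqs[ci][start - 1 : end] = list(placed)
            gene_id = f"{gid}_{role}"
            features.append(GeneFeature(gene_id, f"{gid}_c{ci+1}", start, end,
                                        spec.strand, proteins[role]))
            role_genes[role] = gene_id
            occupied[ci].append((start, end))
            pos = end + spec.intergenic_bp
        occupied[ci].append((offset + 1, pos))

    # scatter decoy genes in unoccupied background
    for d in range(spec.n_decoys):
        ci = int(rng.integers(n_contigs))
        prot = _random_protein(rng, int(rng.integers(150, 401)))
        gene_nt = reverse_translate(prot, rng)
        span = _free_position(rng, contig_len, len(gene_nt), occupied[ci])
        if span is None:
            continue
        start, end = span
        contig_seqs[ci][start - 1 : end] = list(gene_nt)
        occupied[ci].append((start, end))
        features.append(GeneFeature(f"{gid}_decoy{d+1}", f"{gid}_c{ci+1}",
                                    start, end, "+", prot))

    contigs = [Contig(f"{gid}_c{i+1}", "".join(s)) for i, s in enumerate(contig_seqs)]
    genome = Genome(gid, contigs, features)
    truth = TruthLabel(gid, VARIANT_EXPECTED[spec.variant], role_genes)
    return genome, truth


def _free_position(rng, contig_len, gene_len, occupied, tries: int = 60):
    for _ in range(tries):
        start = int(rng.integers(1, contig_len - gene_len))
        end = start + gene_len - 1
        if all(end < s - 50 or start > e + 50 for s, e in occupied):
            return start, end
    return None


# ---------------------------------------------------------------------------
# genome pairs & panels
# ---------------------------------------------------------------------------

def genome_pair(length: int = 200_000, divergence: float = 0.05,
                seed: int = 0) -> tuple[Genome, Genome]:
    """A genome and a mutated copy with per-site substitution = divergence."""
    if not (0 <= divergence < 0.25):
        raise ValueError("divergence must be in [0, 0.25)")
    rng = np.random.default_rng([int(seed), 401])
    a = rng.choice(_NT, size=length)
    b = _mutate_dna(a, divergence, rng)
    ga = Genome(f"pairA_s{seed}", [Contig(f"pairA_s{seed}_c1", "".join(a))])
    gb = Genome(f"pairB_s{seed}", [Contig(f"pairB_s{seed}_c1", "".join(b))])
    return ga, gb


def _mutate_dna(a: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    b = a.copy()
    mask = rng.random(a.shape[0]) < rate
    idx = np.flatnonzero(mask)
    for i in idx:
        alternatives = [x for x in "ACGT" if x != b[i]]
        b[i] = alternatives[int(rng.integers(3))]
    return b


def _identity_to_rate(pairwise_identity: float) -> float:
    """Per-lineage substitution rate r with (1-r)^2 + r^2/19 = identity."""
    a, b, c = 20.0 / 19.0, -2.0, 1.0 - pairwise_identity
    return (-b - np.sqrt(b * b - 4 * a * c)) / (2 * a)


def make_divergent_families(n_per_clade: int = 5, n_clades: int = 2,
                            length: int = 300, within_identity: float = 0.95,
                            between_identity: float = 0.40, seed: int = 0,
                            ) -> tuple[list[tuple[str, str]], dict[str, str]]:
    """Protein families with clean clade structure for tree/bootstrap tests.

    Returns ``(named sequences, tip -> clade label)``.  Pairwise identity is
    ~``within_identity`` inside a clade and at most ~``between_identity``
    across clades (member mutations push cross-clade identity slightly
    below the target, widening the separation).
    """
    rng = np.random.default_rng([int(seed), 503])
    root = _random_protein(rng, length)
    r_anc = float(_identity_to_rate(between_identity))
    r_mem = float(_identity_to_rate(within_identity))
    seqs: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    for c in range(n_clades):
        anc = mutate_protein(root, 1.0 - r_anc, int(rng.integers(2**31)))
        for m in range(n_per_clade):
            name = f"clade{c+1}_t{m+1}"
            seqs.append((name, mutate_protein(anc, 1.0 - r_mem,
                                              int(rng.integers(2**31)))))
            labels[name] = f"clade{c+1}"
    return seqs, labels


def make_species_panel(n_species: int = 3, per_species: int = 3,
                       length: int = 60_000, within_divergence: float = 0.01,
                       between_divergence: float = 0.15, seed: int = 0,
                       ) -> tuple[list[Genome], dict[str, int]]:
    """Genomes descended from ``n_species`` ancestors, for ANI clustering.

    Each species ancestor sits ~``between_divergence`` from the others
    (half the divergence applied per lineage from a common root); members
    sit ~``within_divergence`` from each other.  Returns the genomes plus
    the genome_id -> species index truth map.
    """
    rng = np.random.default_rng([int(seed), 701])
    root = rng.choice(_NT, size=length)
    genomes: list[Genome] = []
    truth: dict[str, int] = {}
    for s in range(n_species):
        anc = _mutate_dna(root, between_divergence / 2.0, rng)
        for m in range(per_species):
            member = _mutate_dna(anc, within_divergence / 2.0, rng)
            gid = f"sp{s+1}_g{m+1}"
            genomes.append(Genome(gid, [Contig(f"{gid}_c1", "".join(member))]))
            truth[gid] = s
    return genomes, truth


def make_panel(seed: int = 0, n_polyyne: int = 6, n_alkyne: int = 3,
               n_none: int = 3, genome_size: int = 60_000,
               queries: RoleQuerySet | None = None,
               ) -> tuple[list[tuple[Genome, TruthLabel, str]], RoleQuerySet]:
    """A genome panel with clade-structured cassette families.

    Polyyne and alkyne genomes derive their planted role proteins from two
    distinct ancestors (each ~85% identical to the role query, members ~93%
    identical to their ancestor), so cassette-gene trees separate the two
    groups cleanly; "none" genomes carry decoys only.  Returns the panel as
    ``(genome, truth, group)`` triples plus the role query set used.
    """
    rng = np.random.default_rng([int(seed), 601])
    queries = queries or make_role_queries(seed=int(rng.integers(2**31)))
    ancestors = {
        grp: {role: mutate_protein(q, 0.85, int(rng.integers(2**31)))
              for role, q in queries.roles.items()}
        for grp in ("polyyne", "alkyne")
    }
    panel: list[tuple[Genome, TruthLabel, str]] = []
    jobs = ([("polyyne_full", "polyyne")] * n_polyyne
            + [("alkyne_only", "alkyne")] * n_alkyne
            + [("none", "none")] * n_none)
    for i, (variant, grp) in enumerate(jobs):
        spec = CassetteSpec(variant=variant, n_decoys=6)
        role_proteins = None
        if grp in ancestors and VARIANT_ROLES[variant]:
            role_proteins = {
                role: mutate_protein(ancestors[grp][role], 0.93,
                                     int(rng.integers(2**31)))
                for role in VARIANT_ROLES[variant]
            }
        g, t = plant_cassette(
            spec, genome_size=genome_size, n_contigs=1,
            seed=int(rng.integers(2**31)), queries=queries,
            genome_id=f"panel{i+1:02d}_{variant}", role_proteins=role_proteins)
        panel.append((g, t, grp))
    return panel, queries


# ---------------------------------------------------------------------------
# on-disk fixtures
# ---------------------------------------------------------------------------

def write_genome(genome: Genome, truth: TruthLabel | None, outdir) -> dict:
    """Write FASTA + GFF3 (+ truth TSV) for one genome; returns the paths."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / f"{genome.genome_id}.fna"
    gff = outdir / f"{genome.genome_id}.gff3"
    write_fasta([(c.id, c.seq) for c in genome.contigs], fasta)
    write_gff(genome, gff)
    paths = {"fasta": fasta, "gff": gff}
    if truth is not None:
        tsv = outdir / f"{genome.genome_id}.truth.tsv"
        with open(tsv, "w") as fh:
            fh.write("genome_id\texpected\trole\tgene_id\n")
            if truth.role_genes:
                for role, gene in sorted(truth.role_genes.items()):
                    fh.write(f"{truth.genome_id}\t{truth.expected}\t{role}\t{gene}\n")
            else:
                fh.write(f"{truth.genome_id}\t{truth.expected}\t.\t.\n")
        paths["truth"] = tsv
    return paths


def write_role_queries(queries: RoleQuerySet, path) -> None:
    write_fasta(list(queries.items()), path)
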