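"""Readers, writers and core genome containers.

All genomic coordinates in this package are 1-based and inclusive, exactly as
they appear in GFF3.  Nothing converts silently to 0-based half-open
coordinates; slicing into Python strings happens only inside the helpers
defined here.

Supported formats: FASTA (nucleotide and protein, via Biopython), a GFF3
subset carrying ``gene``/``CDS`` rows with ``ID`` attributes, and Newick with
internal-node support labels (via scikit-bio).
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

__all__ = [
    "Contig",
    "GeneFeature",
    "Genome",
    "read_fasta",
    "write_fasta",
    "read_gff",
    "write_gff",
    "read_newick",
    "write_newick",
    "translate_feature",
    "attach_translations",
    "attach_proteins",
    "reverse_complement_genome",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


@dataclass(frozen=True)
class Contig:
    """A single assembly contig: an id and an upper-case nucleotide string."""

    id: str
    seq: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("contig id must be nonempty")
        if len(self.seq) < 1:
            raise ValueError(f"contig {self.id!r}: sequence must be nonempty")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneFeature:
    """A protein-coding gene located on a contig (1-based inclusive span)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein: str | None = None

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id!r}: strand must be '+' or '-'")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id!r}: invalid span {self.start}..{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class Genome:
    """Contigs plus gene features; the unit the cassette miner scans."""

    genome_id: str
    contigs: list[Contig] = field(default_factory=list)
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self):
        self.validate()

    # -- access helpers -------------------------------------------------
    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.id == contig_id:
                return c
        raise KeyError(f"genome {self.genome_id!r}: no contig {contig_id!r}")

    def features_on(self, contig_id: str) -> list[GeneFeature]:
        return sorted(
            (f for f in self.features if f.contig_id == contig_id),
            key=lambda f: (f.start, f.end, f.gene_id),
        )

    def sorted_features(self) -> list[GeneFeature]:
        order = {c.id: i for i, c in enumerate(self.contigs)}
        return sorted(
            self.features,
            key=lambda f: (order[f.contig_id], f.start, f.end, f.gene_id),
        )

    def feature(self, gene_id: str) -> GeneFeature:
        for f in self.features:
            if f.gene_id == gene_id:
                return f
        raise KeyError(f"genome {self.genome_id!r}: no gene {gene_id!r}")

    def proteome(self) -> dict[str, str]:
        """gene_id -> protein for every feature, translating where needed."""
        out: dict[str, str] = {}
        for f in self.sorted_features():
            out[f.gene_id] = f.protein if f.protein is not None else translate_feature(self, f)
        return out

    def validate(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            raise ValueError(f"genome {self.genome_id!r}: duplicate contig ids")
        lengths = {c.id: len(c) for c in self.contigs}
        seen: set[str] = set()
        for f in self.features:
            if f.gene_id in seen:
                raise ValueError(
                    f"genome {self.genome_id!r}: duplicate gene id {f.gene_id!r}"
                )
            seen.add(f.gene_id)
            if f.contig_id not in lengths:
                raise ValueError(
                    f"gene {f.gene_id!r} references unknown contig {f.contig_id!r}"
                )
            if f.end > lengths[f.contig_id]:
                raise ValueError(
                    f"gene {f.gene_id!r}: end {f.end} exceeds contig "
                    f"{f.contig_id!r} length {lengths[f.contig_id]}"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, SEQ) pairs, uppercased, order preserved."""
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append((rec.id, str(rec.seq).upper()))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


# ---------------------------------------------------------------------------
# GFF3 (gene/CDS subset)
# ---------------------------------------------------------------------------

def read_gff(path, genome: Genome) -> Genome:
    """Attach gene/CDS rows from a GFF3 file to *genome* (in place).

    Coordinates stay 1-based inclusive.  Rows on unknown contigs, reversed
    spans, out-of-bounds spans or rows without an ``ID`` attribute are
    rejected with the offending line number.
    """
    lengths = {c.id: len(c) for c in genome.contigs}
    feats: list[GeneFeature] = []
    seen = {f.gene_id for f in genome.features}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
            seqid, _source, ftype, start_s, end_s, _score, strand, _phase, attrs = cols
            if ftype not in ("gene", "CDS"):
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
            if start > end:
                raise ValueError(f"{path}:{lineno}: start {start} > end {end}")
            if seqid not in lengths:
                raise ValueError(f"{path}:{lineno}: unknown contig {seqid!r}")
            if end > lengths[seqid]:
                raise ValueError(
                    f"{path}:{lineno}: end {end} exceeds contig {seqid!r} "
                    f"length {lengths[seqid]}"
                )
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{lineno}: strand must be '+' or '-'")
            gene_id = _gff_attr(attrs, "ID")
            if gene_id is None:
                raise ValueError(f"{path}:{lineno}: missing ID attribute")
            if gene_id in seen:
                raise ValueError(f"{path}:{lineno}: duplicate gene id {gene_id!r}")
            seen.add(gene_id)
            feats.append(GeneFeature(gene_id, seqid, start, end, strand))
    genome.features.extend(feats)
    genome.validate()
    return genome


def _gff_attr(attrs: str, key: str) -> str | None:
    for part in attrs.split(";"):
        part = part.strip()
        if part.startswith(key + "="):
            return part[len(key) + 1 :]
    return None


def write_gff(genome: Genome, path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in genome.contigs:
            fh.write(f"##sequence-region {c.id} 1 {len(c)}\n")
        for f in genome.sorted_features():
            fh.write(
                f"{f.contig_id}\tpolyprospect\tCDS\t{f.start}\t{f.end}\t.\t"
                f"{f.strand}\t0\tID={f.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# Translation & protein attachment
# ---------------------------------------------------------------------------

def translate_feature(genome: Genome, feat: GeneFeature) -> str:
    """Translate a CDS with the bacterial code (table 11).

    The trailing stop is removed; ambiguous codons translate to ``X``.
    """
    contig = genome.contig(feat.contig_id)
    nt = contig.seq[feat.start - 1 : feat.end]
    if feat.strand == "-":
        nt = nt.translate(_COMPLEMENT)[::-1]
    aa = str(Seq(nt).translate(table=11))
    return aa[:-1] if aa.endswith("*") else aa


def attach_translations(genome: Genome) -> Genome:
    """Fill in missing ``protein`` fields by translating each CDS."""
    genome.features = [
        f if f.protein is not None else replace(f, protein=translate_feature(genome, f))
        for f in genome.features
    ]
    return genome


def attach_proteins(genome: Genome, records) -> Genome:
    """Attach proteins from a parallel FASTA keyed by gene_id."""
    by_id = dict(records)
    genome.features = [
        replace(f, protein=by_id[f.gene_id]) if f.gene_id in by_id else f
        for f in genome.features
    ]
    return genome


def reverse_complement_genome(genome: Genome) -> Genome:
    """Mirror every contig and remap features; proteins are unchanged."""
    contigs = [Contig(c.id, c.seq.translate(_COMPLEMENT)[::-1]) for c in genome.contigs]
    lengths = {c.id: len(c) for c in contigs}
    feats = [
        replace(
            f,
            start=lengths[f.contig_id] - f.end + 1,
            end=lengths[f.contig_id] - f.start + 1,
            strand="-" if f.strand == "+" else "+",
        )
        for f in genome.features
    ]
    return Genome(genome.genome_id, contigs, feats)


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(text: str) -> TreeNode:
    """Parse a Newick string; internal labels become integer/float supports."""
    try:
        tree = TreeNode.read(_io.StringIO(text), convert_underscores=False)
    except Exception as exc:  # skbio raises format-specific errors
        raise ValueError(f"Newick parse error: {exc}") from exc
    tree.assign_supports()
    return tree


def write_newick(tree: TreeNode) -> str:
    """Serialise a tree; node supports become internal labels.

    skbio's writer emits the ``support`` attribute as the internal label
    when present; integral supports are normalised to plain integers.
    """
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        support = getattr(node, "support", None)
        if support is not None and float(support) == int(support):
            node.support = int(support)
    buf = _io.StringIO()
    out.write(buf)
    return buf.getvalue().strip()
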