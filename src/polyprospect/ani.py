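"""Fragment-based average nucleotide identity and species clustering.

A desk-scale ANI in the fastANI tradition: the query genome is cut into
consecutive fixed-length fragments, each fragment is mapped to its best
matching region anywhere in the reference (semi-global edit-distance
alignment via edlib), and fragments reaching 70% identity count as mapped.
ANI is the mean identity over mapped fragments.  Species are delimited by
single-linkage clustering at the conventional 95% threshold, using the
larger of the two directional ANIs per genome pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

from .io_formats import Genome

__all__ = ["ANIResult", "fragment_ani", "ani_matrix", "species_clusters"]

MIN_FRAGMENT_IDENTITY = 0.70


@dataclass(frozen=True)
class ANIResult:
    """Directional ANI of query fragments mapped onto a reference genome."""

    query_id: str
    reference_id: str
    ani: float | None          # percentage; None when no fragment maps
    fragments_total: int
    fragments_mapped: int

    @property
    def defined(self) -> bool:
        return self.ani is not None


def _fragments(genome: Genome, frag_len: int) -> list[str]:
    frags = []
    for contig in genome.contigs:
        seq = contig.seq
        for i in range(0, len(seq) - frag_len + 1, frag_len):
            frags.append(seq[i : i + frag_len])
    return frags


def fragment_ani(genome_a: Genome, genome_b: Genome,
                 frag_len: int = 1000) -> ANIResult:
    """ANI of A's fragments against genome B (directional: A -> B)."""
    if frag_len < 100:
        raise ValueError("frag_len must be >= 100")
    if not genome_a.contigs or not genome_b.contigs:
        raise ValueError("both genomes must be nonempty")
    frags = _fragments(genome_a, frag_len)
    if not frags:
        raise ValueError(
            f"genome {genome_a.genome_id!r}: no contig reaches frag_len={frag_len}")
    identities = []
    # distances beyond the mapping floor are irrelevant: bound the search
    k_max = int(frag_len * (1.0 - MIN_FRAGMENT_IDENTITY))
    for frag in frags:
        best = 0.0
        for contig in genome_b.contigs:
            res = edlib.align(frag, contig.seq, mode="HW", task="distance", k=k_max)
            ed = res["editDistance"]
            if ed >= 0:
                best = max(best, 1.0 - ed / frag_len)
        if best >= MIN_FRAGMENT_IDENTITY:
            identities.append(best)
    if not identities:
        return ANIResult(genome_a.genome_id, genome_b.genome_id, None,
                         len(frags), 0)
    ani = 100.0 * sum(identities) / len(identities)
    return ANIResult(genome_a.genome_id, genome_b.genome_id, ani,
                     len(frags), len(identities))


def ani_matrix(genomes, frag_len: int = 1000) -> dict[tuple[str, str], ANIResult]:
    """Both directional ANIs for every genome pair."""
    genomes = sorted(genomes, key=lambda g: g.genome_id)
    out: dict[tuple[str, str], ANIResult] = {}
    for i, a in enumerate(genomes):
        for b in genomes[i + 1 :]:
            out[(a.genome_id, b.genome_id)] = fragment_ani(a, b, frag_len)
            out[(b.genome_id, a.genome_id)] = fragment_ani(b, a, frag_len)
    return out


def species_clusters(genomes, threshold: float = 95.0,
                     frag_len: int = 1000,
                     pair_ani: dict[tuple[str, str], ANIResult] | None = None,
                     ) -> list[list[str]]:
    """Single-linkage species clusters at an ANI threshold.

    An edge joins two genomes when the larger of their directional ANIs
    reaches *threshold*.  Clusters are returned as sorted member lists,
    ordered by their smallest genome id.
    """
    if not (0 < threshold <= 100):
        raise ValueError("threshold must be in (0, 100]")
    ids = sorted(g.genome_id for g in genomes)
    if pair_ani is None:
        pair_ani = ani_matrix(genomes, frag_len)
    parent = {i: i for i in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            vals = [r.ani for r in (pair_ani.get((a, b)), pair_ani.get((b, a)))
                    if r is not None and r.ani is not None]
            if vals and max(vals) >= threshold:
                ra, rb = find(a), find(b)
                if ra != rb:
                    parent[max(ra, rb)] = min(ra, rb)

    clusters: dict[str, list[str]] = {}
    for i in ids:
        clusters.setdefault(find(i), []).append(i)
    return [sorted(v) for _, v in sorted(clusters.items())]


def write_ani_tsv(pair_ani, path) -> None:
    with open(path, "w") as fh:
        fh.write("query\treference\tani\tfragments_mapped\tfragments_total\n")
        for (a, b), r in sorted(pair_ani.items()):
            ani = f"{r.ani:.3f}" if r.ani is not None else "NA"
            fh.write(f"{a}\t{b}\t{ani}\t{r.fragments_mapped}\t{r.fragments_total}\n")
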