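# Methods

## Scope and model

`polyprospect` implements the computational core of a phylogeny-guided
screen for alkyne/polyyne biosynthetic gene clusters (BGCs): homology-based
cassette detection with colocalization rules, distance-based diversity
phylogenetics, ANI species delineation, and exact-mass verification of
candidate metabolite formulas. The screen's external stages — assembly,
annotation, InterPro domain prediction, MAFFT alignment, maximum-likelihood
tree inference, fastANI/pyANI — are out of scope; where the original
workflow used them, this package defines explicit desk-scale stand-ins
whose behaviour is fixed by the conventions below and exercised against
synthetic genomes with construction-time truth.

## Homology search

Optimal local alignment (Smith–Waterman with Gotoh's affine-gap
recurrences, numba kernels) under BLOSUM62; a gap of length k costs
`11 + k` (BLAST's 11/1 convention). `X` scores 0 against everything.
E-values use the Karlin–Altschul form `E = K·m·n·e^(−λS)` with the
published gapped-BLOSUM62 parameters λ = 0.267, K = 0.041; effective
lengths equal raw lengths and no composition-based adjustment is applied.
Absolute E-values therefore differ from NCBI BLAST bit-for-bit; every
threshold in the miner is calibrated against this same convention, which
is what the property suites assert. Tie-breaks: among equal-scoring end
cells the alignment minimising (target start, query start, length) is
reported, with a fixed diagonal-first traceback preference.

## Cassette mining

Roles: `FAAL`, `DES_B`, `ACP` (the alkyne triad), `DES_2`, `DES_3`, `TE`,
`RUB` (the polyyne extension) and `P450` (the actinobacterial replacement).
Thresholds, all configurable in `MiningConfig`:

| parameter | default | note |
|---|---|---|
| `seed_e_threshold` | 1e−50 | anchor (DES_B-class) hits and FAAL/DES_B roles |
| `desaturase_e_threshold` | 1e−100 | the two polyyne-specific desaturases |
| `accessory_e_threshold` | 1e−20 | TE / RUB / P450; replaces the manual delimitation of these roles with an explicit cutoff |
| `acp_e_threshold` | 1e−20 | see below |
| `window_radius_bp` | 30 000 | flank on *each side* of the anchor |
| `seed_role` | `DES_B` | anchoring on FAAL instead is a config option |

The ACP gets its own cutoff because Karlin–Altschul arithmetic makes
1e−50 unattainable for an ~80-residue protein: a perfect BLOSUM62
self-alignment of 80 aa scores ≈ 432, giving E ≈ 1e−43 against a
10⁶-residue database. Domain-presence evidence for the triad is therefore
mapped to the accessory-class cutoff for this short role.

The 30-kbp flank is symmetric about the anchor: characterized polyyne BGCs
span ~15–25 kbp with the anchor desaturase internal, so a one-sided or
30-kbp-total window would truncate them. Role assignment is greedy,
best-E-first, with each gene consumable by exactly one role, so a single
desaturase cannot satisfy `DES_B`, `DES_2` and `DES_3` simultaneously.
E-values during window assignment use the window's total residue count as
the database size (the screened unit is the extracted fragment);
whole-proteome searches use the proteome residue count.

Classification is a top-down decision table: incomplete triad → `none`;
triad + all four extras → `polyyne`; triad + both desaturases + P450 with
TE and RUB absent → `polyyne_p450_variant`; the same without P450 but with
TE and no RUB → `polyyne_norub`; triad + a *partial* extra set in an
edge-truncated window → split-rescue candidate; otherwise `alkyne`.
Rescue searches the missing roles among genes lying within the window
radius of an end of any *other* contig; if the merged role set completes a
polyyne-family composition the call is upgraded to `polyyne_split` with
the rescue contigs recorded. Candidates that cannot be completed stay
`alkyne` — calls never upgrade on partial evidence.

## Phylogenetics

Distances come from pairwise global alignments (Biopython PairwiseAligner;
BLOSUM62 12/1 for proteins, 5/−4 with 11/1 gaps for nucleotides) rather
than a multiple alignment: p-distance over non-gap columns, optionally
Poisson-corrected (`−ln(1−p)`, proteins) or JC69-corrected
(`−¾ ln(1−4p/3)`, nucleotides), with saturation (p beyond the model
domain) raised as an error. Neighbor joining follows Saitou–Nei with the
Studier–Keppler update; Q-ties resolve toward the lexicographically
smallest taxon pair, and negative branch lengths are clamped to zero with
the deficit moved to the sibling branch. On additive matrices the
algorithm provably returns the generating topology with exact path
lengths; the test suite verifies both against random known trees and
against scikit-bio's independent NJ.

Bootstrap without an MSA: the resampling unit is the column set of each
pairwise comparison. Per replicate, every column of a pair's alignment
receives a Poisson(1) weight from a generator seeded by
(seed, replicate, pair) — deterministic and order-independent — and the
weighted p-distance feeds a replicate NJ tree. Support on an internal edge
is the percentage of replicate trees containing its bipartition. A
resample that pushes a near-saturated pair over the correction bound is
clipped just inside the domain rather than aborting the replicate.

Monophyly is tested in the unrooted sense (some bipartition isolates the
tip set) or after outgroup rooting; rooting re-hangs the tree on the edge
subtending the outgroup with its length split equally. Composition tables
round percentages half-up to one decimal and also report integer-rounded
values, matching how clade compositions are conventionally quoted.

## ANI and species clustering

The query genome is cut into consecutive 1000-bp fragments (tail
fragments shorter than `frag_len` are dropped); each fragment is mapped to
its best region anywhere in the reference by semi-global edit-distance
alignment (edlib), with the search bounded at the mapping floor since
poorer matches cannot count. Fragments at ≥70% identity are mapped; ANI is
the mean identity over mapped fragments, and *undefined* (not zero) when
nothing maps. Species are single-linkage clusters of the graph with edges
where the larger directional ANI reaches the threshold (default 95%) —
conservative, deterministic merging. This is an ANI in the fastANI
tradition, not a bit-exact reproduction of fastANI or pyANI.

## Exact mass

Monoisotopic masses on the ¹²C scale; adduct m/z is the mass of the
adjusted neutral composition with one electron mass added per negative
(removed per positive) charge, divided by |charge|. Adduct notation is
parsed generally, so both the sodium-exchange reading `[M-2H+Na]-` and the
literal sodium-loss reading `[(M-2H)-Na]-` of the ambiguous
"(M − 2H) − Na" notation are available as distinct, named ions rather
than a silent guess.

## Synthetic data: what it emulates and what it does not

The generator stands in for a public assembly collection. Role queries are
random proteins at the field-typical lengths (FAAL 600 aa, desaturases
350 aa, ACP 80 aa, TE 250 aa, rubredoxin 60 aa, P450 400 aa); random
sequences of this length share ~6% identity, far below any threshold, so
role cross-talk is excluded by construction. Planted cassette genes are
homologs of the queries at 80% identity (substitutions only — realized
identity is then exact, keeping the divergence arithmetic sharp; indels
are exercised separately in the alignment tests). Genes are
reverse-translated with random synonymous codons of the bacterial code so
annotated CDS translation reproduces the planted protein exactly.
Genome pairs apply uniform per-site substitution, giving expected ANI of
100·(1−divergence); panels with clade or species structure derive members
from shared ancestors at solved per-lineage rates.

Not emulated: realistic GC content and codon usage, gene-density and
operon structure, low-complexity or repetitive sequence, horizontal
transfer within a panel, and indel divergence between genomes. Passing
tests therefore demonstrate the *logic* of the screen — thresholds,
colocalization, rescue, clustering — not robustness to compositional
biases of real assemblies, which BLAST-class tools handle with masking and
composition-based statistics this package deliberately omits.

## Pipeline

Stages run mine → trees → composition → ANI on a sorted genome panel, so
reports are invariant to input order and byte-identical across reruns with
the same seed. The diversity tree is built from the second-desaturase
(`DES_2`) proteins of polyyne-family calls, the protein the polyyne
diversity phylogeny is anchored on. Because that tree contains only
polyyne producers, the polyyne-monophyly verdict is computed on a
companion tree of anchor-desaturase (`DES_B`) proteins spanning *all*
cassette-positive genomes; both roles are configurable. Panels with fewer
than three tree sequences skip the tree stages with a logged warning while
mining and ANI results are still emitted.

## Problem sizes and determinism

Synthetic genomes default to 120 kbp over two contigs (panel genomes
40–60 kbp); the classifier truth table runs 6 variants × 5 seeds; the
alignment oracle uses ≥100 random pairs of length ≤12 against a
memoised recursive formulation (plus literal path enumeration at length
≤5 and Biopython as a second oracle in the tests); NJ consistency uses 50
random additive matrices of ≤8 taxa; ANI recovery uses a 200-kbp pair at
5% divergence and a 3-ancestor × 3-genome species panel; bootstrap checks
use two 5-member clades (~95% within, ~40% between identity) at 100
replicates. Every stochastic component draws from
`numpy.random.default_rng` seeded per call; there is no global random
state, and `scripts/acceptance.py` derives all of its seeds from its
`--seed` argument.

## Known limitations

- E-values are package-internal reference values, not NCBI-BLAST-comparable.
- NJ + pairwise distances approximate, but do not reproduce, ML (GTR+Γ)
  phylogenies; clade logic is tool-agnostic and accepts external Newick.
- The fragment ANI is not bit-identical to fastANI/pyANI.
- GFF3 ingestion is limited to `gene`/`CDS` rows with `ID` attributes;
  GenBank/EMBL input is unsupported.
- The split-rescue rule requires the stranded roles to lie within the
  window radius of a contig end, mirroring the manual-inspection rationale;
  mid-contig relocations of cassette genes are reported as `alkyne`.
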