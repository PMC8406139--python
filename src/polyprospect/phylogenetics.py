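"""Distance-based phylogenetics and clade logic.

Trees here stand in for the maximum-likelihood phylogenies of the original
diversity analysis: pairwise global alignments give p-distances (optionally
Poisson-corrected for proteins or Jukes-Cantor-corrected for nucleotides),
neighbor joining builds the topology, and a nonparametric bootstrap over
alignment columns attaches integer supports.  The clade operations
(monophyly, outgroup rooting, clade extraction, composition tables) are
tool-agnostic and accept any tree, including external Newick input.

Trees are :class:`skbio.TreeNode` objects; unrooted trees carry a
trifurcating root by convention.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import DistanceMatrix, TreeNode

__all__ = [
    "pairwise_distance",
    "distance_matrix",
    "neighbor_joining",
    "bootstrap_support",
    "is_monophyletic",
    "root_tree",
    "extract_clade",
    "clade_composition",
    "CompositionTable",
]

MODELS = ("p", "poisson", "jc69")


def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = substitution_matrices.load("BLOSUM62")
    a.open_gap_score = -12.0
    a.extend_gap_score = -1.0
    return a


def _nucleotide_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 5.0
    a.mismatch_score = -4.0
    a.open_gap_score = -11.0
    a.extend_gap_score = -1.0
    return a

_ALIGNERS: dict[str, Align.PairwiseAligner] = {}


def _aligner_for(model: str) -> Align.PairwiseAligner:
    kind = "nt" if model == "jc69" else "aa"
    if kind not in _ALIGNERS:
        _ALIGNERS[kind] = _nucleotide_aligner() if kind == "nt" else _protein_aligner()
    return _ALIGNERS[kind]


def aligned_columns(seq_a: str, seq_b: str, model: str = "poisson") -> np.ndarray:
    """Boolean mismatch indicator per aligned (non-gap) column."""
    aln = _aligner_for(model).align(seq_a.upper(), seq_b.upper())[0]
    mism: list[bool] = []
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for x, y in zip(seq_a[a0:a1].upper(), seq_b[b0:b1].upper()):
            mism.append(x != y)
    return np.array(mism, dtype=bool)


def _correct(p: float, model: str) -> float:
    if model == "p":
        return p
    if model == "poisson":
        if p >= 1.0:
            raise ValueError("saturated: p-distance >= 1 for Poisson correction")
        return -math.log(1.0 - p)
    if model == "jc69":
        if p >= 0.75:
            raise ValueError("saturated: p-distance >= 3/4 for JC69 correction")
        return -0.75 * math.log(1.0 - 4.0 * p / 3.0)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def pairwise_distance(seq_a: str, seq_b: str, model: str = "poisson") -> float:
    """Evolutionary distance from a pairwise global alignment."""
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    mism = aligned_columns(seq_a, seq_b, model)
    if mism.size == 0:
        raise ValueError("no aligned columns between sequences")
    return _correct(float(mism.mean()), model)


def distance_matrix(named_seqs, model: str = "poisson") -> DistanceMatrix:
    """All pairwise distances for ``[(name, seq), ...]``."""
    names = [n for n, _ in named_seqs]
    seqs = dict(named_seqs)
    n = len(names)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_distance(seqs[names[i]], seqs[names[j]], model)
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(mat, ids=names)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties are resolved toward the lexicographically smallest
    taxon pair (clusters are represented by their smallest tip label).
    Negative branch lengths are clamped to zero with the deficit moved to
    the sibling branch.  The result is unrooted, stored with a trifurcating
    root.
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    D = np.array(dm.data, dtype=float)
    nodes = [TreeNode(name=i) for i in ids]
    reps = list(ids)  # smallest tip label within each active cluster

    while len(nodes) > 3:
        n = len(nodes)
        r = D.sum(axis=1)
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * D[i, j] - r[i] - r[j]
                pair = tuple(sorted((reps[i], reps[j])))
                key = (q, pair)
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        D = np.vstack([D[keep][:, keep],
                       new_row[keep][np.newaxis, :]])
        D = np.hstack([D, np.append(new_row[keep], 0.0)[:, np.newaxis]])
        new_rep = min(reps[i], reps[j])
        nodes = [nodes[k] for k in keep] + [parent]
        reps = [reps[k] for k in keep] + [new_rep]

    # resolve the final three clusters on a trifurcating root
    (a, b, c) = nodes
    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    la, lb = _clamp_pair(la, lb)
    lb, lc = _clamp_pair(lb, lc)
    la, lc = _clamp_pair(la, lc)
    root = TreeNode(children=[a, b, c])
    a.length, b.length, c.length = max(la, 0.0), max(lb, 0.0), max(lc, 0.0)
    return root


def _clamp_pair(x: float, y: float) -> tuple[float, float]:
    if x < 0:
        y += x
        x = 0.0
    if y < 0:
        x = max(x + y, 0.0)
        y = 0.0
    return x, y


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def _bipartitions(tree: TreeNode, all_tips: frozenset[str]) -> set[frozenset[str]]:
    """Nontrivial splits, canonicalised to the side without the first taxon."""
    anchor = min(all_tips)
    splits: set[frozenset[str]] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (2 <= len(side) <= len(all_tips) - 2):
            continue
        if anchor in side:
            side = all_tips - side
        splits.add(side)
    return splits


def bootstrap_support(named_seqs, n_reps: int = 100, seed: int = 0,
                      model: str = "poisson") -> TreeNode:
    """NJ tree with integer bootstrap supports on internal edges.

    Without a multiple alignment the resampling unit is the column set of
    each pairwise comparison: per replicate, every column of a pair's
    global alignment receives a Poisson(1) weight drawn from a generator
    seeded by (seed, replicate, pair), and the pair's p-distance is
    recomputed under those weights.  Support = percentage of replicate NJ
    trees containing the edge's bipartition.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    named_seqs = list(named_seqs)
    names = [n for n, _ in named_seqs]
    all_tips = frozenset(names)
    n = len(names)
    cols: dict[tuple[int, int], np.ndarray] = {}
    for i in range(n):
        for j in range(i + 1, n):
            cols[(i, j)] = aligned_columns(named_seqs[i][1], named_seqs[j][1], model)

    def matrix_from(pfun) -> DistanceMatrix:
        mat = np.zeros((n, n))
        for (i, j), mism in cols.items():
            mat[i, j] = mat[j, i] = _correct(pfun(i, j, mism), model)
        return DistanceMatrix(mat, ids=names)

    tree = neighbor_joining(matrix_from(lambda i, j, m: float(m.mean())))

    counts: Counter[frozenset[str]] = Counter()
    for rep in range(n_reps):
        def p_boot(i, j, mism, rep=rep):
            rng = np.random.default_rng([int(seed) % (2**31), rep, i, j])
            w = rng.poisson(1.0, size=mism.size)
            tot = w.sum()
            if tot == 0:
                return float(mism.mean())
            p = float((w * mism).sum() / tot)
            # a resample can push a near-saturated pair over the model bound
            bound = 0.75 if model == "jc69" else 1.0
            return min(p, bound - 1e-9) if model != "p" else p
        rep_tree = neighbor_joining(matrix_from(p_boot))
        counts.update(_bipartitions(rep_tree, all_tips))

    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if not (2 <= len(side) <= n - 2):
            node.support = None
            continue
        if min(all_tips) in side:
            side = all_tips - side
        node.support = int(round(100.0 * counts[side] / n_reps))
    return tree


# ---------------------------------------------------------------------------
# clade logic
# ---------------------------------------------------------------------------

def _tipset(tree: TreeNode) -> set[str]:
    return {t.name for t in tree.tips()}


def _check_tips(tree: TreeNode, tips) -> set[str]:
    known = _tipset(tree)
    tips = set(tips)
    for t in sorted(tips):
        if t not in known:
            raise ValueError(f"unknown tip label {t!r}")
    return tips


def is_monophyletic(tree: TreeNode, tips, outgroup=None) -> bool:
    """Do *tips* form a single clade (after rooting on *outgroup*, if given)?

    Without an outgroup the test is unrooted: true iff some bipartition
    separates *tips* from everything else.
    """
    tips = _check_tips(tree, tips)
    if not tips:
        raise ValueError("empty tip set")
    if len(tips) == 1:
        return True
    if outgroup is not None:
        og = _check_tips(tree, outgroup)
        if og & tips:
            raise ValueError("outgroup overlaps the tested tip set")
        rooted = root_tree(tree, og)
        lca = rooted.lca(list(tips))
        return _tipset(lca) == tips
    every = _tipset(tree)
    if tips == every:
        return True
    for node in tree.traverse(include_self=False):
        side = _tipset(node) if not node.is_tip() else {node.name}
        if side == tips or every - side == tips:
            return True
    return False


def root_tree(tree: TreeNode, outgroup) -> TreeNode:
    """Root on the edge subtending *outgroup*, splitting its length equally."""
    og = _check_tips(tree, outgroup)
    every = _tipset(tree)
    if og == every:
        raise ValueError("outgroup cannot contain every tip")
    work = tree.copy()
    target = None
    for node in work.traverse(include_self=False):
        side = _tipset(node) if not node.is_tip() else {node.name}
        if side == og or every - side == og:
            target = node
            break
    if target is None:
        raise ValueError("outgroup is not monophyletic in this tree")
    has_support = any(getattr(nd, "support", None) is not None
                      for nd in work.non_tips(include_self=False))
    return work.root_at(target, above=True,
                        branch_attrs=["support"] if has_support else [])


def extract_clade(tree: TreeNode, tips) -> TreeNode:
    """The minimal clade spanning *tips* (error if not monophyletic)."""
    tips = _check_tips(tree, tips)
    if not is_monophyletic(tree, tips):
        raise ValueError("tips are not monophyletic; cannot extract clade")
    every = _tipset(tree)
    if tips == every:
        return tree.copy()
    for node in tree.traverse(include_self=False):
        side = _tipset(node) if not node.is_tip() else {node.name}
        if side == tips:
            return node.copy()
    # tips span the current root: reroot on the complement first
    rooted = root_tree(tree, every - tips)
    for node in rooted.traverse(include_self=False):
        side = _tipset(node) if not node.is_tip() else {node.name}
        if side == tips:
            return node.copy()
    raise AssertionError("unreachable: monophyletic tips must exist as a clade")


# ---------------------------------------------------------------------------
# composition tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompositionTable:
    """Group counts for a clade with half-up-rounded percentages."""

    counts: dict[str, int]
    total: int
    percentages: dict[str, float]       # one decimal place
    int_percentages: dict[str, int]     # nearest integer

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("group\tcount\tpercent\tpercent_int\n")
            for g in sorted(self.counts):
                fh.write(f"{g}\t{self.counts[g]}\t{self.percentages[g]:.1f}\t"
                         f"{self.int_percentages[g]}\n")


def clade_composition(labels, clade_tips) -> CompositionTable:
    """Per-group counts and percentages for the tips of a clade."""
    clade_tips = list(clade_tips)
    if not clade_tips:
        raise ValueError("empty clade")
    for t in clade_tips:
        if t not in labels:
            raise ValueError(f"unlabeled tip {t!r}")
    counts = Counter(labels[t] for t in clade_tips)
    total = sum(counts.values())
    pct, ipct = {}, {}
    for g, c in counts.items():
        exact = Decimal(c) * 100 / Decimal(total)
        pct[g] = float(exact.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
        ipct[g] = int(exact.quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return CompositionTable(dict(counts), total, pct, ipct)
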