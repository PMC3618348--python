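"""Maximum-parsimony phylogenetics over reference-projected alignments.

Pairwise alignments against a common reference are projected into a
gap-free character matrix (any column with a gap or ambiguity in any taxon
is dropped).  Tree search is exact: full enumeration of unrooted
topologies or branch-and-bound, scored by Fitch parsimony on site-pattern
bitmasks.  Bootstrap support is the percentage of column-resampled
replicates whose strict-consensus best tree contains each bipartition.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .compare import PairwiseAlignment

_CODE = {65: 0, 67: 1, 71: 2, 84: 3}  # A C G T bytes


@dataclass
class CharacterMatrix:
    taxa: list[str]
    data: np.ndarray  # (n_taxa, n_columns) uint8 states 0..3

    def __post_init__(self):
        if self.data.ndim != 2 or self.data.shape[0] != len(self.taxa):
            raise ValueError("matrix shape does not fit the taxon list")

    @property
    def n_columns(self) -> int:
        return self.data.shape[1]

    def patterns(self) -> tuple[np.ndarray, np.ndarray]:
        """(unique column patterns as (n_taxa, P) array, counts)."""
        cols = np.ascontiguousarray(self.data.T)
        uniq, counts = np.unique(cols, axis=0, return_counts=True)
        return uniq.T, counts

    def to_phylip(self) -> str:
        lines = [f"{len(self.taxa)} {self.n_columns}"]
        alpha = np.frombuffer(b"ACGT", dtype=np.uint8)
        for name, row in zip(self.taxa, self.data):
            lines.append(f"{name}  " + alpha[row].tobytes().decode())
        return "\n".join(lines) + "\n"


def build_matrix(
    alignments: dict[str, PairwiseAlignment],
    reference_name: str | None = None,
) -> CharacterMatrix:
    """Project per-species alignments onto the shared reference.

    The reference joins the matrix as its own taxon.  Columns where any
    taxon has a gap or a non-ACGT state are excluded.
    """
    if not alignments:
        raise ValueError("no alignments given")
    first = next(iter(alignments.values()))
    ref_seq = first.reference
    ref_name = reference_name or first.reference_id
    n = len(ref_seq)
    taxa = [ref_name] + sorted(alignments)
    if len(taxa) < 3:
        raise ValueError("need at least three taxa")
    rows = [np.frombuffer(ref_seq.encode(), dtype=np.uint8)]
    for sp in taxa[1:]:
        aln = alignments[sp]
        if aln.reference != ref_seq:
            raise ValueError(f"alignment for {sp} uses a different reference")
        rows.append(aln.query_states())
    raw = np.vstack(rows)
    coded = np.full_like(raw, 255)
    for byte, code in _CODE.items():
        coded[raw == byte] = code
    keep = (coded != 255).all(axis=0)
    return CharacterMatrix(taxa=taxa, data=coded[:, keep].astype(np.uint8))


# ---------------------------------------------------------------------------
# trees: nested tuples rooted at taxon 0's pendant edge
# ---------------------------------------------------------------------------
# An unrooted binary tree over taxa 0..n-1 is stored as a nested tuple over
# 1..n-1; the implicit root edge leads to taxon 0.


def _leaves(node) -> frozenset:
    if isinstance(node, int):
        return frozenset((node,))
    return _leaves(node[0]) | _leaves(node[1])


def _canonical(node):
    if isinstance(node, int):
        return node
    a, b = _canonical(node[0]), _canonical(node[1])
    return (a, b) if str(a) <= str(b) else (b, a)


def enumerate_topologies(n_taxa: int):
    """All unrooted binary topologies over n_taxa labels (3 or more)."""
    if n_taxa < 3:
        raise ValueError("need >= 3 taxa")

    def insert_everywhere(node, t):
        yield (node, t)
        if isinstance(node, tuple):
            for v in insert_everywhere(node[0], t):
                yield (v, node[1])
            for v in insert_everywhere(node[1], t):
                yield (node[0], v)

    trees = [(1, 2)] if n_taxa >= 3 else [1]
    for t in range(3, n_taxa):
        trees = [v for tr in trees for v in insert_everywhere(tr, t)]
    return trees


def n_unrooted_topologies(n_taxa: int) -> int:
    out = 1
    for i in range(3, n_taxa + 1):
        out *= 2 * i - 5
    return out


def bipartitions(tree, n_taxa: int) -> set[frozenset]:
    """Non-trivial bipartitions, each as the side excluding taxon 0."""
    out: set[frozenset] = set()

    def walk(node):
        if isinstance(node, int):
            return
        ls = _leaves(node)
        if 2 <= len(ls) <= n_taxa - 2:
            out.add(ls)
        walk(node[0])
        walk(node[1])

    walk(tree)
    return out


@dataclass
class Tree:
    taxa: list[str]
    topology: tuple
    score: int | None = None
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self, with_supports: bool = True) -> str:
        n = len(self.taxa)

        def fmt(node) -> str:
            if isinstance(node, int):
                return self.taxa[node]
            inner = f"({fmt(node[0])},{fmt(node[1])})"
            if with_supports:
                ls = _leaves(node)
                if 2 <= len(ls) <= n - 2 and ls in self.supports:
                    inner += f"{self.supports[ls]:.0f}"
            return inner
        return f"({self.taxa[0]},{fmt(self.topology)});"

    def bipartitions(self) -> set[frozenset]:
        return bipartitions(self.topology, len(self.taxa))


# ---------------------------------------------------------------------------
# Fitch parsimony
# ---------------------------------------------------------------------------

def _fitch_masks(node, leaf_masks, out_cost):
    if isinstance(node, int):
        return leaf_masks[node]
    lm = _fitch_masks(node[0], leaf_masks, out_cost)
    rm = _fitch_masks(node[1], leaf_masks, out_cost)
    inter = lm & rm
    empty = inter == 0
    out_cost += empty
    return np.where(empty, lm | rm, inter)


def _score_patterns(tree, leaf_masks, weights) -> int:
    cost = np.zeros(weights.shape, dtype=np.int64)
    root_mask = _fitch_masks(tree, leaf_masks, cost)
    inter = root_mask & leaf_masks[0]
    cost += inter == 0
    return int(np.dot(cost, weights))


def parsimony_score(tree: Tree | tuple, matrix: CharacterMatrix) -> int:
    """Fitch small-parsimony score of an unrooted tree over the matrix."""
    topology = tree.topology if isinstance(tree, Tree) else tree
    if isinstance(tree, Tree) and tree.taxa != matrix.taxa:
        raise ValueError("tree and matrix taxa differ")
    labels = sorted(_leaves(topology) | {0})
    if labels != list(range(len(matrix.taxa))):
        raise ValueError("tree leaves do not match matrix taxa")
    pats, counts = matrix.patterns()
    leaf_masks = (1 << pats.astype(np.uint8)).astype(np.uint8)
    return _score_patterns(topology, leaf_masks, counts)


# ---------------------------------------------------------------------------
# exact search
# ---------------------------------------------------------------------------

def search_mp(
    matrix: CharacterMatrix,
    strategy: str = "branch_and_bound",
) -> tuple[list[Tree], int]:
    """All maximum-parsimony topologies and their score.

    ``exhaustive`` enumerates every unrooted topology (up to 12 taxa);
    ``branch_and_bound`` prunes stepwise-addition prefixes whose partial
    score already exceeds the best complete tree (up to 20 taxa).
    """
    n = len(matrix.taxa)
    if strategy == "exhaustive":
        if not 4 <= n <= 12:
            raise ValueError("exhaustive search supports 4..12 taxa")
    elif strategy == "branch_and_bound":
        if not 4 <= n <= 20:
            raise ValueError("branch-and-bound supports 4..20 taxa")
    else:
        raise ValueError(f"unknown strategy {strategy!r}")

    pats, counts = matrix.patterns()
    leaf_masks = (1 << pats.astype(np.uint8)).astype(np.uint8)

    if strategy == "exhaustive":
        best_trees: list[tuple] = []
        best = None
        for topo in enumerate_topologies(n):
            sc = _score_patterns(topo, leaf_masks, counts)
            if best is None or sc < best:
                best, best_trees = sc, [topo]
            elif sc == best:
                best_trees.append(topo)
        return (
            [Tree(matrix.taxa, _canonical(t), best) for t in best_trees],
            int(best),
        )

    best: list[int | None] = [None]
    best_trees = []

    def insert_everywhere(node, t):
        yield (node, t)
        if isinstance(node, tuple):
            for v in insert_everywhere(node[0], t):
                yield (v, node[1])
            for v in insert_everywhere(node[1], t):
                yield (node[0], v)

    def grow(topo, next_taxon):
        sc = _score_patterns(topo, leaf_masks, counts)
        if best[0] is not None and sc > best[0]:
            return  # adding taxa never lowers the score
        if next_taxon == n:
            if best[0] is None or sc < best[0]:
                best[0] = sc
                best_trees.clear()
                best_trees.append(topo)
            elif sc == best[0]:
                best_trees.append(topo)
            return
        for t in insert_everywhere(topo, next_taxon):
            grow(t, next_taxon + 1)

    grow((1, 2), 3)
    return (
        [Tree(matrix.taxa, _canonical(t), best[0]) for t in best_trees],
        int(best[0]),
    )


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

def strict_consensus_bipartitions(trees: list[Tree]) -> set[frozenset]:
    sets = [t.bipartitions() for t in trees]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def bootstrap(
    matrix: CharacterMatrix,
    replicates: int = 1000,
    seed: int = 0,
    strategy: str = "branch_and_bound",
) -> Tree:
    """Bootstrap the MP tree: resample columns with replacement, re-search
    per replicate, and report per-edge support percentages on the best
    tree of the original matrix."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    best_trees, _ = search_mp(matrix, strategy=strategy)
    main = best_trees[0]
    counts_by_split: dict[frozenset, int] = {bp: 0 for bp in main.bipartitions()}
    rng = np.random.default_rng(seed)
    n_cols = matrix.n_columns
    for _ in range(replicates):
        idx = rng.integers(0, n_cols, n_cols)
        rep = CharacterMatrix(taxa=matrix.taxa, data=matrix.data[:, idx])
        rep_best, _ = search_mp(rep, strategy=strategy)
        rep_splits = strict_consensus_bipartitions(rep_best)
        for bp in counts_by_split:
            if bp in rep_splits:
                counts_by_split[bp] += 1
    supports = {
        bp: 100.0 * c / replicates for bp, c in counts_by_split.items()
    }
    return Tree(main.taxa, main.topology, main.score, supports)
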