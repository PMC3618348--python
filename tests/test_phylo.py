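import itertools

import numpy as np
import pytest

from plastomekit.compare import align_pair
from plastomekit.phylo import (
    CharacterMatrix,
    Tree,
    bipartitions,
    bootstrap,
    build_matrix,
    enumerate_topologies,
    n_unrooted_topologies,
    parsimony_score,
    search_mp,
)
from plastomekit.synth import (
    PlastomeSpec,
    default_inventory,
    deletion,
    evolve_genome,
    generate_plastome,
)


def brute_force_score(topo, matrix: CharacterMatrix) -> int:
    """Exhaustive minimization over all internal-node state assignments."""

    def internal_nodes(node):
        if isinstance(node, int):
            return []
        return [node] + internal_nodes(node[0]) + internal_nodes(node[1])

    ints = internal_nodes(topo)
    total = 0
    for col in matrix.data.T:
        best = None
        for assign in itertools.product(range(4), repeat=len(ints) + 1):
            states = {id(n): assign[i] for i, n in enumerate(ints)}
            root_state = assign[-1]

            def state(n):
                return col[n] if isinstance(n, int) else states[id(n)]

            cost = int(col[0] != root_state) + int(state(topo) != root_state)
            stack = [topo]
            while stack:
                n = stack.pop()
                if isinstance(n, int):
                    continue
                for ch in n:
                    cost += state(ch) != state(n)
                    stack.append(ch)
            best = cost if best is None else min(best, cost)
        total += best
    return total


class TestMatrix:
    def test_identical_sequences_keep_all_columns(self, rng):
        from conftest import random_seq

        seq = random_seq(rng, 2_000)
        alns = {f"t{i}": align_pair(seq, seq) for i in range(2)}
        m = build_matrix(alns, reference_name="ref")
        assert m.n_columns == 2_000
        assert np.all(m.data == m.data[0])

    def test_deletion_drops_exactly_its_columns(self):
        base = generate_plastome(
            PlastomeSpec(8_000, 2_000, 1_500, default_inventory(3, 1, 1, seed=5), seed=8),
            "ref",
        )
        c1, _ = evolve_genome(base, structured_events=[deletion(3_000, 3_100)],
                              seed=1, child_id="a")
        c2, _ = evolve_genome(base, sub_rate=0.005, seed=2, child_id="b")
        m = build_matrix({
            "a": align_pair(base, c1),
            "b": align_pair(base, c2),
        })
        assert m.n_columns == len(base.sequence) - 100

    def test_matches_projection_oracle(self):
        base = generate_plastome(PlastomeSpec(4_000, 1_500, 1_000, seed=3), "ref")
        kids = {}
        for i in range(2):
            c, _ = evolve_genome(base, sub_rate=0.01, seed=10 + i, child_id=f"s{i}")
            kids[f"s{i}"] = c
        alns = {sp: align_pair(base, c) for sp, c in kids.items()}
        m = build_matrix(alns)
        # oracle: per-taxon state arrays built column by column from ops
        states = {}
        for sp, aln in alns.items():
            arr = [None] * len(base.sequence)
            r = q = 0
            for op, n in aln.ops:
                for _ in range(n):
                    if op in "=X":
                        arr[r] = aln.query[q]
                        r += 1
                        q += 1
                    elif op == "D":
                        r += 1
                    else:
                        q += 1
            states[sp] = arr
        keep = [
            i for i in range(len(base.sequence))
            if all(states[sp][i] in "ACGT" for sp in states)
        ]
        assert m.n_columns == len(keep)
        code = {c: i for i, c in enumerate("ACGT")}
        for row, sp in zip(m.data[1:], m.taxa[1:]):
            assert list(row) == [code[states[sp][i]] for i in keep]

    def test_needs_three_taxa(self, rng):
        from conftest import random_seq

        seq = random_seq(rng, 500)
        with pytest.raises(ValueError):
            build_matrix({"only": align_pair(seq, seq)})


class TestFitch:
    def test_invariant_matrix_scores_zero(self):
        m = CharacterMatrix(list("abcd"), np.zeros((4, 30), dtype=np.uint8))
        for topo in enumerate_topologies(4):
            assert parsimony_score(topo, m) == 0

    def test_four_taxon_informative_column(self):
        m = CharacterMatrix(list("abcd"), np.array([[0], [0], [1], [1]], dtype=np.uint8))
        assert parsimony_score((1, (2, 3)), m) == 1  # ab | cd
        assert parsimony_score((2, (1, 3)), m) == 2  # ac | bd

    def test_equals_exhaustive_assignment_oracle(self, rng):
        for trial in range(3):
            n = int(rng.integers(4, 7))
            m = CharacterMatrix(
                [f"t{i}" for i in range(n)],
                rng.integers(0, 4, (n, 12)).astype(np.uint8),
            )
            for topo in enumerate_topologies(n)[:6]:
                assert parsimony_score(topo, m) == brute_force_score(topo, m)

    def test_score_invariance_column_permutation(self, rng):
        m = CharacterMatrix(
            [f"t{i}" for i in range(5)], rng.integers(0, 4, (5, 40)).astype(np.uint8)
        )
        perm = rng.permutation(40)
        m2 = CharacterMatrix(m.taxa, m.data[:, perm])
        for topo in enumerate_topologies(5)[:5]:
            assert parsimony_score(topo, m) == parsimony_score(topo, m2)

    def test_leaf_mismatch_error(self):
        m = CharacterMatrix(list("abcd"), np.zeros((4, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            parsimony_score((1, (2, 4)), m)


class TestSearch:
    def test_five_taxa_enumeration_count(self):
        assert len(enumerate_topologies(5)) == 15
        assert n_unrooted_topologies(5) == 15
        assert len({str(t) for t in enumerate_topologies(7)}) == 945

    def test_bnb_equals_exhaustive(self, rng):
        for seed in range(3):
            r = np.random.default_rng(seed)
            m = CharacterMatrix(
                [f"t{i}" for i in range(7)],
                r.integers(0, 4, (7, 30)).astype(np.uint8),
            )
            te, se = search_mp(m, "exhaustive")
            tb, sb = search_mp(m, "branch_and_bound")
            assert se == sb
            assert {t.topology for t in te} == {t.topology for t in tb}

    def test_strategy_limits(self):
        m = CharacterMatrix(list("abc"), np.zeros((3, 5), dtype=np.uint8))
        with pytest.raises(ValueError):
            search_mp(m, "exhaustive")
        with pytest.raises(ValueError):
            search_mp(m, "unknown")


class TestBootstrap:
    def _synapomorphic_matrix(self):
        data = np.zeros((5, 80), dtype=np.uint8)
        data[3, :50] = 1
        data[4, :50] = 1
        rng = np.random.default_rng(9)
        data[:, 50:] = rng.integers(0, 4, (5, 30))
        return CharacterMatrix(list("abcde"), data)

    def test_strong_split_gets_full_support(self):
        data = np.zeros((5, 50), dtype=np.uint8)
        data[3] = 1
        data[4] = 1
        m = CharacterMatrix(list("abcde"), data)
        tree = bootstrap(m, replicates=30, seed=0)
        assert tree.supports[frozenset({3, 4})] == 100.0

    def test_seed_determinism(self):
        m = self._synapomorphic_matrix()
        t1 = bootstrap(m, replicates=40, seed=7)
        t2 = bootstrap(m, replicates=40, seed=7)
        assert t1.supports == t2.supports and t1.topology == t2.topology

    def test_support_stability_when_replicates_doubled(self):
        # well-supported nested clades (40 synapomorphies each) + light noise
        data = np.zeros((8, 200), dtype=np.uint8)
        rng = np.random.default_rng(4)
        for cols, clade in (
            (slice(0, 40), [6, 7]),
            (slice(40, 80), [4, 5]),
            (slice(80, 120), [4, 5, 6, 7]),
            (slice(120, 160), [2, 3]),
        ):
            data[clade, cols] = 1
        data[:, 160:] = rng.integers(0, 4, (8, 40))
        m = CharacterMatrix([f"t{i}" for i in range(8)], data)
        a = bootstrap(m, replicates=60, seed=1)
        b = bootstrap(m, replicates=120, seed=1)
        for bp, v in a.supports.items():
            assert abs(v - b.supports.get(bp, 0.0)) <= 5.0

    def test_supports_in_range_and_newick(self):
        m = self._synapomorphic_matrix()
        tree = bootstrap(m, replicates=25, seed=2)
        assert all(0.0 <= v <= 100.0 for v in tree.supports.values())
        nwk = tree.newick()
        assert nwk.endswith(";") and nwk.count("(") == nwk.count(")")

    def test_replicates_validation(self):
        m = self._synapomorphic_matrix()
        with pytest.raises(ValueError):
            bootstrap(m, replicates=0)


class TestTreeRepresentation:
    def test_bipartitions_of_known_topology(self):
        topo = ((1, 2), (3, (4, 5)))
        bps = bipartitions(topo, 6)
        assert frozenset({1, 2}) in bps
        assert frozenset({4, 5}) in bps
        assert frozenset({3, 4, 5}) in bps

    def test_newick_roundtrip_isomorphic(self):
        import dendropy

        taxa = ["Lp", "Lm", "Fp", "Fa", "Fo", "O1", "O2"]
        topo = ((1, (2, (3, 4))), (5, 6))
        t = Tree(taxa, topo)
        nwk = t.newick(with_supports=False)
        parsed = dendropy.Tree.get(data=nwk, schema="newick")
        # same taxon set and same splits after round-trip
        assert {l.taxon.label for l in parsed.leaf_node_iter()} == set(taxa)
        parsed2 = dendropy.Tree.get(
            data=parsed.as_string(schema="newick"), schema="newick",
            taxon_namespace=parsed.taxon_namespace,
        )
        parsed.encode_bipartitions()
        parsed2.encode_bipartitions()
        assert (
            dendropy.calculate.treecompare.symmetric_difference(parsed, parsed2) == 0
        )
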