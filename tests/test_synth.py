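import numpy as np
import pytest

from plastomekit.model import PackingError, revcomp
from plastomekit.synth import (
    ConflictError,
    GeneSpec,
    ParameterError,
    PlastomeSpec,
    deletion,
    default_inventory,
    evolve_genome,
    generate_plastome,
    insertion,
    replay_events,
    simulate_reads,
    snp,
)


def naive_replay(parent: str, log) -> str:
    """Independent oracle: apply events one base at a time."""
    keep = [True] * len(parent)
    subs = {}
    ins = {}
    for e in log.events:
        if e.kind == "snp":
            subs[e.start] = e.payload
        elif e.end == e.start and e.payload:
            ins[e.start] = ins.get(e.start, "") + e.payload
        else:
            for i in range(e.start, e.end):
                keep[i] = False
    out = []
    for i, b in enumerate(parent):
        out.append(ins.get(i, ""))
        if keep[i]:
            out.append(subs.get(i, b))
    out.append(ins.get(len(parent), ""))
    return "".join(out)


class TestGeneratePlastome:
    def test_paper_geometry_length(self):
        spec = PlastomeSpec(79_972, 12_428, 21_441, seed=1)
        g = generate_plastome(spec)
        assert len(g.sequence) == 135_282

    def test_empty_inventory(self):
        g = generate_plastome(PlastomeSpec(5_000, 2_000, 1_500, seed=3))
        assert g.features == []
        assert len(g.sequence) == 5_000 + 2_000 + 2 * 1_500

    def test_seed_determinism_and_ir_mirror(self):
        spec = PlastomeSpec(8_000, 2_000, 1_500,
                            default_inventory(4, 2, 1, seed=9), seed=42)
        g1 = generate_plastome(spec)
        g2 = generate_plastome(spec)
        assert g1.sequence == g2.sequence
        ira = g1.region_sequence("ira")
        irb = g1.region_sequence("irb")
        # base-by-base string-compare oracle
        expected = irb.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        assert all(a == b for a, b in zip(ira, expected))

    def test_all_genes_placed(self, small_genome):
        inv_names = {f"lscG{i:03d}" for i in range(10)}
        names = {f.name for f in small_genome.features}
        assert inv_names <= names
        # IR genes appear twice
        ir_names = [f.name for f in small_genome.features if f.name.startswith("irG")]
        assert len(ir_names) == 2 * len(set(ir_names))

    def test_packing_error_names_region(self):
        bad = PlastomeSpec(
            2_000, 2_000, 1_500,
            (GeneSpec("huge", "LSC", codons=1_000),), seed=0,
        )
        with pytest.raises(PackingError, match="LSC"):
            generate_plastome(bad)

    def test_ir_too_short_rejected(self):
        with pytest.raises(ParameterError):
            generate_plastome(PlastomeSpec(5_000, 2_000, 999, seed=0))


class TestEvolveGenome:
    def test_noop(self, small_genome):
        child, log = evolve_genome(small_genome, seed=0)
        assert child.sequence == small_genome.sequence
        assert log.events == []

    def test_structured_deletion_removes_feature(self, small_genome):
        victim = small_genome.features[2]
        child, log = evolve_genome(
            small_genome,
            structured_events=[deletion(victim.start, victim.end)],
            seed=0,
        )
        names = [f.name for f in child.features]
        assert names.count(victim.name) == 0
        assert len(child.sequence) == len(small_genome.sequence) - (victim.end - victim.start)

    def test_partial_deletion_truncates(self, small_genome):
        victim = small_genome.features[2]
        child, _ = evolve_genome(
            small_genome,
            structured_events=[deletion(victim.start, victim.start + 10)],
            seed=0,
        )
        lifted = [f for f in child.features if f.name == victim.name][0]
        assert lifted.truncated

    def test_replay_oracle_random_rates(self, small_genome):
        child, log = evolve_genome(
            small_genome, sub_rate=0.01, indel_rate=0.001, seed=11
        )
        assert naive_replay(small_genome.sequence, log) == child.sequence
        assert replay_events(small_genome.sequence, log) == child.sequence
        # length conservation from the event-log arithmetic
        dels = sum(
            e.end - e.start for e in log.events if e.end > e.start and not e.payload
        )
        ins = sum(len(e.payload) for e in log.events if e.end == e.start)
        assert len(child.sequence) == len(small_genome.sequence) - dels + ins

    def test_overlapping_deletions_rejected(self, small_genome):
        with pytest.raises(ConflictError):
            evolve_genome(
                small_genome,
                structured_events=[deletion(100, 300), deletion(200, 400)],
            )

    def test_rate_bounds(self, small_genome):
        with pytest.raises(ParameterError):
            evolve_genome(small_genome, sub_rate=0.5)

    def test_seed_determinism(self, small_genome):
        c1, l1 = evolve_genome(small_genome, sub_rate=0.02, seed=5)
        c2, l2 = evolve_genome(small_genome, sub_rate=0.02, seed=5)
        assert c1.sequence == c2.sequence
        assert l1.events == l2.events

    def test_mixed_structured_events(self, small_genome):
        ev = [deletion(50, 60), snp(100, "A"), insertion(200, "ACGT")]
        child, log = evolve_genome(small_genome, structured_events=ev, seed=0)
        assert naive_replay(small_genome.sequence, log) == child.sequence


class TestSimulateReads:
    def test_error_free_reads_are_substrings(self, small_genome):
        pairs, truth = simulate_reads(small_genome, 300, seed=2)
        doubled = small_genome.sequence * 2
        for (r1, r2), t in zip(pairs, truth):
            frag = doubled[t.start:t.start + t.insert]
            if t.strand == -1:
                frag = revcomp(frag)
            assert r1.bases == frag[:100]
            assert r2.bases == revcomp(frag[-100:])

    def test_error_rate_recovered(self, small_genome):
        n, rate = 10_000, 0.01
        pairs, truth = simulate_reads(small_genome, n, error_rate=rate, seed=3)
        doubled = small_genome.sequence * 2
        mism = total = 0
        for (r1, r2), t in zip(pairs, truth):
            frag = doubled[t.start:t.start + t.insert]
            if t.strand == -1:
                frag = revcomp(frag)
            for obs, exp in ((r1.bases, frag[:100]), (r2.bases, revcomp(frag[-100:]))):
                mism += sum(a != b for a, b in zip(obs, exp))
                total += len(obs)
        sd = np.sqrt(rate * (1 - rate) / total)
        assert abs(mism / total - rate) < 3 * sd

    def test_contaminant_fraction(self, small_genome):
        bact = generate_plastome(
            PlastomeSpec(30_000, 2_000, 1_000, seed=77), "bact"
        )
        pairs, truth = simulate_reads(
            small_genome, 5_000, contaminants=[(bact, 0.3)], seed=4
        )
        frac = sum(t.category == "contaminant" for t in truth) / len(truth)
        sd = np.sqrt(0.3 * 0.7 / 5_000)
        assert abs(frac - 0.3) < 3 * sd

    def test_insert_shorter_than_read_rejected(self, small_genome):
        with pytest.raises(ParameterError):
            simulate_reads(small_genome, 10, insert_mean=50, read_len=100)

    def test_seed_determinism(self, small_genome):
        p1, t1 = simulate_reads(small_genome, 100, seed=9)
        p2, t2 = simulate_reads(small_genome, 100, seed=9)
        assert [(a.bases, b.bases) for a, b in p1] == [(a.bases, b.bases) for a, b in p2]
        assert [(a.quals, b.quals) for a, b in p1] == [(a.quals, b.quals) for a, b in p2]
        assert t1 == t2

    def test_quality_range(self, small_genome):
        pairs, _ = simulate_reads(small_genome, 50, seed=1)
        for r1, r2 in pairs:
            assert all(2 <= q <= 40 for q in r1.quals + r2.quals)
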