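import numpy as np
import pytest

from plastomekit.assembly import (
    AssemblyResult,
    Contig,
    assemble_plastome,
    debruijn_assemble,
    locate_ir_by_overhang,
    merge_contigs,
    order_contigs,
    recruit_reads,
    resolve_ir,
    scaffold_contigs,
    select_assembly,
)
from plastomekit.model import AnnotatedGenome, revcomp
from plastomekit.structure import NoIRError
from plastomekit.synth import (
    PlastomeSpec,
    default_inventory,
    evolve_genome,
    generate_plastome,
    simulate_reads,
)

from conftest import random_seq


def tile_reads(seq: str, read_len: int = 100, step: int = 2) -> list[str]:
    """Error-free tiling reads over a linear sequence (both strands)."""
    out = []
    for i in range(0, len(seq) - read_len + 1, step):
        r = seq[i:i + read_len]
        out.append(r if (i // step) % 2 == 0 else revcomp(r))
    return out


@pytest.fixture(scope="module")
def genomes():
    truth = generate_plastome(
        PlastomeSpec(12_000, 3_000, 2_000, default_inventory(4, 2, 1, seed=1), seed=3),
        "truth",
    )
    relative, _ = evolve_genome(truth, sub_rate=0.02, seed=7, child_id="rel")
    relative = AnnotatedGenome(id="rel", sequence=relative.sequence)
    bact = generate_plastome(PlastomeSpec(20_000, 3_000, 1_000, seed=9), "bact")
    return truth, relative, bact


class TestRecruit:
    def test_self_reads_all_recruited(self, genomes):
        truth, _, _ = genomes
        pairs, _ = simulate_reads(truth, 500, seed=1)
        assert len(recruit_reads(pairs, [truth])) == 500

    def test_diverged_relative_recall(self, genomes):
        truth, relative, _ = genomes
        pairs, _ = simulate_reads(truth, 1_000, seed=2)
        kept = recruit_reads(pairs, [relative])
        assert len(kept) / len(pairs) >= 0.95

    def test_contaminants_rejected(self, genomes):
        truth, relative, bact = genomes
        pairs, truthlab = simulate_reads(
            truth, 1_000, contaminants=[(bact, 0.5)], seed=3
        )
        kept_ids = {
            p[0].id.rsplit("/", 1)[0] for p in recruit_reads(pairs, [relative])
        }
        bact_ids = {t.pair_id for t in truthlab if t.category == "contaminant"}
        leaked = len(kept_ids & bact_ids) / max(1, len(bact_ids))
        assert leaked <= 0.001


class TestDebruijn:
    def test_single_contig_from_clean_coverage(self, rng):
        src = random_seq(rng, 10_000)
        contigs = debruijn_assemble(tile_reads(src), 31)
        assert len(contigs) == 1
        seq = contigs[0].sequence
        assert seq == src or seq == revcomp(src)

    def test_single_read(self):
        read = "ACGTACGGTTCAACGGGTTACACGGATCAGACT"
        contigs = debruijn_assemble([read], 21)
        assert len(contigs) == 1
        assert contigs[0].sequence in (read, revcomp(read))

    def test_exact_repeat_splits_contigs(self, rng):
        rep = random_seq(rng, 2_000)
        src = (
            random_seq(rng, 3_000) + rep + random_seq(rng, 3_000)
            + rep + random_seq(rng, 3_000)
        )
        k = 31
        contigs = debruijn_assemble(tile_reads(src), k)
        assert len(contigs) >= 3
        # every contig is an exact substring of the source (either strand)
        for c in contigs:
            assert c.sequence in src or revcomp(c.sequence) in src
        # the collapsed repeat is one of the contigs, delimited at its
        # boundaries (up to the k-1 junction context)
        cores = [c.sequence for c in contigs] + [revcomp(c.sequence) for c in contigs]
        assert any(rep[k:len(rep) - k] in s and len(s) <= len(rep) + 2 * k for s in cores)

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            debruijn_assemble(["ACGT" * 30], 20)

    def test_no_reads(self):
        assert debruijn_assemble([], 21) == []

    def test_kmers_all_from_reads(self, rng):
        reads = [random_seq(rng, 60) for _ in range(20)]
        k = 21
        pool = set()
        for r in reads:
            for s in (r, revcomp(r)):
                pool.update(s[i:i + k] for i in range(len(s) - k + 1))
        for c in debruijn_assemble(reads, k):
            for s in (c.sequence, revcomp(c.sequence)):
                pass
            assert all(
                c.sequence[i:i + k] in pool
                for i in range(len(c.sequence) - k + 1)
            )


class TestSelectAssembly:
    def _mk(self, lengths):
        return {
            k: AssemblyResult(
                contigs=[Contig(f"c{k}", "A" * n, 1.0, k)], k=k
            )
            for k, n in lengths.items()
        }

    def test_nearest_additive_length(self):
        res = self._mk({51: 140_000, 71: 135_300, 91: 120_000})
        assert select_assembly(res, 135_282) == 71

    def test_single_candidate(self):
        res = self._mk({61: 99_000})
        assert select_assembly(res, 135_282) == 61

    def test_tie_prefers_larger_k(self):
        res = self._mk({51: 135_182, 91: 135_382})
        for _ in range(5):
            assert select_assembly(res, 135_282) == 91

    def test_empty_error(self):
        with pytest.raises(ValueError):
            select_assembly({}, 1000)


class TestMergeContigs:
    def test_perfect_60bp_overlap(self, rng):
        src = random_seq(rng, 500)
        a = Contig("a", src[:300], 10.0, 31)
        b = Contig("b", src[240:], 10.0, 31)
        merged = merge_contigs([a, b])
        assert len(merged) == 1
        assert len(merged[0].sequence) == 300 + len(b.sequence) - 60
        assert merged[0].sequence in (src, revcomp(src))

    def test_49bp_overlap_not_merged(self, rng):
        src = random_seq(rng, 500)
        a = Contig("a", src[:300], 10.0, 31)
        b = Contig("b", src[251:], 10.0, 31)
        merged = merge_contigs([a, b], min_overlap=50)
        assert len(merged) == 2

    def test_fragmented_source_reconstructed(self, rng):
        src = random_seq(rng, 4_000)
        pieces = []
        cuts = sorted(rng.integers(150, 3_700, 18))
        starts = [0] + [c - 70 for c in cuts]
        ends = [c + 70 for c in cuts] + [4_000]
        for i, (s, e) in enumerate(zip(starts, ends)):
            seq = src[s:e]
            pieces.append(Contig(f"p{i}", seq if i % 2 else revcomp(seq), 5.0, 31))
        merged = merge_contigs(pieces)
        assert len(merged) == 1
        assert merged[0].sequence in (src, revcomp(src))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            merge_contigs([], min_identity=0.0)

    def test_additive_length_conserved(self, rng):
        src = random_seq(rng, 2_000)
        a = Contig("a", src[:1_100], 5.0, 31)
        b = Contig("b", src[1_000:], 5.0, 31)
        merged = merge_contigs([a, b])
        assert sum(len(c) for c in merged) == len(a) + len(b) - 100


class TestResolveIR:
    def test_generator_scaffold_recircularized(self, small_genome):
        q = small_genome.regions
        scaffold = (
            small_genome.region_sequence("lsc")
            + small_genome.region_sequence("irb")
            + small_genome.region_sequence("ssc")
        )
        genome, report = resolve_ir(
            scaffold, ir_interval=(q.lsc_len, q.lsc_len + q.ir_len)
        )
        assert genome.sequence == small_genome.sequence
        assert not report.asymmetric

    def test_overhang_autolocation(self, small_genome):
        q = small_genome.regions
        lsc = small_genome.region_sequence("lsc")
        irb = small_genome.region_sequence("irb")
        ssc = small_genome.region_sequence("ssc")
        relic = 60
        scaffold = revcomp(irb[:relic]) + lsc + irb + ssc + revcomp(irb[-relic:])
        genome, report = resolve_ir(scaffold)  # no interval given
        assert report.trimmed_prefix == relic
        assert report.trimmed_suffix == relic
        assert genome.sequence == small_genome.sequence

    def test_already_circular_warns(self, small_genome):
        with pytest.warns(UserWarning, match="already"):
            genome, report = resolve_ir(small_genome.sequence)
        assert genome.sequence == small_genome.sequence
        assert "already circular" in report.notes[0]

    def test_no_ir_no_interval_raises(self, rng):
        with pytest.raises(NoIRError):
            resolve_ir(random_seq(rng, 20_000))

    def test_truncated_boundary_flags_asymmetry(self, small_genome):
        q = small_genome.regions
        lsc = small_genome.region_sequence("lsc")
        irb = small_genome.region_sequence("irb")
        ssc = small_genome.region_sequence("ssc")
        relic = 60
        scaffold = revcomp(irb[:relic]) + lsc + irb + ssc + revcomp(irb[-relic:])
        # claim an interval 500 bp short of the true right boundary
        s = relic + q.lsc_len
        genome, report = resolve_ir(scaffold, ir_interval=(s, s + q.ir_len - 500))
        assert report.asymmetric

    def test_interval_below_min_len(self, small_genome):
        with pytest.raises(NoIRError):
            resolve_ir(small_genome.sequence[:10_000], ir_interval=(100, 600))


class TestEndToEndSmall:
    def test_error_free_recovery(self, small_genome):
        relative, _ = evolve_genome(small_genome, sub_rate=0.01, seed=9, child_id="rel")
        relative = AnnotatedGenome(id="rel", sequence=relative.sequence)
        n = int(len(small_genome.sequence) * 60 / 200)
        pairs, _ = simulate_reads(small_genome, n, seed=3)
        genome, result, report = assemble_plastome(
            pairs, [relative], ks=(41, 61), target_length=len(small_genome.sequence)
        )
        doubled = small_genome.sequence * 2
        assert genome.sequence in doubled or revcomp(genome.sequence) in doubled
        assert result.status == "circularized"

    def test_gap_closed_by_closer_relative(self, small_genome):
        # a region of the genome is novel relative to the distant reference,
        # so recruitment misses it; a closer relative recovers it
        seq = small_genome.sequence
        novel_at, novel_len = 9_000, 400
        rng = np.random.default_rng(0)
        distant_seq = (
            seq[:novel_at] + random_seq(rng, novel_len) + seq[novel_at + novel_len:]
        )
        distant = AnnotatedGenome(id="distant", sequence=distant_seq)
        closer = AnnotatedGenome(id="closer", sequence=seq)
        n = int(len(seq) * 60 / 200)
        pairs, _ = simulate_reads(small_genome, n, seed=4)
        genome, result, report = assemble_plastome(
            pairs, [distant], relatives=[closer], ks=(41,),
            target_length=len(seq),
        )
        doubled = seq * 2
        assert genome.sequence in doubled or revcomp(genome.sequence) in doubled
        assert result.gap_report == []
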