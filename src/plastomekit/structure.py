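"""Inverted-repeat detection and quadripartite accounting on circular genomes.

The IR finder seeds on k-mers shared between the sequence and its reverse
complement and extends each seed maximally on the circle; the maximal pair
of disjoint, exactly reverse-complementary intervals is the IR.  The two
arcs between the IR copies become the LSC (longer) and SSC (shorter)
regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnnotatedGenome, GeneFeature, Quadripartite, revcomp

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


class NoIRError(ValueError):
    pass


class AmbiguousIRError(ValueError):
    pass


class ArcTieError(ValueError):
    pass


@dataclass(frozen=True)
class SpaceAccounting:
    pct_gene: float
    pct_intron: float
    pct_intergenic: float

    def as_dict(self) -> dict:
        return {
            "pct_gene": self.pct_gene,
            "pct_intron": self.pct_intron,
            "pct_intergenic": self.pct_intergenic,
        }


def _circ_overlap(s1: int, l1: int, s2: int, l2: int, n: int) -> bool:
    """Do circular intervals [s1, s1+l1) and [s2, s2+l2) intersect?"""
    return ((s2 - s1) % n) < l1 or ((s1 - s2) % n) < l2


def _extend_pair(seq: str, i: int, j_end: int, k: int):
    """Maximally extend a seed with seq[i:i+k] == revcomp(seq[j_end-k:j_end]).

    Intervals live on the circle: A = [a, a+len), B = [b_end-len, b_end),
    maintaining seq[a+t] == complement(seq[b_end-1-t]).  Extension stops at
    the first mismatch or when the two intervals would collide.
    Returns (a, b_end, length) with a, b_end arbitrary integers (use mod n).
    """
    n = len(seq)
    length = k
    a, be = i, j_end

    def disjoint(na, nbe, L):
        return 2 * L <= n and not _circ_overlap(na % n, L, (nbe - L) % n, L, n)

    # grow A leftward / B rightward
    while True:
        na, nbe, L = a - 1, be + 1, length + 1
        if not disjoint(na, nbe, L):
            break
        if _COMP.get(seq[na % n]) != seq[be % n]:
            break
        a, be, length = na, nbe, L
    # grow A rightward / B leftward
    while True:
        L = length + 1
        if not disjoint(a, be, L):
            break
        if _COMP.get(seq[(a + length) % n]) != seq[(be - length - 1) % n]:
            break
        length = L
    return a, be, length


def detect_inverted_repeat(
    genome: AnnotatedGenome | str,
    min_len: int = 1000,
    seed_k: int = 24,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Find the maximal pair of reverse-complementary intervals >= min_len.

    Returns ((a_start, a_end), (b_start, b_end)), 0-based half-open on the
    circle; an interval that wraps the origin has end > genome length.
    Raises :class:`NoIRError` when nothing qualifies and
    :class:`AmbiguousIRError` when two non-equivalent maximal pairs tie.
    """
    seq = (genome.sequence if isinstance(genome, AnnotatedGenome) else genome).upper()
    n = len(seq)
    if n < 2 * min_len:
        raise NoIRError(f"genome ({n} bp) shorter than two copies of {min_len} bp")
    k = min(seed_k, min_len)
    doubled = seq + seq[:k - 1]

    kmer_pos: dict[str, list[int]] = {}
    for i in range(n):
        kmer_pos.setdefault(doubled[i:i + k], []).append(i)

    rc = revcomp(seq)
    rc_doubled = rc + rc[:k - 1]
    # candidates keyed by anti-diagonal (a + b_end stays constant while a
    # seed extends); a diagonal can host several distinct repeat pairs
    found: dict[int, list[tuple[int, int, int]]] = {}
    step = max(1, min_len // 4)
    for p in list(range(0, n, step)):
        kmer = rc_doubled[p:p + k]
        hits = kmer_pos.get(kmer)
        if not hits:
            continue
        # the rc k-mer starting at p mirrors the forward interval ending at n-p
        j_end = n - p
        for i in hits:
            diag = (i + j_end) % n
            prior = found.setdefault(diag, [])
            if any(((i - a0) % n) <= l0 - k for a0, _, l0 in prior):
                continue  # seed already inside an extended pair
            prior.append(_extend_pair(seq, i, j_end, k))

    candidates: set[tuple[int, int, int]] = set()
    for pairs in found.values():
        for a, be, length in pairs:
            if length < min_len:
                continue
            a %= n
            b = (be - length) % n
            candidates.add((a, b, length) if a <= b else (b, a, length))
    if not candidates:
        raise NoIRError(f"no inverted repeat of length >= {min_len} found")
    best_len = max(c[2] for c in candidates)
    best = sorted(c for c in candidates if c[2] == best_len)
    if len(best) > 1:
        raise AmbiguousIRError(f"{len(best)} equally maximal repeat pairs: {best}")
    a, b, length = best[0]
    return (a, a + length), (b, b + length)


def partition_quadripartite(
    genome: AnnotatedGenome | str,
    ir: tuple[tuple[int, int], tuple[int, int]] | None = None,
    min_len: int = 1000,
) -> Quadripartite:
    """Partition a circular genome into LSC / IRb / SSC / IRa.

    The longer inter-repeat arc is the LSC; the repeat copy that follows
    the LSC clockwise is IRb.  LSC + SSC + 2*IR equals the genome length
    exactly.
    """
    seq = genome.sequence if isinstance(genome, AnnotatedGenome) else genome
    n = len(seq)
    if ir is None:
        ir = detect_inverted_repeat(seq, min_len=min_len)
    (p1, p2), (q1, q2) = ir
    ir_len = p2 - p1
    if ir_len != q2 - q1:
        raise ValueError("IR copies differ in length")
    p, q = p1 % n, q1 % n
    arc_after_p = ((p + ir_len) % n, q)
    la = (q - (p + ir_len)) % n
    arc_after_q = ((q + ir_len) % n, p)
    lb = (p - (q + ir_len)) % n
    if la == lb:
        raise ArcTieError(
            f"inter-repeat arcs both span {la} bp; LSC/SSC labeling is ambiguous"
        )
    p_iv = (p, (p + ir_len) % n or n)
    q_iv = (q, (q + ir_len) % n or n)
    if la > lb:
        quad = Quadripartite(lsc=arc_after_p, irb=q_iv, ssc=arc_after_q,
                             ira=p_iv, genome_length=n)
    else:
        quad = Quadripartite(lsc=arc_after_q, irb=p_iv, ssc=arc_after_p,
                             ira=q_iv, genome_length=n)
    assert quad.lsc_len + quad.ssc_len + 2 * quad.ir_len == n
    return quad


def canonical_rotation(genome: AnnotatedGenome, min_len: int = 1000) -> AnnotatedGenome:
    """Rotate a circular genome so the LSC starts at position 0.

    The result carries a fresh quadripartite partition; features are not
    lifted (annotation happens downstream of rotation).
    """
    quad = partition_quadripartite(genome, min_len=min_len)
    n = len(genome.sequence)
    shift = quad.lsc[0] % n
    seq = genome.sequence[shift:] + genome.sequence[:shift]
    g = AnnotatedGenome(id=genome.id, sequence=seq, circular=True)
    g.regions = partition_quadripartite(g, min_len=min_len)
    return g


def space_accounting(
    genome: AnnotatedGenome, features: list[GeneFeature] | None = None
) -> SpaceAccounting:
    """Percentages of the genome labeled exon / intron / intergenic.

    Per-base labeling, precedence exon > intron > intergenic at overlaps;
    the three percentages sum to 100 exactly (integer base counts).
    """
    feats = genome.features if features is None else features
    n = len(genome.sequence)
    label = np.zeros(n, dtype=np.uint8)  # 0 intergenic, 1 intron, 2 exon
    for f in feats:
        for s, e in f.introns:
            np.maximum(label[s:e], 1, out=label[s:e])
    for f in feats:
        for s, e in f.exons:
            label[s:e] = 2
    counts = np.bincount(label, minlength=3)
    return SpaceAccounting(
        pct_gene=100.0 * counts[2] / n,
        pct_intron=100.0 * counts[1] / n,
        pct_intergenic=100.0 * counts[0] / n,
    )
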