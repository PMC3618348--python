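"""Whole-plastome pairwise comparison.

Alignment is anchor-based: maximal unique shared k-mers are chained
colinearly and the inter-anchor segments are filled by affine-gap global
alignment.  From the resulting column runs the module derives overall and
sliding-window identity tracks (reference coordinates) and a catalogue of
query deletions above a length cutoff inside a named region.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from .model import AnnotatedGenome, revcomp


class AlignmentFailure(ValueError):
    pass


@dataclass
class PairwiseAlignment:
    """Run-length encoded alignment columns: '=' match, 'X' mismatch,
    'D' gap in query (deletion), 'I' gap in reference (insertion)."""

    reference_id: str
    query_id: str
    ops: list[tuple[str, int]]
    reference: str
    query: str

    def __post_init__(self):
        ref_cols = sum(n for op, n in self.ops if op in "=XD")
        if ref_cols != len(self.reference):
            raise ValueError(
                f"ops cover {ref_cols} reference columns, sequence has "
                f"{len(self.reference)}"
            )
        qry_cols = sum(n for op, n in self.ops if op in "=XI")
        if qry_cols != len(self.query):
            raise ValueError("ops do not cover the query sequence")

    @property
    def n_columns(self) -> int:
        return sum(n for _, n in self.ops)

    @property
    def matches(self) -> int:
        return sum(n for op, n in self.ops if op == "=")

    def identity(self) -> float:
        """Overall percent identity: matches over all alignment columns."""
        return 100.0 * self.matches / self.n_columns

    def reference_profile(self) -> tuple[np.ndarray, np.ndarray]:
        """(match, gap) boolean arrays over reference positions."""
        match = np.zeros(len(self.reference), dtype=bool)
        gap = np.zeros(len(self.reference), dtype=bool)
        r = 0
        for op, n in self.ops:
            if op == "=":
                match[r:r + n] = True
                r += n
            elif op == "X":
                r += n
            elif op == "D":
                gap[r:r + n] = True
                r += n
        return match, gap

    def query_states(self) -> np.ndarray:
        """Per-reference-position query base (byte), 0 where the query has
        a gap; insertions have no reference coordinate and are skipped."""
        states = np.zeros(len(self.reference), dtype=np.uint8)
        r = q = 0
        qarr = np.frombuffer(self.query.encode(), dtype=np.uint8)
        for op, n in self.ops:
            if op in "=X":
                states[r:r + n] = qarr[q:q + n]
                r += n
                q += n
            elif op == "D":
                r += n
            else:
                q += n
        return states


def _push(ops: list[tuple[str, int]], op: str, n: int) -> None:
    if n <= 0:
        return
    if ops and ops[-1][0] == op:
        ops[-1] = (op, ops[-1][1] + n)
    else:
        ops.append((op, n))


def _match_runs(ops: list, a: str, b: str) -> None:
    """Append '='/'X' runs comparing equal-length segments."""
    for x, y in zip(a, b):
        _push(ops, "=" if x == y else "X", 1)


def _segment_ops(ops: list, ref_seg: str, qry_seg: str, aligner) -> None:
    if not ref_seg and not qry_seg:
        return
    if not ref_seg:
        _push(ops, "I", len(qry_seg))
        return
    if not qry_seg:
        _push(ops, "D", len(ref_seg))
        return
    aln = aligner.align(ref_seg, qry_seg)[0]
    blocks_r, blocks_q = aln.aligned
    pr = pq = 0
    for (rs, re_), (qs, qe) in zip(blocks_r, blocks_q):
        # unaligned stretch before this block: D then I
        _push(ops, "D", rs - pr)
        _push(ops, "I", qs - pq)
        _match_runs(ops, ref_seg[rs:re_], qry_seg[qs:qe])
        pr, pq = re_, qe
    _push(ops, "D", len(ref_seg) - pr)
    _push(ops, "I", len(qry_seg) - pq)


def _unique_kmers(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _chain_anchors(pairs: list[tuple[int, int]], k: int) -> list[tuple[int, int]]:
    """Longest colinear chain (increasing in both coordinates), then made
    non-overlapping by dropping anchors that collide with their
    predecessor."""
    pairs.sort()
    # LIS on query positions (strictly increasing)
    tails: list[int] = []
    tails_idx: list[int] = []
    parent = [-1] * len(pairs)
    for i, (_, q) in enumerate(pairs):
        j = bisect.bisect_left(tails, q)
        if j == len(tails):
            tails.append(q)
            tails_idx.append(i)
        else:
            tails[j] = q
            tails_idx[j] = i
        parent[i] = tails_idx[j - 1] if j > 0 else -1
    chain = []
    i = tails_idx[-1] if tails_idx else -1
    while i != -1:
        chain.append(pairs[i])
        i = parent[i]
    chain.reverse()
    out = []
    for r, q in chain:
        if out and (r < out[-1][0] + k or q < out[-1][1] + k):
            continue
        out.append((r, q))
    return out


def _global_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -8
    a.extend_gap_score = -1
    return a


def align_pair(
    reference: AnnotatedGenome | str,
    query: AnnotatedGenome | str,
    k: int = 31,
    max_segment: int = 20_000,
) -> PairwiseAlignment:
    """Anchor-chained end-to-end alignment of two colinear genomes.

    Both inputs must already be canonically rotated and stranded (see the
    structure module).  Raises :class:`AlignmentFailure` when no anchors
    exist or an inter-anchor segment is too divergent to fill.
    """
    ref_id = reference.id if isinstance(reference, AnnotatedGenome) else "reference"
    qry_id = query.id if isinstance(query, AnnotatedGenome) else "query"
    ref = (reference.sequence if isinstance(reference, AnnotatedGenome) else reference).upper()
    qry = (query.sequence if isinstance(query, AnnotatedGenome) else query).upper()

    ref_k = _unique_kmers(ref, k)
    qry_k = _unique_kmers(qry, k)
    pairs = [(r, qry_k[km]) for km, r in ref_k.items() if km in qry_k]
    if not pairs:
        raise AlignmentFailure(
            f"no shared unique {k}-mers between {ref_id} and {qry_id}"
        )
    anchors = _chain_anchors(pairs, k)
    aligner = _global_aligner()
    ops: list[tuple[str, int]] = []
    pr = pq = 0
    for r, q in anchors:
        if r - pr > max_segment or q - pq > max_segment:
            raise AlignmentFailure(
                f"inter-anchor segment too large ({r - pr}/{q - pq} bp) at "
                f"reference {pr}"
            )
        _segment_ops(ops, ref[pr:r], qry[pq:q], aligner)
        _match_runs(ops, ref[r:r + k], qry[q:q + k])
        pr, pq = r + k, q + k
    _segment_ops(ops, ref[pr:], qry[pq:], aligner)
    return PairwiseAlignment(ref_id, qry_id, ops, ref, qry)


def orient_like(reference: AnnotatedGenome, query: AnnotatedGenome, k: int = 31) -> AnnotatedGenome:
    """Return the query on the strand sharing more unique k-mers with the
    reference (alignment inputs must be co-stranded)."""
    ref_k = set(_unique_kmers(reference.sequence, k))
    fwd = len(ref_k & set(_unique_kmers(query.sequence, k)))
    rc_seq = revcomp(query.sequence)
    rev = len(ref_k & set(_unique_kmers(rc_seq, k)))
    if rev > fwd:
        return AnnotatedGenome(id=query.id, sequence=rc_seq, circular=query.circular)
    return query


# ---------------------------------------------------------------------------
# identity tracks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IdentityTrack:
    window: int
    step: int
    starts: np.ndarray
    values: np.ndarray

    def rows(self) -> list[dict]:
        return [
            {"start": int(s), "end": int(s) + self.window, "pct_identity": float(v)}
            for s, v in zip(self.starts, self.values)
        ]


def window_identity(
    alignment: PairwiseAlignment, window: int = 100, step: int = 25
) -> IdentityTrack:
    """Sliding-window percent identity on reference coordinates.

    Each window scores matches over its reference columns; mismatch and
    query-gap columns count zero (insertions carry no reference
    coordinate and are excluded).
    """
    n = len(alignment.reference)
    if window < step or window > n:
        raise ValueError("need step <= window <= reference length")
    match, _ = alignment.reference_profile()
    csum = np.concatenate([[0], np.cumsum(match)])
    starts = np.arange(0, n - window + 1, step)
    values = 100.0 * (csum[starts + window] - csum[starts]) / window
    return IdentityTrack(window=window, step=step, starts=starts, values=values)


# ---------------------------------------------------------------------------
# deletion catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DeletionEvent:
    start: int   # reference coordinates
    end: int
    length: int  # deleted reference bases within [start, end)


@dataclass
class DeletionCatalog:
    region_name: str
    region: tuple[int, int]
    min_len: int
    by_species: dict[str, list[DeletionEvent]] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        out = []
        for sp in sorted(self.by_species):
            for ev in self.by_species[sp]:
                out.append(
                    {
                        "species": sp,
                        "region": self.region_name,
                        "start": ev.start,
                        "end": ev.end,
                        "length": ev.length,
                    }
                )
        return out


def _gap_runs(gap: np.ndarray) -> list[tuple[int, int]]:
    runs = []
    d = np.diff(gap.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if gap[0]:
        starts.insert(0, 0)
    if gap[-1]:
        ends.append(len(gap))
    return list(zip(starts, ends))


def catalog_deletions(
    alignments: dict[str, PairwiseAlignment],
    region: tuple[int, int],
    region_name: str = "region",
    min_len: int = 40,
    merge_within: int = 5,
) -> DeletionCatalog:
    """Catalogue query deletions strictly longer than ``min_len`` inside a
    reference region.

    Gap runs separated by fewer than ``merge_within`` matched columns are
    merged first (alignment jitter should not split one biological
    deletion); a merged event's length counts its deleted columns only.
    """
    lo, hi = region
    catalog = DeletionCatalog(
        region_name=region_name, region=region, min_len=min_len
    )
    for sp, aln in alignments.items():
        if hi > len(aln.reference):
            raise ValueError(
                f"region {region} outside reference ({len(aln.reference)} bp)"
            )
        _, gap = aln.reference_profile()
        runs = [
            (max(s, lo), min(e, hi))
            for s, e in _gap_runs(gap)
            if s < hi and e > lo
        ]
        merged: list[list[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] < merge_within:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        events = []
        for s, e in merged:
            deleted = int(gap[s:e].sum())
            if deleted > min_len:
                events.append(DeletionEvent(start=s, end=e, length=deleted))
        catalog.by_species[sp] = events
    return catalog
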