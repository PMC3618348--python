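"""Shared k-mer primitives: canonicalization, indexing, edit-distance checks."""

from __future__ import annotations

import numpy as np

from .model import revcomp


def canonical(kmer: str) -> str:
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def iter_kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        yield i, seq[i:i + k]


def kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


class PositionIndex:
    """Canonical k-mer -> (reference, position, strand) postings.

    ``strand=+1`` means the forward k-mer at that reference position equals
    the canonical key; ``-1`` means its reverse complement does.
    """

    def __init__(self, k: int):
        self.k = k
        self.postings: dict[str, list[tuple[int, int, int]]] = {}
        self.ref_ids: list[str] = []
        self.ref_seqs: list[str] = []

    def add_reference(self, ref_id: str, seq: str) -> int:
        if ref_id in self.ref_ids:
            raise ValueError(f"duplicate reference id {ref_id!r}")
        idx = len(self.ref_ids)
        self.ref_ids.append(ref_id)
        self.ref_seqs.append(seq)
        k = self.k
        for pos in range(len(seq) - k + 1):
            kmer = seq[pos:pos + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            if kmer <= rc:
                self.postings.setdefault(kmer, []).append((idx, pos, +1))
            else:
                self.postings.setdefault(rc, []).append((idx, pos, -1))
        return idx

    def lookup(self, kmer: str):
        return self.postings.get(canonical(kmer), ())


def hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def edit_distance_infix(query: str, window: str, cap: int | None = None) -> int:
    """Edit distance of ``query`` against the best-matching substring of
    ``window`` (free gaps at both window ends).  Returns ``cap + 1`` early
    when every alignment already exceeds ``cap``.
    """
    m, n = len(query), len(window)
    if n == 0:
        return m
    warr = np.frombuffer(window.encode(), dtype=np.uint8)
    idx = np.arange(n + 1, dtype=np.int32)
    prev = np.zeros(n + 1, dtype=np.int32)  # free leading window gap
    for i in range(1, m + 1):
        cur = np.empty(n + 1, dtype=np.int32)
        cur[0] = i
        mismatch = (warr != ord(query[i - 1])).astype(np.int32)
        cur[1:] = np.minimum(prev[:-1] + mismatch, prev[1:] + 1)
        # horizontal (gap-in-window) moves via prefix-min transform:
        # cur[j] = min_{l<=j} cur0[l] + (j-l)
        t = np.minimum.accumulate(cur - idx)
        cur = t + idx
        if cap is not None and cur.min() > cap:
            return cap + 1
        prev = cur
    return int(prev.min())  # free trailing window gap
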