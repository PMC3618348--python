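"""Read-origin estimation against a labeled reference panel.

Each read votes with its canonical k-mers; the reference sharing the most
k-mers wins, provided the vote clears ``min_hit_fraction`` of the read's
k-mers and a banded edit-distance check against the anchored locus stays
within ``max_edit_distance``.  Ties break by category priority (plastid
before bacterial) and then lexical reference id, so results are
deterministic and independent of read order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._kmers import PositionIndex, edit_distance_infix, hamming
from .model import revcomp
from .qc import ReadRecord

CATEGORY_PRIORITY = {"plastid": 0, "bacterial": 1}


@dataclass(frozen=True)
class PanelReference:
    id: str
    category: str
    length: int


@dataclass
class PanelIndex:
    k: int
    index: PositionIndex
    references: list[PanelReference]

    def category_of(self, ref_idx: int) -> str:
        return self.references[ref_idx].category


@dataclass
class OriginReport:
    total: int = 0
    by_category: Counter = field(default_factory=Counter)
    by_reference: Counter = field(default_factory=Counter)
    unassigned: int = 0

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {}
        props = {c: n / self.total for c, n in self.by_category.items()}
        props["unassigned"] = self.unassigned / self.total
        return props

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "unassigned": self.unassigned,
            "by_category": dict(self.by_category),
            "by_reference": dict(self.by_reference),
            "proportions": self.proportions,
        }


def build_panel_index(
    references: list[tuple[str, str, str]],
    k: int = 21,
    circular: bool = False,
    wrap: int = 300,
) -> PanelIndex:
    """Index a labeled panel; ``references`` holds (id, category, sequence).

    ``circular=True`` appends the first ``wrap`` bases of each reference so
    reads spanning the origin still anchor and verify.
    """
    if not references:
        raise ValueError("reference panel is empty")
    if k % 2 == 0 or not 15 <= k <= 31:
        raise ValueError(f"k must be odd and in [15, 31], got {k}")
    idx = PositionIndex(k)
    metas = []
    for ref_id, category, seq in references:
        seq = seq.upper()
        if circular:
            seq = seq + seq[:wrap]
        idx.add_reference(ref_id, seq)
        metas.append(PanelReference(ref_id, category, len(seq)))
    return PanelIndex(k=k, index=idx, references=metas)


def _vote(read_seq: str, panel: PanelIndex):
    """Count shared canonical k-mers per reference and collect anchors.

    Anchors come from the first and last matching k-mer of each reference
    (a read overlapping a repeat boundary needs more than one candidate
    locus to verify against).
    """
    k = panel.k
    votes: Counter = Counter()
    first: dict[int, list[tuple[int, int, int]]] = {}
    last: dict[int, list[tuple[int, int, int]]] = {}
    n_kmers = 0
    for qpos in range(len(read_seq) - k + 1):
        kmer = read_seq[qpos:qpos + k]
        if "N" in kmer:
            continue
        n_kmers += 1
        hits = panel.index.lookup(kmer)
        if not hits:
            continue
        fwd_is_canon = kmer <= revcomp(kmer)
        seen_here = set()
        by_ref: dict[int, list[tuple[int, int, int]]] = {}
        for ref_idx, rpos, rstrand in hits[:8]:
            strand = +1 if fwd_is_canon == (rstrand == +1) else -1
            by_ref.setdefault(ref_idx, []).append((qpos, rpos, strand))
            if ref_idx not in seen_here:
                seen_here.add(ref_idx)
                votes[ref_idx] += 1
        for ref_idx, entries in by_ref.items():
            first.setdefault(ref_idx, entries[:4])
            last[ref_idx] = entries[:4]
    anchors = {
        ref: list(dict.fromkeys(first.get(ref, []) + last.get(ref, [])))
        for ref in votes
    }
    return votes, anchors, n_kmers


def _verify_any(
    read_seq: str,
    ref_seq: str,
    anchors: list[tuple[int, int, int]],
    k: int,
    max_edit: int,
) -> bool:
    return any(
        _verify(read_seq, ref_seq, a, k, max_edit) for a in anchors
    )


def _verify(
    read_seq: str,
    ref_seq: str,
    anchor: tuple[int, int, int],
    k: int,
    max_edit: int,
) -> bool:
    qpos, rpos, strand = anchor
    if strand == -1:
        read_seq = revcomp(read_seq)
        qpos = len(read_seq) - k - qpos
    start = rpos - qpos
    lo = max(0, start - max_edit)
    hi = min(len(ref_seq), start + len(read_seq) + max_edit)
    window = ref_seq[lo:hi]
    if len(window) < len(read_seq) - max_edit:
        return False
    # cheap paths first: exact containment, then Hamming at predicted offset
    if read_seq in window:
        return True
    if 0 <= start and start + len(read_seq) <= len(ref_seq):
        if hamming(read_seq, ref_seq[start:start + len(read_seq)]) <= max_edit:
            return True
    return edit_distance_infix(read_seq, window, cap=max_edit) <= max_edit


def assign_read(
    read: ReadRecord | str,
    panel: PanelIndex,
    min_hit_fraction: float = 0.5,
    max_edit_distance: int = 5,
) -> int | None:
    """Return the winning reference index, or None if unassigned."""
    seq = read.bases if isinstance(read, ReadRecord) else read
    if len(seq) < panel.k:
        return None
    votes, anchors, n_kmers = _vote(seq, panel)
    if not votes or n_kmers == 0:
        return None
    top = max(votes.values())
    tied = sorted(
        (r for r in votes if votes[r] == top),
        key=lambda r: (
            CATEGORY_PRIORITY.get(panel.category_of(r), 99),
            panel.references[r].id,
        ),
    )
    best = tied[0]
    if votes[best] < min_hit_fraction * n_kmers:
        return None
    if not _verify_any(
        seq, panel.index.ref_seqs[best], anchors[best], panel.k, max_edit_distance
    ):
        return None
    return best


def classify_reads(
    reads,
    panel: PanelIndex,
    min_hit_fraction: float = 0.5,
    max_edit_distance: int = 5,
    subsample: int | None = None,
    seed: int = 0,
) -> OriginReport:
    """Classify a read stream into plastid / bacterial / unassigned."""
    reads = list(reads)
    if subsample is not None and subsample < len(reads):
        rng = np.random.default_rng(seed)
        keep = rng.choice(len(reads), size=subsample, replace=False)
        reads = [reads[i] for i in sorted(keep)]
    report = OriginReport()
    for read in reads:
        report.total += 1
        ref = assign_read(read, panel, min_hit_fraction, max_edit_distance)
        if ref is None:
            report.unassigned += 1
        else:
            meta = panel.references[ref]
            report.by_category[meta.category] += 1
            report.by_reference[meta.id] += 1
    return report
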