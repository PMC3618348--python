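"""Read quality control.

A read is flagged when any of these fire:

* ``consecutive_N``  — a run of more than three N calls,
* ``low_qual_count`` — more than three bases with PHRED quality <= 20,
* ``low_median``     — a median PHRED quality below 20.

Flagged reads are trimmed from the 3' end back to the longest prefix on
which no rule fires; reads shorter than the minimum length (25 by default)
are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

MIN_LEN = 25
N_RUN_MAX = 3          # runs longer than this fire consecutive_N
LOW_Q = 20             # quality <= LOW_Q counts as low
LOW_Q_COUNT_MAX = 3    # more than this many low-quality bases fires
MEDIAN_MIN = 20        # median below this fires


@dataclass(frozen=True)
class ReadRecord:
    id: str
    bases: str
    quals: list[int]

    def __post_init__(self):
        if len(self.quals) != len(self.bases):
            raise ValueError(
                f"{self.id}: {len(self.bases)} bases but {len(self.quals)} qualities"
            )
        if self.quals and not all(0 <= q <= 60 for q in self.quals):
            raise ValueError(f"{self.id}: PHRED scores must lie in [0, 60]")

    def __len__(self) -> int:
        return len(self.bases)

    def prefix(self, n: int) -> "ReadRecord":
        return ReadRecord(self.id, self.bases[:n], self.quals[:n])


@dataclass(frozen=True)
class QCDecision:
    action: str  # pass | trim | discard
    trim_to: int | None = None
    reasons: frozenset = frozenset()


def _lower_median(values: list[int]) -> int:
    # even-length lists take the lower middle value (integer PHRED)
    s = sorted(values)
    return s[(len(s) - 1) // 2]


def _flags(bases: str, quals: list[int]) -> set[str]:
    reasons = set()
    run = 0
    for b in bases:
        run = run + 1 if b == "N" else 0
        if run > N_RUN_MAX:
            reasons.add("consecutive_N")
            break
    if sum(1 for q in quals if q <= LOW_Q) > LOW_Q_COUNT_MAX:
        reasons.add("low_qual_count")
    if quals and _lower_median(quals) < MEDIAN_MIN:
        reasons.add("low_median")
    return reasons


def _longest_clean_prefix(read: ReadRecord) -> int:
    """Length of the longest prefix on which no QC rule fires.

    Works incrementally from the 5' end: the N-run and low-quality counters
    are monotone, the median is recomputed per prefix.
    """
    best = 0
    run = 0
    low = 0
    sorted_quals: list[int] = []
    import bisect

    for i in range(len(read)):
        run = run + 1 if read.bases[i] == "N" else 0
        if read.quals[i] <= LOW_Q:
            low += 1
        bisect.insort(sorted_quals, read.quals[i])
        if run > N_RUN_MAX or low > LOW_Q_COUNT_MAX:
            break  # monotone rules: no longer prefix can be clean
        if sorted_quals[i // 2] < MEDIAN_MIN:
            continue  # median may recover with more bases
        best = i + 1
    return best


def assess_read(read: ReadRecord, min_len: int = MIN_LEN) -> QCDecision:
    """Decide pass / trim / discard for one read."""
    if len(read) == 0:
        return QCDecision("discard", reasons=frozenset({"too_short"}))
    reasons = _flags(read.bases, read.quals)
    if not reasons:
        if len(read) < min_len:
            return QCDecision("discard", reasons=frozenset({"too_short"}))
        return QCDecision("pass")
    keep = _longest_clean_prefix(read)
    if keep >= min_len:
        return QCDecision("trim", trim_to=keep, reasons=frozenset(reasons))
    return QCDecision("discard", reasons=frozenset(reasons | {"too_short"}))


def apply_decision(read: ReadRecord, decision: QCDecision) -> ReadRecord | None:
    if decision.action == "pass":
        return read
    if decision.action == "trim":
        return read.prefix(decision.trim_to)
    return None


@dataclass
class QCStats:
    input: int = 0
    passed: int = 0
    trimmed: int = 0
    discarded: int = 0
    reasons: dict = field(default_factory=dict)

    def record(self, decision: QCDecision) -> None:
        self.input += 1
        if decision.action == "pass":
            self.passed += 1
        elif decision.action == "trim":
            self.trimmed += 1
        else:
            self.discarded += 1
        for r in decision.reasons:
            self.reasons[r] = self.reasons.get(r, 0) + 1

    def as_dict(self) -> dict:
        return {
            "input": self.input,
            "passed": self.passed,
            "trimmed": self.trimmed,
            "discarded": self.discarded,
            **{f"reason_{k}": v for k, v in sorted(self.reasons.items())},
        }


class PairDesyncError(ValueError):
    pass


def filter_reads(
    reads: Iterable[ReadRecord], min_len: int = MIN_LEN
) -> tuple[list[ReadRecord], QCStats]:
    """Filter an unpaired read stream; returns surviving reads and stats."""
    stats = QCStats()
    out = []
    for read in reads:
        d = assess_read(read, min_len=min_len)
        stats.record(d)
        kept = apply_decision(read, d)
        if kept is not None:
            out.append(kept)
    return out, stats


def filter_pairs(
    pairs: Iterable[tuple[ReadRecord, ReadRecord]],
    min_len: int = MIN_LEN,
    pair_policy: str = "both",
) -> tuple[list[tuple[ReadRecord, ReadRecord]], QCStats]:
    """Filter mate pairs.

    ``pair_policy='both'`` (default) drops both mates when either is
    discarded, keeping mates in sync for assembly; ``'independent'`` keeps
    a surviving mate as an orphan pair entry with the other set to None.
    """
    if pair_policy not in ("both", "independent"):
        raise ValueError(f"unknown pair policy {pair_policy!r}")
    stats = QCStats()
    out = []
    for r1, r2 in pairs:
        d1 = assess_read(r1, min_len=min_len)
        d2 = assess_read(r2, min_len=min_len)
        stats.record(d1)
        stats.record(d2)
        k1 = apply_decision(r1, d1)
        k2 = apply_decision(r2, d2)
        if pair_policy == "both":
            if k1 is not None and k2 is not None:
                out.append((k1, k2))
        else:
            if k1 is not None or k2 is not None:
                out.append((k1, k2))
    return out, stats


def filter_fastq(
    in_records: Iterator[ReadRecord],
    min_len: int = MIN_LEN,
) -> tuple[list[ReadRecord], QCStats]:
    """Contract alias of :func:`filter_reads` for streamed FASTQ input."""
    return filter_reads(in_records, min_len=min_len)
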