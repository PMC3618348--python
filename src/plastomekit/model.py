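"""Core data model shared by every pipeline stage.

Coordinates are 0-based, half-open, everywhere.  Circular genomes fix their
origin at the first base of the large single-copy region; features may wrap
the origin only in intermediate products, canonical genomes keep all
features unwrapped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneFeature:
    """A gene model: one or more exons on one strand of the genome.

    ``exons`` are ordered along the genome; the gaps between consecutive
    exons are the introns.  ``kind`` is one of ``protein``, ``tRNA``,
    ``rRNA``, ``pseudogene``, ``orf``.
    """

    name: str
    kind: str
    strand: int  # +1 or -1
    exons: tuple[tuple[int, int], ...]
    truncated: bool = False
    region: str | None = None  # LSC / SSC / IRa / IRb when known

    def __post_init__(self) -> None:
        if self.strand not in (+1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")
        ex = tuple((int(s), int(e)) for s, e in self.exons)
        if any(e <= s for s, e in ex):
            raise ValueError(f"empty exon in {self.name}: {ex}")
        if any(ex[i][1] > ex[i + 1][0] for i in range(len(ex) - 1)):
            raise ValueError(f"exons overlap or are unsorted in {self.name}")
        object.__setattr__(self, "exons", ex)

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def exonic_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def codons(self) -> int:
        """Length in codons (exonic length / 3, floor for truncated models)."""
        return self.exonic_length // 3

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    def spliced(self, sequence: str) -> str:
        """Spliced (exon-concatenated) sequence on the coding strand."""
        s = "".join(sequence[a:b] for a, b in self.exons)
        return s if self.strand == +1 else revcomp(s)

    def shifted(self, offset: int) -> "GeneFeature":
        return replace(
            self, exons=tuple((s + offset, e + offset) for s, e in self.exons)
        )


@dataclass(frozen=True)
class Quadripartite:
    """LSC / IRb / SSC / IRa intervals partitioning a circular genome."""

    lsc: tuple[int, int]
    irb: tuple[int, int]
    ssc: tuple[int, int]
    ira: tuple[int, int]
    genome_length: int

    def _span(self, iv: tuple[int, int]) -> int:
        s, e = iv
        return e - s if e >= s else self.genome_length - s + e

    @property
    def lsc_len(self) -> int:
        return self._span(self.lsc)

    @property
    def ssc_len(self) -> int:
        return self._span(self.ssc)

    @property
    def ir_len(self) -> int:
        return self._span(self.irb)

    @property
    def sizes(self) -> dict[str, int]:
        return {
            "lsc": self.lsc_len,
            "ssc": self.ssc_len,
            "ir": self.ir_len,
            "total": self.lsc_len + self.ssc_len + 2 * self.ir_len,
        }


class PackingError(ValueError):
    """A gene inventory does not fit inside its declared region."""


@dataclass
class AnnotatedGenome:
    """A circular nucleotide sequence with gene features and region labels."""

    id: str
    sequence: str
    features: list[GeneFeature] = field(default_factory=list)
    regions: Quadripartite | None = None
    circular: bool = True

    def __len__(self) -> int:
        return len(self.sequence)

    def fetch(self, start: int, end: int) -> str:
        """Subsequence on the circle; ``end`` may exceed the length (wrap)."""
        n = len(self.sequence)
        start %= n
        if end <= n and start < end:
            return self.sequence[start:end]
        end = end % n if end > n else end
        return self.sequence[start:] + self.sequence[:end]

    def region_sequence(self, name: str) -> str:
        if self.regions is None:
            raise ValueError("genome has no quadripartite partition")
        iv = getattr(self.regions, name.lower())
        s, e = iv
        n = len(self.sequence)
        return self.fetch(s, e if e > s else e + n)

    def validate(self) -> None:
        n = len(self.sequence)
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"non-ACGTN characters in sequence: {sorted(bad)}")
        for f in self.features:
            if not (0 <= f.start and f.end <= n):
                raise ValueError(f"feature {f.name} out of bounds [0,{n})")
        if self.regions is not None:
            ira = self.region_sequence("ira")
            irb = self.region_sequence("irb")
            if ira != revcomp(irb):
                raise ValueError("IRa is not the reverse complement of IRb")
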