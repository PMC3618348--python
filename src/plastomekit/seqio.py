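"""Readers and writers for the plain-text formats used across the toolkit.

Internal coordinates are 0-based half-open; GFF3's 1-based inclusive
convention is converted at this boundary only.  FASTA headers may carry a
``[circular]`` tag which round-trips through :class:`~plastomekit.model.AnnotatedGenome`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .model import AnnotatedGenome, GeneFeature
from .qc import PairDesyncError, ReadRecord

IUPAC = set("ACGTRYSWKMBDHVN")


class FormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


@dataclass(frozen=True)
class FastaRecord:
    id: str
    description: str
    sequence: str

    @property
    def circular(self) -> bool:
        return "[circular]" in self.description


# -- FASTA ------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[FastaRecord]:
    records: list[FastaRecord] = []
    seen: set[str] = set()
    header, seq_parts, header_line = None, [], 0

    def flush():
        if header is None:
            return
        rid = header.split()[0]
        if rid in seen:
            raise FormatError(f"duplicate record id {rid!r}", header_line)
        seen.add(rid)
        records.append(FastaRecord(rid, header, "".join(seq_parts)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header, seq_parts, header_line = line[1:].strip(), [], lineno
                if not header:
                    raise FormatError("empty FASTA header", lineno)
            else:
                if header is None:
                    raise FormatError("sequence before first header", lineno)
                chunk = line.strip().upper()
                bad = set(chunk) - IUPAC
                if bad:
                    raise FormatError(
                        f"non-IUPAC characters {sorted(bad)}", lineno
                    )
                seq_parts.append(chunk)
    flush()
    return records


def write_fasta(
    path: str | Path,
    records: Iterable[FastaRecord | AnnotatedGenome | tuple],
    wrap: int = 70,
) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, AnnotatedGenome):
                tag = " [circular]" if rec.circular else ""
                name, seq = rec.id + tag, rec.sequence
            elif isinstance(rec, FastaRecord):
                name, seq = rec.description, rec.sequence
            else:
                name, seq = rec
            fh.write(f">{name}\n")
            for i in range(0, len(seq), wrap):
                fh.write(seq[i:i + wrap] + "\n")


def read_genome(path: str | Path) -> AnnotatedGenome:
    recs = read_fasta(path)
    if len(recs) != 1:
        raise FormatError(f"expected a single record, found {len(recs)}")
    r = recs[0]
    return AnnotatedGenome(id=r.id, sequence=r.sequence, circular=r.circular)


# -- FASTQ ------------------------------------------------------------------

def read_fastq(path: str | Path, offset: int = 33) -> Iterator[ReadRecord]:
    """Stream PHRED+33 (or +64) FASTQ records."""
    if offset not in (33, 64):
        raise ValueError("quality encoding offset must be 33 or 64")
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4:
        raise FormatError(
            f"truncated final record (record {len(lines) // 4 + 1})"
        )
    implausible_warned = False
    for rec_idx in range(len(lines) // 4):
        head, bases, plus, qline = lines[rec_idx * 4: rec_idx * 4 + 4]
        lineno = rec_idx * 4 + 1
        if not head.startswith("@"):
            raise FormatError("record header must start with '@'", lineno)
        if not plus.startswith("+"):
            raise FormatError("third line must start with '+'", lineno + 2)
        if len(bases) != len(qline):
            raise FormatError(
                f"base/quality length mismatch in record {rec_idx + 1}", lineno
            )
        quals = [ord(c) - offset for c in qline]
        if offset == 64 and not implausible_warned and any(q < 0 for q in quals):
            import warnings

            warnings.warn(
                "negative PHRED scores: data looks PHRED+33, not PHRED+64",
                stacklevel=2,
            )
            implausible_warned = True
        if any(q < 0 or q > 60 for q in quals):
            raise FormatError(
                f"PHRED score outside [0,60] in record {rec_idx + 1}", lineno + 3
            )
        yield ReadRecord(head[1:].split()[0], bases.upper(), quals)


def read_fastq_pairs(
    path1: str | Path, path2: str | Path, offset: int = 33
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    import itertools

    idx = 0
    for r1, r2 in itertools.zip_longest(
        read_fastq(path1, offset), read_fastq(path2, offset)
    ):
        idx += 1
        if r1 is None or r2 is None:
            raise PairDesyncError(f"mate files desynchronized at record {idx}")
        import re

        stem1 = re.sub(r"/[12]$", "", r1.id)
        stem2 = re.sub(r"/[12]$", "", r2.id)
        if stem1 != stem2:
            raise PairDesyncError(
                f"mate ids disagree at record {idx}: {r1.id} vs {r2.id}"
            )
        yield r1, r2


def write_fastq(path: str | Path, reads: Iterable[ReadRecord], offset: int = 33) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qline = "".join(chr(q + offset) for q in r.quals)
            fh.write(f"@{r.id}\n{r.bases}\n+\n{qline}\n")


# -- GFF3 -------------------------------------------------------------------

_KIND_TO_SO = {
    "protein": "gene",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "pseudogene": "pseudogene",
    "orf": "gene",
}


def write_gff3(path: str | Path, genome: AnnotatedGenome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write(f"##sequence-region {genome.id} 1 {len(genome.sequence)}\n")
        for i, f in enumerate(genome.features):
            strand = "+" if f.strand == +1 else "-"
            attrs = f"ID=feat{i};Name={f.name};kind={f.kind}"
            if f.truncated:
                attrs += ";truncated=true"
            if f.region:
                attrs += f";region={f.region}"
            fh.write(
                "\t".join(
                    [
                        genome.id,
                        "plastomekit",
                        _KIND_TO_SO.get(f.kind, "gene"),
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )
            for s, e in f.exons:
                fh.write(
                    "\t".join(
                        [
                            genome.id,
                            "plastomekit",
                            "exon",
                            str(s + 1),
                            str(e),
                            ".",
                            strand,
                            ".",
                            f"Parent=feat{i}",
                        ]
                    )
                    + "\n"
                )


def read_gff3(path: str | Path, genome_length: int | None = None) -> list[GeneFeature]:
    """Read gene features (with exon children) from a GFF3 file."""
    parents: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"expected 9 columns, got {len(cols)}", lineno)
            _, _, ftype, start, end, _, strand, _, attr_col = cols
            start0, end0 = int(start) - 1, int(end)
            if start0 < 0 or (genome_length is not None and end0 > genome_length):
                raise FormatError(f"feature out of bounds: {start}..{end}", lineno)
            attrs = dict(
                kv.split("=", 1) for kv in attr_col.split(";") if "=" in kv
            )
            if ftype == "exon":
                pid = attrs.get("Parent")
                if pid in parents:
                    parents[pid]["exons"].append((start0, end0))
                continue
            fid = attrs.get("ID", f"feat{lineno}")
            parents[fid] = {
                "name": attrs.get("Name", fid),
                "kind": attrs.get("kind", "protein" if ftype == "gene" else ftype),
                "strand": +1 if strand == "+" else -1,
                "span": (start0, end0),
                "exons": [],
                "truncated": attrs.get("truncated") == "true",
                "region": attrs.get("region"),
            }
            order.append(fid)
    feats = []
    for fid in order:
        p = parents[fid]
        exons = sorted(p["exons"]) or [p["span"]]
        feats.append(
            GeneFeature(
                name=p["name"],
                kind=p["kind"],
                strand=p["strand"],
                exons=tuple(exons),
                truncated=p["truncated"],
                region=p["region"],
            )
        )
    return feats


# -- trees and tables -------------------------------------------------------

def write_newick(path: str | Path, newick: str) -> None:
    Path(path).write_text(newick.rstrip() + "\n")


def write_tsv(path: str | Path, rows: list[dict], columns: list[str] | None = None) -> None:
    if not rows:
        Path(path).write_text("")
        return
    columns = columns or list(rows[0])
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join(str(row.get(c, "")) for c in columns))
    Path(path).write_text("\n".join(lines) + "\n")


def write_json(path: str | Path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True) + "\n")
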