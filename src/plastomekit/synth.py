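"""Synthetic plastome generator, genome evolver and paired-end read simulator.

Everything is seeded and deterministic: the same spec and seed always yield
the same bytes.  Evolved genomes carry an event log whose replay on the
parent reproduces the child exactly, giving downstream stages ground truth
for deletions, pseudogene ablations and substitution divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .model import AnnotatedGenome, GeneFeature, PackingError, Quadripartite, revcomp
from .qc import ReadRecord

NUCS = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_NONSTOP_CODONS = [
    a + b + c
    for a in NUCS
    for b in NUCS
    for c in NUCS
    if a + b + c not in _STOPS
]


class ParameterError(ValueError):
    pass


class ConflictError(ValueError):
    """Structured events overlap each other."""

    def __init__(self, conflicts):
        self.conflicts = conflicts
        super().__init__(f"overlapping structured events: {conflicts}")


# ---------------------------------------------------------------------------
# plastome generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneSpec:
    """One gene to place in a region of the synthetic plastome.

    For ``kind='protein'`` the coding length is ``codons * 3`` (start and
    stop codon included); for RNA kinds ``length_nt`` is used instead.
    """

    name: str
    region: str  # LSC | SSC | IR
    codons: int = 0
    strand: int = +1
    introns: tuple[int, ...] = ()
    kind: str = "protein"
    length_nt: int = 0

    @property
    def body_length(self) -> int:
        return self.codons * 3 if self.kind == "protein" else self.length_nt

    @property
    def genomic_length(self) -> int:
        return self.body_length + sum(self.introns)


@dataclass(frozen=True)
class PlastomeSpec:
    lsc_len: int
    ssc_len: int
    ir_len: int
    gene_inventory: tuple[GeneSpec, ...] = ()
    seed: int = 0

    @property
    def total_length(self) -> int:
        return self.lsc_len + self.ssc_len + 2 * self.ir_len

    def validate(self) -> None:
        if self.ir_len < 1000:
            raise ParameterError(f"ir_len must be >= 1000, got {self.ir_len}")
        if min(self.lsc_len, self.ssc_len) <= 0:
            raise ParameterError("region lengths must be positive")
        for g in self.gene_inventory:
            if g.region not in ("LSC", "SSC", "IR"):
                raise ParameterError(f"unknown region {g.region!r} for {g.name}")
            if g.kind == "protein" and g.codons < 2:
                raise ParameterError(f"{g.name}: protein needs >= 2 codons")
            if g.kind != "protein" and g.length_nt <= 0:
                raise ParameterError(f"{g.name}: RNA gene needs length_nt > 0")
            if any(i < 4 for i in g.introns):
                raise ParameterError(f"{g.name}: introns must be >= 4 bp")


def _random_seq(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(np.array(list(NUCS))[rng.integers(0, 4, n)])


def _gene_body(rng: np.random.Generator, g: GeneSpec) -> str:
    if g.kind == "protein":
        mid = rng.integers(0, len(_NONSTOP_CODONS), g.codons - 2)
        return "ATG" + "".join(_NONSTOP_CODONS[i] for i in mid) + "TAA"
    return _random_seq(rng, g.length_nt)


def _with_introns(rng: np.random.Generator, body: str, introns: tuple[int, ...]):
    """Split a gene body into exons interleaved with random introns.

    Returns (genomic sequence on + strand, exon intervals local to the gene).
    """
    if not introns:
        return body, [(0, len(body))]
    n_ex = len(introns) + 1
    # cut points keeping every exon >= 3 bases
    usable = len(body) - 3 * n_ex
    if usable < 0:
        raise ParameterError("gene too short for its intron count")
    cuts = np.sort(rng.integers(0, usable + 1, n_ex - 1))
    sizes = np.diff(np.concatenate([[0], cuts, [usable]])) + 3
    parts, exons, seq_pos, body_pos = [], [], 0, 0
    for i, sz in enumerate(sizes):
        parts.append(body[body_pos:body_pos + sz])
        exons.append((seq_pos, seq_pos + int(sz)))
        seq_pos += int(sz)
        body_pos += int(sz)
        if i < len(introns):
            intron = "GT" + _random_seq(rng, introns[i] - 4) + "AG"
            parts.append(intron)
            seq_pos += len(intron)
    return "".join(parts), exons


def _build_region(rng, name: str, length: int, genes: list[GeneSpec]):
    """Lay genes into a region with random intergenic filler.

    Returns (sequence, features with region-local coordinates).
    """
    occupied = sum(g.genomic_length for g in genes)
    spare = length - occupied
    if spare < 0:
        raise PackingError(
            f"gene inventory overflows region {name}: "
            f"{occupied} bp of genes in {length} bp"
        )
    n_slots = len(genes) + 1
    spacers = rng.multinomial(spare, np.full(n_slots, 1.0 / n_slots))
    parts, feats, pos = [], [], 0
    for i, g in enumerate(genes):
        filler = _random_seq(rng, int(spacers[i]))
        parts.append(filler)
        pos += len(filler)
        seq, local_exons = _with_introns(rng, _gene_body(rng, g), g.introns)
        if g.strand == -1:
            glen = len(seq)
            seq = revcomp(seq)
            local_exons = [(glen - e, glen - s) for s, e in reversed(local_exons)]
        feats.append(
            GeneFeature(
                name=g.name,
                kind=g.kind,
                strand=g.strand,
                exons=tuple((pos + s, pos + e) for s, e in local_exons),
                region=name,
            )
        )
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_seq(rng, int(spacers[-1])))
    return "".join(parts), feats


def _mirror_into_ira(f: GeneFeature, irb: tuple[int, int], ira: tuple[int, int]) -> GeneFeature:
    b0, b1 = irb
    a0, _ = ira
    exons = tuple(
        (a0 + (b1 - e), a0 + (b1 - s)) for s, e in reversed(f.exons)
    )
    return GeneFeature(
        name=f.name, kind=f.kind, strand=-f.strand, exons=exons, region="IRa"
    )


def _break_ir_boundaries(seq: str, L: int, I: int, S: int, features) -> str:
    """Ensure the planted IR pair is maximal at exactly its boundaries.

    Chance complementarity of the filler bases flanking the repeats would
    let an exact-match repeat finder extend past the planted coordinates;
    adjust one intergenic base per boundary pair to break it.
    """
    exonic = set()
    for f in features:
        for s, e in f.exons:
            exonic.update(range(s, e))
    chars = list(seq)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    # (outer base, partner) pairs probed by leftward/rightward extension of
    # the true IRb/IRa pair on the circle
    pairs = [(L - 1, 0), (L + I + S - 1, L + I)]
    for a, b in pairs:
        if chars[a] == comp[chars[b]]:
            target = a if a not in exonic else b
            partner = b if target == a else a
            for c in "ACGT":
                if c != comp[chars[partner]] and c != chars[target]:
                    chars[target] = c
                    break
    return "".join(chars)


def generate_plastome(spec: PlastomeSpec, genome_id: str = "synthetic") -> AnnotatedGenome:
    """Generate a circular quadripartite plastome from a seeded spec.

    The circle is laid out as LSC + IRb + SSC + IRa with the origin at the
    first LSC base; IRa is the exact reverse complement of IRb, and genes
    declared in the IR appear as mirrored duplicates in both copies.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    by_region = {"LSC": [], "IR": [], "SSC": []}
    for g in spec.gene_inventory:
        by_region[g.region].append(g)

    lsc_seq, lsc_feats = _build_region(rng, "LSC", spec.lsc_len, by_region["LSC"])
    irb_seq, irb_feats = _build_region(rng, "IRb", spec.ir_len, by_region["IR"])
    ssc_seq, ssc_feats = _build_region(rng, "SSC", spec.ssc_len, by_region["SSC"])
    ira_seq = revcomp(irb_seq)

    L, I, S = spec.lsc_len, spec.ir_len, spec.ssc_len
    irb_iv = (L, L + I)
    ssc_iv = (L + I, L + I + S)
    ira_iv = (L + I + S, L + 2 * I + S)

    features: list[GeneFeature] = list(lsc_feats)
    features += [f.shifted(L) for f in irb_feats]
    features += [f.shifted(L + I) for f in ssc_feats]
    features += [
        _mirror_into_ira(f.shifted(L), irb_iv, ira_iv) for f in irb_feats
    ]
    features.sort(key=lambda f: f.start)

    sequence = _break_ir_boundaries(
        lsc_seq + irb_seq + ssc_seq + ira_seq, L, I, S, features
    )
    genome = AnnotatedGenome(
        id=genome_id,
        sequence=sequence,
        features=features,
        regions=Quadripartite(
            lsc=(0, L), irb=irb_iv, ssc=ssc_iv, ira=ira_iv,
            genome_length=spec.total_length,
        ),
    )
    genome.validate()
    return genome


def default_inventory(
    n_lsc: int = 82, n_ir: int = 20, n_ssc: int = 12, seed: int = 0,
    mean_codons: int = 220,
) -> tuple[GeneSpec, ...]:
    """A plausibly sized gene inventory (82 LSC + 20 IR + 12 SSC = 114)."""
    rng = np.random.default_rng(seed)
    inv = []
    counters = {"LSC": n_lsc, "IR": n_ir, "SSC": n_ssc}
    for region, n in counters.items():
        for i in range(n):
            codons = int(rng.integers(mean_codons // 2, mean_codons * 3 // 2))
            introns = (int(rng.integers(80, 200)),) if rng.random() < 0.15 else ()
            inv.append(
                GeneSpec(
                    name=f"{region.lower()}G{i:03d}",
                    region=region,
                    codons=codons,
                    strand=int(rng.choice([-1, 1])),
                    introns=introns,
                )
            )
    return tuple(inv)


# ---------------------------------------------------------------------------
# genome evolution with an event log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Event:
    """One evolutionary edit, in parent coordinates.

    kind: snp (payload = new base), deletion / pseudogene_ablation
    (interval [start, end)), small_indel (payload = inserted sequence with
    start == end, or an interval deletion with empty payload).
    """

    kind: str
    start: int
    end: int
    payload: str = ""

    @property
    def is_deletion(self) -> bool:
        return self.end > self.start and not self.payload

    @property
    def is_insertion(self) -> bool:
        return self.end == self.start and bool(self.payload)


def snp(pos: int, base: str) -> Event:
    return Event("snp", pos, pos + 1, base)


def deletion(start: int, end: int) -> Event:
    return Event("deletion", start, end)


def insertion(pos: int, seq: str) -> Event:
    return Event("small_indel", pos, pos, seq)


def ablation(start: int, end: int) -> Event:
    return Event("pseudogene_ablation", start, end)


@dataclass
class EventLog:
    parent_id: str
    child_id: str
    events: list[Event] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(
            {
                "parent_id": self.parent_id,
                "child_id": self.child_id,
                "events": [
                    {"kind": e.kind, "start": e.start, "end": e.end, "payload": e.payload}
                    for e in self.events
                ],
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventLog":
        d = json.loads(text)
        return cls(
            d["parent_id"],
            d["child_id"],
            [Event(e["kind"], e["start"], e["end"], e["payload"]) for e in d["events"]],
        )


def _event_masks(length: int, events: list[Event]):
    deleted = np.zeros(length, dtype=bool)
    subs: dict[int, str] = {}
    ins: dict[int, str] = {}
    for e in events:
        if e.kind == "snp":
            subs[e.start] = e.payload
        elif e.is_insertion:
            ins[e.start] = ins.get(e.start, "") + e.payload
        else:
            deleted[e.start:e.end] = True
    return deleted, subs, ins


def replay_events(parent_seq: str, log: EventLog) -> str:
    """Rebuild the child sequence from the parent and the event log."""
    deleted, subs, ins = _event_masks(len(parent_seq), log.events)
    out = []
    for i, base in enumerate(parent_seq):
        if i in ins:
            out.append(ins[i])
        if not deleted[i]:
            out.append(subs.get(i, base))
    if len(parent_seq) in ins:
        out.append(ins[len(parent_seq)])
    return "".join(out)


def _check_conflicts(events: list[Event], length: int) -> None:
    ivs = sorted(
        (e.start, e.end, e.kind)
        for e in events
        if e.is_deletion
    )
    conflicts = [
        (ivs[i], ivs[i + 1])
        for i in range(len(ivs) - 1)
        if ivs[i][1] > ivs[i + 1][0]
    ]
    if conflicts:
        raise ConflictError(conflicts)
    for e in events:
        if not (0 <= e.start <= e.end <= length):
            raise ParameterError(f"event outside parent coordinates: {e}")


def _lift_features(
    features: list[GeneFeature], deleted: np.ndarray, ins: dict[int, str]
) -> list[GeneFeature]:
    length = len(deleted)
    del_before = np.concatenate([[0], np.cumsum(deleted)])
    ins_positions = np.array(sorted(ins), dtype=int)
    ins_lengths = np.array([len(ins[p]) for p in sorted(ins)], dtype=int)
    ins_cum = np.concatenate([[0], np.cumsum(ins_lengths)])

    def new_pos(p: int) -> int:
        k = int(np.searchsorted(ins_positions, p, side="right"))
        return p - int(del_before[p]) + int(ins_cum[k])

    lifted = []
    for f in features:
        new_exons = []
        touched = False
        for s, e in f.exons:
            kept = np.flatnonzero(~deleted[s:e])
            if kept.size == 0:
                touched = True
                continue
            if kept.size < e - s:
                touched = True
            s2 = new_pos(s + int(kept[0]))
            e2 = new_pos(s + int(kept[-1])) + 1
            # insertions strictly inside the exon stretch it
            inside = (ins_positions > s + int(kept[0])) & (ins_positions <= s + int(kept[-1]))
            if inside.any():
                touched = True
            new_exons.append((s2, e2))
        if not new_exons:
            continue  # feature fully removed
        lifted.append(
            GeneFeature(
                name=f.name,
                kind=f.kind,
                strand=f.strand,
                exons=tuple(new_exons),
                truncated=f.truncated or touched,
                region=f.region,
            )
        )
    return lifted


def evolve_genome(
    parent: AnnotatedGenome,
    sub_rate: float = 0.0,
    indel_rate: float = 0.0,
    structured_events: list[Event] | tuple[Event, ...] = (),
    seed: int = 0,
    child_id: str | None = None,
    indel_max: int = 10,
) -> tuple[AnnotatedGenome, EventLog]:
    """Evolve a child genome from ``parent`` and log every event.

    Structured events are applied first, in the order given; stochastic
    substitutions and small indels are then drawn at the supplied per-base
    rates, never overlapping a structured deletion.  Replaying the returned
    log on the parent reproduces the child byte-for-byte.
    """
    if not (0.0 <= sub_rate <= 0.2 and 0.0 <= indel_rate <= 0.2):
        raise ParameterError("rates must lie in [0, 0.2]")
    L = len(parent.sequence)
    structured = list(structured_events)
    _check_conflicts(structured, L)
    rng = np.random.default_rng(seed)

    events = list(structured)
    deleted, subs, ins = _event_masks(L, events)

    if sub_rate > 0:
        pos = np.flatnonzero(rng.random(L) < sub_rate)
        for p in pos:
            p = int(p)
            if deleted[p] or p in subs:
                continue
            old = parent.sequence[p]
            if old not in NUCS:
                continue
            choices = [c for c in NUCS if c != old]
            events.append(snp(p, choices[int(rng.integers(0, 3))]))
    if indel_rate > 0:
        pos = np.flatnonzero(rng.random(L) < indel_rate)
        for p in pos:
            p = int(p)
            size = int(rng.integers(1, indel_max + 1))
            if rng.random() < 0.5:
                e = min(p + size, L)
                if e > p and not deleted[p:e].any():
                    events.append(Event("small_indel", p, e))
                    deleted[p:e] = True
            else:
                if p not in ins:
                    events.append(insertion(p, _random_seq(rng, size)))
                    ins[p] = "x"  # placeholder, recomputed below

    log = EventLog(parent.id, child_id or parent.id + ".child", events)
    deleted, subs, ins = _event_masks(L, events)
    child_seq = replay_events(parent.sequence, log)
    child = AnnotatedGenome(
        id=log.child_id,
        sequence=child_seq,
        features=_lift_features(parent.features, deleted, ins),
        regions=None,
    )
    return child, log


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QualityModel:
    """Position-dependent PHRED model: mean decays linearly 3'-ward."""

    q_start: float = 38.0
    q_end: float = 28.0
    sd: float = 3.0
    q_min: int = 2
    q_max: int = 40

    def sample(self, rng: np.random.Generator, n_reads: int, read_len: int) -> np.ndarray:
        means = np.linspace(self.q_start, self.q_end, read_len)
        q = rng.normal(means, self.sd, size=(n_reads, read_len))
        return np.clip(np.rint(q), self.q_min, self.q_max).astype(int)


@dataclass(frozen=True)
class TruthLabel:
    pair_id: str
    source_id: str
    category: str  # plastid | contaminant
    start: int
    insert: int
    strand: int


def simulate_reads(
    genome: AnnotatedGenome,
    n_pairs: int,
    insert_mean: int = 200,
    read_len: int = 100,
    error_rate: float = 0.0,
    contaminants: list[tuple[AnnotatedGenome, float]] | tuple = (),
    seed: int = 0,
    insert_sd: float | None = None,
    quality_model: QualityModel = QualityModel(),
) -> tuple[list[tuple[ReadRecord, ReadRecord]], list[TruthLabel]]:
    """Simulate paired-end reads from a circular genome plus contaminants.

    Fragments are sampled uniformly on the circle (wrapping the origin);
    mate 1 reads the fragment 5' end, mate 2 the reverse complement of the
    3' end.  Substitution errors are drawn i.i.d. per base at ``error_rate``.
    Every pair carries a truth label naming its source genome.
    """
    if insert_mean < read_len:
        raise ParameterError("insert_mean must be >= read_len")
    fracs = [f for _, f in contaminants]
    if any(not 0 <= f <= 1 for f in fracs) or sum(fracs) > 1 + 1e-9:
        raise ParameterError("contaminant fractions must lie in [0,1] and sum <= 1")
    if insert_sd is None:
        insert_sd = 0.1 * insert_mean

    sources = [(genome, "plastid")] + [(g, "contaminant") for g, _ in contaminants]
    probs = np.array([1.0 - sum(fracs)] + fracs)
    rng = np.random.default_rng(seed)

    src_idx = rng.choice(len(sources), size=n_pairs, p=probs)
    inserts = np.maximum(
        read_len, np.rint(rng.normal(insert_mean, insert_sd, n_pairs)).astype(int)
    )
    strands = np.where(rng.random(n_pairs) < 0.5, 1, -1)
    starts = np.empty(n_pairs, dtype=int)
    for i in range(n_pairs):
        src = sources[src_idx[i]][0]
        starts[i] = rng.integers(0, len(src.sequence))
        inserts[i] = min(inserts[i], len(src.sequence))

    quals1 = quality_model.sample(rng, n_pairs, read_len)
    quals2 = quality_model.sample(rng, n_pairs, read_len)

    pairs: list[tuple[ReadRecord, ReadRecord]] = []
    truth: list[TruthLabel] = []
    nuc_arr = np.frombuffer(b"ACGT", dtype=np.uint8)

    def _inject_errors(seq: str) -> str:
        if error_rate <= 0:
            return seq
        hits = np.flatnonzero(rng.random(len(seq)) < error_rate)
        if hits.size == 0:
            return seq
        arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
        for p in hits:
            cur = arr[p]
            alt = nuc_arr[rng.integers(0, 4)]
            while alt == cur:
                alt = nuc_arr[rng.integers(0, 4)]
            arr[p] = alt
        return arr.tobytes().decode()

    for i in range(n_pairs):
        src, category = sources[src_idx[i]]
        doubled = src.sequence + src.sequence
        frag = doubled[starts[i]: starts[i] + inserts[i]]
        if strands[i] == -1:
            frag = revcomp(frag)
        r1 = _inject_errors(frag[:read_len])
        r2 = _inject_errors(revcomp(frag[-read_len:]))
        pid = f"pair{i:07d}"
        pairs.append(
            (
                ReadRecord(f"{pid}/1", r1, list(map(int, quals1[i]))),
                ReadRecord(f"{pid}/2", r2, list(map(int, quals2[i]))),
            )
        )
        truth.append(
            TruthLabel(pid, src.id, category, int(starts[i]), int(inserts[i]), int(strands[i]))
        )
    return pairs, truth


def truth_table_rows(truth: list[TruthLabel]) -> list[dict]:
    return [
        {
            "pair_id": t.pair_id,
            "source_id": t.source_id,
            "category": t.category,
            "start": t.start,
            "insert": t.insert,
            "strand": t.strand,
        }
        for t in truth
    ]
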