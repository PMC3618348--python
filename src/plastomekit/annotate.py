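"""Homology-based annotation transfer and grass-plastome feature calls.

Gene models are transferred from an annotated reference by local alignment
of each gene's genomic span onto the target (k-mer anchored), accepting
hits above identity/coverage thresholds.  Cross-species codon-length
tables and the pseudogene / intergenic-hot-spot report are derived from
the transferred annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import Align

from ._kmers import PositionIndex
from .model import AnnotatedGenome, GeneFeature, revcomp

STOP_CODONS = {"TAA", "TAG", "TGA"}


class MissingAnchorError(ValueError):
    """A required flanking gene is not annotated on the genome."""


@dataclass
class TransferResult:
    features: list[GeneFeature]
    missing: list[str]
    notes: dict[str, str] = field(default_factory=dict)


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "local"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -7
    a.extend_gap_score = -1
    return a


def _cluster_offsets(offsets: list[int], span: int) -> list[list[int]]:
    offsets = sorted(offsets)
    clusters: list[list[int]] = [[offsets[0]]]
    for o in offsets[1:]:
        if o - clusters[-1][-1] > span:
            clusters.append([])
        clusters[-1].append(o)
    return clusters


def _map_position(blocks_q, blocks_t, qpos: int, side: str) -> int | None:
    """Project a query position through aligned blocks onto the target.

    ``side='left'`` snaps positions falling in a gap to the next aligned
    base; ``'right'`` to the previous one.
    """
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        if qs <= qpos < qe:
            return ts + (qpos - qs)
        if qpos < qs:
            return ts if side == "left" else te - 1
    if len(blocks_t) and side == "right":
        return blocks_t[-1][1] - 1
    return None


def _codon_snap(seq: str) -> tuple[bool, bool]:
    """(has proper start, has proper terminal stop) for a spliced CDS."""
    ok_start = seq.startswith("ATG")
    ok_stop = len(seq) >= 3 and len(seq) % 3 == 0 and seq[-3:] in STOP_CODONS
    return ok_start, ok_stop


def has_internal_stop(spliced: str) -> bool:
    """Internal stop codon in frame 0, terminal codon excluded."""
    n = (len(spliced) // 3) * 3
    return any(
        spliced[i:i + 3] in STOP_CODONS for i in range(0, max(0, n - 3), 3)
    )


def transfer_annotation(
    target: AnnotatedGenome,
    reference: AnnotatedGenome,
    min_identity: float = 0.8,
    min_coverage: float = 0.7,
    anchor_k: int = 21,
    pad: int = 300,
) -> TransferResult:
    """Transfer every reference gene model onto the target genome.

    Each gene's genomic span is anchored by shared k-mers, locally aligned
    against the best candidate windows, and accepted above ``min_identity``
    and ``min_coverage``.  IR-duplicated genes resolve to the copy nearest
    their relative position on the reference.  Genes without an acceptable
    hit are listed as missing.
    """
    tgt_seq = target.sequence
    index = PositionIndex(anchor_k)
    index.add_reference(target.id, tgt_seq)
    aligner = _aligner()

    out: list[GeneFeature] = []
    missing: list[str] = []
    notes: dict[str, str] = {}

    for fi, feat in enumerate(reference.features):
        gene_seq = reference.sequence[feat.start:feat.end]
        if len(gene_seq) < anchor_k:
            missing.append(feat.name)
            notes[feat.name] = "shorter than anchor k-mer"
            continue
        # collect anchor offsets per relative strand
        offsets: dict[int, list[int]] = {+1: [], -1: []}
        for q in range(0, len(gene_seq) - anchor_k + 1, anchor_k):
            kmer = gene_seq[q:q + anchor_k]
            fwd_is_canon = kmer <= revcomp(kmer)
            for _, tpos, tstrand in index.lookup(kmer):
                strand = +1 if fwd_is_canon == (tstrand == +1) else -1
                if strand == +1:
                    offsets[+1].append(tpos - q)
                else:
                    offsets[-1].append(tpos + anchor_k + q)  # segment end
        candidates = []  # (window_start, window_seq, strand)
        for strand, offs in offsets.items():
            if not offs:
                continue
            for cluster in _cluster_offsets(offs, len(gene_seq)):
                center = int(np.median(cluster))
                if strand == +1:
                    lo = max(0, center - pad)
                    hi = min(len(tgt_seq), center + len(gene_seq) + pad)
                else:
                    lo = max(0, center - len(gene_seq) - pad)
                    hi = min(len(tgt_seq), center + pad)
                candidates.append((lo, tgt_seq[lo:hi], strand, len(cluster)))
        if not candidates:
            missing.append(feat.name)
            continue
        candidates.sort(key=lambda c: -c[3])
        expected = feat.start / len(reference.sequence) * len(tgt_seq)
        best = None
        for lo, window, strand, _ in candidates[:4]:
            query = gene_seq if strand == +1 else revcomp(gene_seq)
            try:
                aln = aligner.align(window, query)[0]
            except (IndexError, ValueError):
                continue
            blocks_t, blocks_q = aln.aligned
            matches = sum(
                sum(1 for a, b in zip(window[ts:te], query[qs:qe]) if a == b)
                for (ts, te), (qs, qe) in zip(blocks_t, blocks_q)
            )
            aligned_q = sum(qe - qs for qs, qe in blocks_q)
            if aligned_q == 0:
                continue
            identity = matches / aligned_q
            coverage = (blocks_q[-1][1] - blocks_q[0][0]) / len(query)
            if identity < min_identity or coverage < min_coverage:
                continue
            dist = min(
                abs(lo - expected), len(tgt_seq) - abs(lo - expected)
            )
            key = (round(identity * coverage, 6), -dist)
            if best is None or key > best[0]:
                best = (key, lo, strand, blocks_t, blocks_q, query, identity, coverage)
        if best is None:
            missing.append(feat.name)
            continue
        _, lo, strand, blocks_t, blocks_q, query, identity, coverage = best

        # project exon boundaries (expressed in query coordinates)
        q_exons = []
        for s, e in feat.exons:
            qs, qe = s - feat.start, e - feat.start
            if strand == -1:
                qs, qe = len(query) - qe, len(query) - qs
            q_exons.append((qs, qe))
        t_exons = []
        for qs, qe in sorted(q_exons):
            ts = _map_position(blocks_q, blocks_t, qs, "left")
            te = _map_position(blocks_q, blocks_t, qe - 1, "right")
            if ts is None or te is None or te < ts:
                continue
            t_exons.append((lo + ts, lo + te + 1))
        if not t_exons:
            missing.append(feat.name)
            continue
        new_strand = feat.strand * strand
        new_feat = GeneFeature(
            name=feat.name,
            kind=feat.kind,
            strand=new_strand,
            exons=tuple(t_exons),
            region=feat.region,
        )
        truncated = False
        if feat.kind == "protein":
            spliced = new_feat.spliced(tgt_seq)
            ok_start, ok_stop = _codon_snap(spliced)
            if not (ok_start and ok_stop):
                snapped = _try_snap(new_feat, tgt_seq)
                if snapped is not None:
                    new_feat = snapped
                else:
                    truncated = True
            if coverage < 0.999 or identity < 0.999:
                spliced = new_feat.spliced(tgt_seq)
                if has_internal_stop(spliced) or len(spliced) % 3:
                    truncated = True
        if truncated:
            new_feat = GeneFeature(
                name=new_feat.name, kind=new_feat.kind, strand=new_feat.strand,
                exons=new_feat.exons, truncated=True, region=new_feat.region,
            )
        out.append(new_feat)

    out.sort(key=lambda f: f.start)
    return TransferResult(features=out, missing=missing, notes=notes)


def _try_snap(feat: GeneFeature, seq: str, slack: int = 6) -> GeneFeature | None:
    """Nudge terminal exon edges by up to ``slack`` bases to recover an
    in-frame start and stop codon."""
    exons = list(feat.exons)
    for dstart in range(0, slack + 1):
        for dend in range(0, slack + 1):
            trial = [list(e) for e in exons]
            if feat.strand == +1:
                trial[0][0] = exons[0][0] + dstart
                trial[-1][1] = exons[-1][1] - dend
            else:
                trial[-1][1] = exons[-1][1] - dstart
                trial[0][0] = exons[0][0] + dend
            if any(e[1] - e[0] <= 0 for e in trial):
                continue
            cand = GeneFeature(
                name=feat.name, kind=feat.kind, strand=feat.strand,
                exons=tuple(tuple(e) for e in trial), region=feat.region,
            )
            spliced = cand.spliced(seq)
            ok_start, ok_stop = _codon_snap(spliced)
            if ok_start and ok_stop and not has_internal_stop(spliced):
                return cand
    return None


# ---------------------------------------------------------------------------
# cross-species gene length table
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneLengthRow:
    gene: str
    lengths: dict[str, int | None]  # codons per species, None when absent
    difference: int


def gene_length_table(
    annotations: dict[str, list[GeneFeature]],
    protein_only: bool = True,
) -> list[GeneLengthRow]:
    """Per-gene codon lengths across species plus max-minus-min difference.

    Only genes whose length varies (difference > 0) are returned; absent
    genes are skipped when computing the difference.
    """
    if len(annotations) < 2:
        raise ValueError("need at least two species")
    species = list(annotations)
    genes: dict[str, dict[str, int]] = {}
    for sp, feats in annotations.items():
        for f in feats:
            if protein_only and f.kind not in ("protein", "orf", "pseudogene"):
                continue
            cur = genes.setdefault(f.name, {})
            # IR-duplicated copies share a name; keep the longer model
            cur[sp] = max(cur.get(sp, 0), f.codons)
    rows = []
    for gene in sorted(genes):
        present = [genes[gene][sp] for sp in species if sp in genes[gene]]
        diff = max(present) - min(present)
        if diff == 0:
            continue
        rows.append(
            GeneLengthRow(
                gene=gene,
                lengths={sp: genes[gene].get(sp) for sp in species},
                difference=diff,
            )
        )
    return rows


def length_difference(lengths: list[int | None]) -> int:
    """max - min over the non-absent entries of one table row."""
    present = [x for x in lengths if x is not None]
    return max(present) - min(present)


# ---------------------------------------------------------------------------
# grass-specific feature calls
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureReport:
    rpoc2_insertion_len: int | None
    rpl23_remnant: bool
    accd_status: str  # present | pseudo | absent
    rbcl_psai_len: int
    notes: tuple[str, ...] = ()


def _feature_by_name(features: list[GeneFeature], name: str) -> GeneFeature | None:
    for f in features:
        if f.name == name:
            return f
    return None


def call_grass_features(
    genome: AnnotatedGenome,
    features: list[GeneFeature] | None = None,
    flank_library: dict[str, str] | None = None,
    remnant_names: tuple[str, ...] = ("rpl23", "rpl32"),
    accd_name: str = "accD",
    accd_reference_codons: int | None = None,
) -> FeatureReport:
    """Call the variable grass-plastome features on one annotated genome.

    The intergenic hot-spot is the half-open interval between the end of
    rbcL and the start of psaI on the canonical strand.  A remnant call
    requires an annotated rpl23/rpl32-homologous feature inside that
    interval.  accD is 'pseudo' when a model exists but its ORF is
    incomplete (internal stop, missing start/stop, frame break, truncation
    or < 70% of the reference length), 'absent' when no model exists.
    """
    feats = genome.features if features is None else features
    notes: list[str] = []
    rbcl = _feature_by_name(feats, "rbcL")
    psai = _feature_by_name(feats, "psaI")
    if rbcl is None or psai is None:
        raise MissingAnchorError(
            "rbcL and psaI must both be annotated to define the hot-spot region"
        )
    if rbcl.end <= psai.start:
        region = (rbcl.end, psai.start)
    else:
        region = (psai.end, rbcl.start)
    rbcl_psai_len = max(0, region[1] - region[0])

    remnant = False
    for f in feats:
        if any(q.lower() in f.name.lower() for q in remnant_names):
            if region[0] <= f.start and f.end <= region[1]:
                remnant = True
                notes.append(f"remnant feature {f.name} inside hot-spot region")

    accd = _feature_by_name(feats, accd_name)
    if accd is None:
        accd_status = "absent"
    else:
        spliced = accd.spliced(genome.sequence)
        ok_start, ok_stop = _codon_snap(spliced)
        incomplete = []
        if has_internal_stop(spliced):
            incomplete.append("internal_stop")
        if not ok_start:
            incomplete.append("missing_start")
        if not ok_stop:
            incomplete.append("missing_stop")
        if accd.truncated:
            incomplete.append("truncated_transfer")
        if (
            accd_reference_codons
            and accd.codons < 0.7 * accd_reference_codons
        ):
            incomplete.append("short_model")
        accd_status = "pseudo" if incomplete else "present"
        if incomplete:
            notes.append("accD incomplete: " + ",".join(incomplete))

    rpoc2_len: int | None = None
    if flank_library and "rpoc2_left" in flank_library and "rpoc2_right" in flank_library:
        rpoc2_len = _anchored_insertion_length(
            genome.sequence, flank_library["rpoc2_left"], flank_library["rpoc2_right"]
        )
        if rpoc2_len is None:
            notes.append("rpoc2 flank anchors not found on either strand")
    else:
        notes.append("rpoc2 flank anchors not supplied")

    return FeatureReport(
        rpoc2_insertion_len=rpoc2_len,
        rpl23_remnant=remnant,
        accd_status=accd_status,
        rbcl_psai_len=rbcl_psai_len,
        notes=tuple(notes),
    )


def _anchored_insertion_length(seq: str, left: str, right: str) -> int | None:
    for s in (seq, revcomp(seq)):
        i = s.find(left)
        if i == -1:
            continue
        j = s.find(right, i + len(left))
        if j == -1:
            continue
        return j - (i + len(left))
    return None
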