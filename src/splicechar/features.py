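"""Per-item feature vectors for events and control constructs.

For a retained intron (or E-I-E control) the focal item is the intron:
donor/acceptor strength at its own splice sites, length, GC, branch-point
distance, and — when CDS context exists — the coding consequence of
retaining it.  For a skipped exon (or E-I-E-I-E control) the focal item is
the exon: its own donor and acceptor, the outer flanking sites, and the
lengths/GC/branch points of both flanking introns.

"Upstream"/"downstream" are always in transcript orientation (5' -> 3' of
the mRNA), so every feature is invariant under mirroring the genome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

from .annotation import GenomeSequence, TranscriptModel, get_sequence
from .controls import ControlConstruct
from .events import SpliceEvent
from .splice_scoring import (
    SpliceSiteModel,
    acceptor_window_interval,
    donor_window_interval,
    find_branch_point,
)

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}

# coding consequences of retaining an intron
IN_FRAME_STOP = "in_frame_stop"
FRAMESHIFT_PTC = "frameshift_ptc_downstream"
NO_PTC = "no_ptc"
FRAME_UNAVAILABLE = "frame_unavailable"


@dataclass
class FeatureVector:
    """Measurements for one event or control item."""

    item_id: str
    group: str  # IRI/DRI/ISE/DSE/ICI/ECI/ICE/ECE
    gene_id: str = ""
    chrom: str = ""
    strand: str = "+"
    donor_score: float | None = None
    acceptor_score: float | None = None
    upstream_donor_score: float | None = None  # SE only
    downstream_acceptor_score: float | None = None  # SE only
    focal_length: int | None = None
    focal_gc: float | None = None
    upstream_exon_len: int | None = None  # RI
    downstream_exon_len: int | None = None  # RI
    upstream_intron_len: int | None = None  # SE
    downstream_intron_len: int | None = None  # SE
    upstream_intron_gc: float | None = None  # SE
    downstream_intron_gc: float | None = None  # SE
    bp_offset: int | None = None  # RI focal intron
    bp_offset_upstream: int | None = None  # SE
    bp_offset_downstream: int | None = None  # SE
    ri_consequence: str | None = None  # RI
    has_n: bool = False  # any scoring window contained N

    def to_dict(self) -> dict:
        return asdict(self)


def gc_content(seq: str) -> float:
    """G+C fraction over unambiguous bases; N excluded from both numerator
    and denominator.  Empty or all-N input is an error."""
    if not seq:
        raise ValueError("empty sequence")
    counts = {b: seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise ValueError("sequence has no unambiguous bases")
    return (counts["G"] + counts["C"]) / denom


def _score_window(
    genome: GenomeSequence,
    chrom: str,
    interval: tuple[int, int],
    strand: str,
    model: SpliceSiteModel,
) -> tuple[float | None, bool]:
    """Score one site window; (None, True) when the window has N or falls
    outside the chromosome."""
    lo, hi = interval
    if lo < 0 or hi > genome.lengths[chrom]:
        return None, True
    seq = get_sequence(genome, chrom, interval, strand)
    if "N" in seq:
        return None, True
    return model.score(seq), False


def classify_ri_consequence(
    transcript: TranscriptModel, intron: tuple[int, int], genome: GenomeSequence
) -> str:
    """Coding consequence of retaining an annotated intron.

    Returns ``frame_unavailable`` when the transcript lacks CDS or the
    intron lies outside the CDS span.  Otherwise the reading frame at the
    insertion point is computed from the CDS annotation and the retained
    sequence is scanned codon by codon: a stop codon overlapping the intron
    gives ``in_frame_stop``; with a frame-shifting intron length a stop
    strictly before the annotated CDS end gives
    ``frameshift_ptc_downstream``; otherwise ``no_ptc``.
    """
    if intron not in transcript.introns:
        raise ValueError(
            f"{intron} is not an annotated intron of {transcript.transcript_id}"
        )
    cds = transcript.cds
    if not cds:
        return FRAME_UNAVAILABLE
    cds_lo = min(s for s, _ in cds)
    cds_hi = max(e for _, e in cds)
    s, e = intron
    if s < cds_lo or e > cds_hi:
        return FRAME_UNAVAILABLE

    strand = transcript.strand
    chrom = transcript.chrom
    # coding nt strictly transcript-5' of the intron
    if strand == "+":
        upstream_len = sum(max(0, min(ce, s) - cs) for cs, ce in cds)
    else:
        upstream_len = sum(max(0, ce - max(cs, e)) for cs, ce in cds)
    phase = upstream_len % 3  # nt already consumed of the current codon
    # the last `phase` coding nt before the intron (straddle-codon prefix)
    if phase:
        if strand == "+":
            tail = get_sequence(genome, chrom, (s - phase, s), "+")
        else:
            tail = get_sequence(genome, chrom, (e, e + phase), "-")
    else:
        tail = ""
    intron_seq = get_sequence(genome, chrom, intron, strand)
    # downstream coding sequence, transcript order, to the annotated CDS end
    down_parts = []
    for cs, ce in sorted(cds, reverse=(strand == "-")):
        if strand == "+":
            lo, hi = max(cs, e), ce
        else:
            lo, hi = cs, min(ce, s)
        if lo < hi:
            down_parts.append(get_sequence(genome, chrom, (lo, hi), strand))
    reading = tail + intron_seq + "".join(down_parts)

    intron_start = len(tail)
    intron_end = intron_start + len(intron_seq)
    for j in range(0, len(reading) - 2, 3):
        codon = reading[j : j + 3]
        if codon in STOP_CODONS:
            if j < intron_end and j + 3 > intron_start:
                return IN_FRAME_STOP
            if len(intron_seq) % 3 == 0:
                return NO_PTC
            # frame-shifted downstream stop; one ending exactly at the CDS
            # end sits at the normal termination point and is not premature
            return FRAMESHIFT_PTC if j + 3 < len(reading) else NO_PTC
    return NO_PTC


def _resolve_ri_segments(item, genes_by_id=None):
    """(chrom, strand, E_up, intron, E_down, transcript) in transcript
    orientation for an RI event or E-I-E construct."""
    if isinstance(item, ControlConstruct):
        segs = item.segments_transcript_order()
        (_, e_up), (_, intron), (_, e_down) = segs
        tx = None
        if genes_by_id and item.source_gene in genes_by_id:
            for t in genes_by_id[item.source_gene].transcripts:
                if t.transcript_id == item.source_transcript:
                    tx = t
                    break
        return item.chrom, item.strand, e_up, intron, e_down, tx
    ev: SpliceEvent = item
    up = ev.coords["upstream_exon"]
    down = ev.coords["downstream_exon"]
    left, right = sorted([up, down])
    intron = (left[1], right[0])
    return ev.chrom, ev.strand, up, intron, down, None


def extract_ri_features(
    item,
    group: str,
    genome: GenomeSequence,
    donor_model: SpliceSiteModel,
    acceptor_model: SpliceSiteModel,
    genes_by_id: dict | None = None,
    reference_transcripts: dict | None = None,
    bp_params: dict | None = None,
    item_id: str | None = None,
) -> FeatureVector:
    """Feature vector for a retained-intron event or an E-I-E control."""
    bp_params = bp_params or {}
    chrom, strand, e_up, intron, e_down, tx = _resolve_ri_segments(item, genes_by_id)
    if isinstance(item, SpliceEvent):
        item_id = item_id or item.event_id
        gene_id = item.gene_id
        if reference_transcripts:
            tx = reference_transcripts.get(gene_id)
    else:
        item_id = item_id or f"{item.origin}:{item.shape}:{item.source_gene}"
        gene_id = item.source_gene

    fv = FeatureVector(item_id=item_id, group=group, gene_id=gene_id,
                       chrom=chrom, strand=strand)
    fv.donor_score, n1 = _score_window(
        genome, chrom, donor_window_interval(intron, strand), strand, donor_model
    )
    fv.acceptor_score, n2 = _score_window(
        genome, chrom, acceptor_window_interval(intron, strand), strand, acceptor_model
    )
    fv.has_n = n1 or n2
    intron_seq = get_sequence(genome, chrom, intron, strand)
    fv.focal_length = len(intron_seq)
    fv.focal_gc = gc_content(intron_seq)
    fv.upstream_exon_len = e_up[1] - e_up[0]
    fv.downstream_exon_len = e_down[1] - e_down[0]
    bp = find_branch_point(intron_seq, **bp_params)
    fv.bp_offset = bp.bp_offset if bp else None
    if tx is not None and intron in tx.introns:
        fv.ri_consequence = classify_ri_consequence(tx, intron, genome)
    else:
        fv.ri_consequence = FRAME_UNAVAILABLE
    return fv


def _resolve_se_segments(item):
    """(chrom, strand, E_up, I_up, E_focal, I_down, E_down), transcript
    orientation, for an SE event or E-I-E-I-E construct."""
    if isinstance(item, ControlConstruct):
        segs = item.segments_transcript_order()
        (_, e_up), (_, i_up), (_, e_f), (_, i_down), (_, e_down) = segs
        return item.chrom, item.strand, e_up, i_up, e_f, i_down, e_down
    ev: SpliceEvent = item
    e_up = ev.coords["upstream_exon"]
    e_f = ev.coords["skipped_exon"]
    e_down = ev.coords["downstream_exon"]
    exons = sorted([e_up, e_f, e_down])
    gaps = [(exons[0][1], exons[1][0]), (exons[1][1], exons[2][0])]
    if ev.strand == "+":
        i_up, i_down = gaps
    else:
        i_down, i_up = gaps
    return ev.chrom, ev.strand, e_up, i_up, e_f, i_down, e_down


def extract_se_features(
    item,
    group: str,
    genome: GenomeSequence,
    donor_model: SpliceSiteModel,
    acceptor_model: SpliceSiteModel,
    bp_params: dict | None = None,
    item_id: str | None = None,
) -> FeatureVector:
    """Feature vector for a skipped-exon event or an E-I-E-I-E control."""
    bp_params = bp_params or {}
    chrom, strand, e_up, i_up, e_f, i_down, e_down = _resolve_se_segments(item)
    if isinstance(item, SpliceEvent):
        item_id = item_id or item.event_id
        gene_id = item.gene_id
    else:
        item_id = item_id or f"{item.origin}:{item.shape}:{item.source_gene}"
        gene_id = item.source_gene

    fv = FeatureVector(item_id=item_id, group=group, gene_id=gene_id,
                       chrom=chrom, strand=strand)
    flags = []
    # the focal exon's own sites: donor feeds the downstream intron,
    # acceptor terminates the upstream intron
    fv.donor_score, f1 = _score_window(
        genome, chrom, donor_window_interval(i_down, strand), strand, donor_model
    )
    fv.acceptor_score, f2 = _score_window(
        genome, chrom, acceptor_window_interval(i_up, strand), strand, acceptor_model
    )
    fv.upstream_donor_score, f3 = _score_window(
        genome, chrom, donor_window_interval(i_up, strand), strand, donor_model
    )
    fv.downstream_acceptor_score, f4 = _score_window(
        genome, chrom, acceptor_window_interval(i_down, strand), strand, acceptor_model
    )
    fv.has_n = any([f1, f2, f3, f4])

    focal_seq = get_sequence(genome, chrom, e_f, strand)
    fv.focal_length = len(focal_seq)
    fv.focal_gc = gc_content(focal_seq)
    up_seq = get_sequence(genome, chrom, i_up, strand)
    down_seq = get_sequence(genome, chrom, i_down, strand)
    fv.upstream_intron_len = len(up_seq)
    fv.downstream_intron_len = len(down_seq)
    fv.upstream_intron_gc = gc_content(up_seq)
    fv.downstream_intron_gc = gc_content(down_seq)
    bp_up = find_branch_point(up_seq, **bp_params)
    bp_down = find_branch_point(down_seq, **bp_params)
    fv.bp_offset_upstream = bp_up.bp_offset if bp_up else None
    fv.bp_offset_downstream = bp_down.bp_offset if bp_down else None
    return fv
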