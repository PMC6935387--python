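"""Matched control constructs for mis-splicing feature comparisons.

Two background sets are built for each event class:

* **internal** controls — exon-intron-exon (E-I-E, matched to retained
  introns) or exon-intron-exon-intron-exon (E-I-E-I-E, matched to skipped
  exons) windows drawn from elsewhere in the *same* gene's reference
  transcript, excluding anything overlapping the gene's own event
  footprints;
* **external** controls — the same shapes drawn from the reference
  transcripts of the most highly expressed genes that are neither
  mitochondrial nor present in any filtered event table.

One construct is sampled uniformly per transcript from the pool of valid
windows, under a caller-supplied seeded random stream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import GeneModel, TranscriptModel, select_reference_transcript
from .events import SpliceEvent

log = logging.getLogger(__name__)

SHAPE_EIE = "EIE"
SHAPE_EIEIE = "EIEIE"

# number of exons a transcript needs to host at least one window
_MIN_EXONS = {SHAPE_EIE: 2, SHAPE_EIEIE: 3}
_ROLES = {
    SHAPE_EIE: ("exon", "intron", "exon"),
    SHAPE_EIEIE: ("exon", "intron", "exon", "intron", "exon"),
}
# index of the focal segment: the intron of an E-I-E, the middle exon of an
# E-I-E-I-E
FOCAL_INDEX = {SHAPE_EIE: 1, SHAPE_EIEIE: 2}


@dataclass
class ControlConstruct:
    """An E-I-E or E-I-E-I-E segment chain from one transcript.

    ``segments`` are (role, [start, end)) in genomic order, alternating
    exon/intron and abutting; ``focal_index`` points at the focal intron
    (EIE) or focal exon (EIEIE).
    """

    shape: str
    origin: str  # "internal" | "external"
    source_gene: str
    source_transcript: str
    chrom: str
    strand: str
    segments: list[tuple[str, tuple[int, int]]]
    focal_index: int

    @property
    def span(self) -> tuple[int, int]:
        return (self.segments[0][1][0], self.segments[-1][1][1])

    def segments_transcript_order(self) -> list[tuple[str, tuple[int, int]]]:
        return self.segments if self.strand == "+" else list(reversed(self.segments))


def event_footprints(events: list[SpliceEvent]) -> list[tuple[int, int]]:
    """Genomic span of each event's own E-I-E / E-I-E-I-E footprint.

    For RI and SE the rMATS flank coordinates delimit the footprint exactly;
    for A5SS/A3SS/MXE the span from leftmost to rightmost coordinate is used.
    """
    return [ev.span() for ev in events]


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _windows(transcript: TranscriptModel, shape: str):
    """All consecutive exon/intron windows of the shape.

    Windows are yielded in transcript (5'->3') order — a strand-symmetric
    enumeration, so seeded sampling picks the same window on a
    mirror-image annotation — while each window's segments stay in genomic
    order."""
    exons = transcript.exons
    introns = transcript.introns
    n_ex = len(exons)
    need = _MIN_EXONS[shape]
    starts = range(n_ex - need + 1)
    if transcript.strand == "-":
        starts = reversed(starts)
    for i in starts:
        if shape == SHAPE_EIE:
            segs = [("exon", exons[i]), ("intron", introns[i]), ("exon", exons[i + 1])]
        else:
            segs = [
                ("exon", exons[i]),
                ("intron", introns[i]),
                ("exon", exons[i + 1]),
                ("intron", introns[i + 1]),
                ("exon", exons[i + 2]),
            ]
        yield segs


def enumerate_internal_candidates(
    transcript: TranscriptModel,
    footprints: list[tuple[int, int]],
    shape: str,
    gene_id: str | None = None,
) -> list[ControlConstruct]:
    """Every within-gene window of the shape that overlaps no event footprint.

    An empty list is a valid outcome (low exon number or dense events make
    construct generation impossible for some transcripts).
    """
    out = []
    for segs in _windows(transcript, shape):
        span = (segs[0][1][0], segs[-1][1][1])
        if any(_overlaps(span, fp) for fp in footprints):
            continue
        out.append(
            ControlConstruct(
                shape=shape,
                origin="internal",
                source_gene=gene_id or transcript.gene_id,
                source_transcript=transcript.transcript_id,
                chrom=transcript.chrom,
                strand=transcript.strand,
                segments=segs,
                focal_index=FOCAL_INDEX[shape],
            )
        )
    return out


def sample_one(
    candidates: list[ControlConstruct], rng: np.random.Generator
) -> ControlConstruct | None:
    """Uniform choice from the candidate pool under the seeded stream."""
    if not candidates:
        return None
    return candidates[int(rng.integers(len(candidates)))]


def load_expression(path) -> pd.DataFrame:
    """Two-column gene expression TSV (gene_id, expression), header required."""
    df = pd.read_csv(path, sep="\t")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, expression")
    df = df.rename(columns={df.columns[0]: "gene_id", df.columns[1]: "expression"})
    df["expression"] = df["expression"].astype(float)
    if (df["expression"] < 0).any():
        raise ValueError(f"{path}: negative expression values")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_id")
    return df[["gene_id", "expression"]]


def select_external_genes(
    expr: pd.DataFrame,
    genes_by_id: dict[str, GeneModel],
    excluded_gene_ids: set[str],
    shape: str,
    n: int = 1200,
) -> list[str]:
    """Top-``n`` expressed genes usable as external controls.

    Excludes mitochondrial genes, genes present in any filtered event table,
    genes without a qualifying reference transcript, and — for the E-I-E-I-E
    shape — genes whose reference transcript has fewer than three exons.
    Expression ties break lexicographically by gene_id for determinism.
    """
    ranked = expr.sort_values(
        ["expression", "gene_id"], ascending=[False, True]
    )["gene_id"]
    out: list[str] = []
    for gid in ranked:
        if gid in excluded_gene_ids:
            continue
        gene = genes_by_id.get(gid)
        if gene is None or gene.is_mitochondrial:
            continue
        ref = select_reference_transcript(gene)
        if ref is None:
            continue
        if shape == SHAPE_EIEIE and len(ref.exons) < 3:
            continue
        out.append(gid)
        if len(out) == n:
            return out
    log.warning(
        "external pool for %s: only %d of requested %d genes available",
        shape,
        len(out),
        n,
    )
    return out


def build_external_controls(
    gene_ids: list[str],
    genes_by_id: dict[str, GeneModel],
    shape: str,
    rng: np.random.Generator,
) -> list[ControlConstruct]:
    """One uniformly sampled window of the shape per external gene.

    No footprint exclusion applies (these genes carry no events); genes
    whose reference transcript yields no window are skipped with a warning.
    """
    out = []
    n_skipped = 0
    for gid in gene_ids:
        ref = select_reference_transcript(genes_by_id[gid])
        candidates = [
            ControlConstruct(
                shape=shape,
                origin="external",
                source_gene=gid,
                source_transcript=ref.transcript_id,
                chrom=ref.chrom,
                strand=ref.strand,
                segments=segs,
                focal_index=FOCAL_INDEX[shape],
            )
            for segs in _windows(ref, shape)
        ]
        pick = sample_one(candidates, rng)
        if pick is None:
            n_skipped += 1
            continue
        out.append(pick)
    if n_skipped:
        log.warning("%d external genes yielded no %s window; skipped", n_skipped, shape)
    return out


def constructs_to_frame(constructs: list[ControlConstruct]) -> pd.DataFrame:
    """Flatten constructs to a TSV-ready table (one row per construct)."""
    rows = []
    for i, c in enumerate(constructs):
        rows.append(
            {
                "construct_id": f"{c.origin}:{c.shape}:{i}",
                "shape": c.shape,
                "origin": c.origin,
                "gene_id": c.source_gene,
                "transcript_id": c.source_transcript,
                "chrom": c.chrom,
                "strand": c.strand,
                "segments": ";".join(
                    f"{role}:{s}-{e}" for role, (s, e) in c.segments
                ),
                "focal_index": c.focal_index,
            }
        )
    return pd.DataFrame(rows)
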