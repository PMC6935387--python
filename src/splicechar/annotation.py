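"""Genome and gene-annotation handling.

Loads a genome FASTA and a Gencode-style GTF into light-weight transcript
models, selects each gene's reference transcript (longest protein-coding
transcript that carries a transcript support level), and extracts
strand-aware sequence.

All internal coordinates are 0-based half-open ``[start, end)``; conversion
to/from the GTF 1-based closed convention happens only at file boundaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO

log = logging.getLogger(__name__)

#: chromosome names treated as the mitochondrial genome (configurable per call)
MITO_NAMES = frozenset({"chrM", "MT", "chrMT"})

_VALID_BASES = frozenset("ACGTN")


@dataclass
class GenomeSequence:
    """In-memory genome: chromosome name -> uppercase A/C/G/T/N string."""

    records: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {name: len(seq) for name, seq in self.records.items()}


@dataclass
class TranscriptModel:
    """One transcript's exon/intron/CDS structure on a strand.

    ``exons`` are [start, end) genomic intervals, strictly sorted and
    non-overlapping; introns are the gaps between consecutive exons.
    ``cds`` intervals (if any) are each contained in an exon.
    """

    gene_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] | None = None
    biotype: str = ""
    tsl: int | None = None

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    def exons_transcript_order(self) -> list[tuple[int, int]]:
        return self.exons if self.strand == "+" else list(reversed(self.exons))

    def introns_transcript_order(self) -> list[tuple[int, int]]:
        ints = self.introns
        return ints if self.strand == "+" else list(reversed(ints))

    def cds_transcript_order(self) -> list[tuple[int, int]]:
        if not self.cds:
            return []
        srt = sorted(self.cds)
        return srt if self.strand == "+" else list(reversed(srt))


@dataclass
class GeneModel:
    """A gene and its transcripts."""

    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    biotype: str
    transcripts: list[TranscriptModel]
    is_mitochondrial: bool = False


def load_genome(fasta_path) -> GenomeSequence:
    """Read a (multi-)FASTA into a :class:`GenomeSequence`.

    Sequences are uppercased; IUPAC ambiguity codes other than N are mapped
    to N with a warning.  Duplicate record names and empty files are errors.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in records:
            raise ValueError(f"duplicate FASTA record name: {rec.id!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _VALID_BASES
        if bad:
            log.warning(
                "record %s: mapping ambiguity codes %s to N", rec.id, sorted(bad)
            )
            seq = "".join(b if b in _VALID_BASES else "N" for b in seq)
        records[rec.id] = seq
    if not records:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return GenomeSequence(records=records)


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def get_sequence(
    genome: GenomeSequence, chrom: str, interval: tuple[int, int], strand: str = "+"
) -> str:
    """Extract ``[start, end)`` from a chromosome; minus strand returns the
    reverse complement (i.e. the transcribed sequence 5'->3')."""
    start, end = interval
    if chrom not in genome.records:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if start < 0 or end > genome.lengths[chrom] or start > end:
        raise ValueError(
            f"interval [{start},{end}) out of bounds for {chrom} "
            f"(length {genome.lengths[chrom]})"
        )
    sub = genome.records[chrom][start:end]
    return sub if strand == "+" else reverse_complement(sub)


def _parse_tsl(raw: str | None) -> int | None:
    if raw is None:
        return None
    tok = str(raw).strip().split()[0] if str(raw).strip() else ""
    try:
        val = int(tok)
    except ValueError:
        return None
    return val if 1 <= val <= 5 else None


def load_annotation(gtf_path, mito_names=MITO_NAMES) -> list[GeneModel]:
    """Load a GTF into one :class:`GeneModel` per gene_id.

    Exon intervals are converted from the GTF 1-based closed convention to
    0-based half-open.  Transcripts without any exon are dropped with a
    warning.  An exon line lacking transcript_id, or with end < start, is a
    hard error.
    """
    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )

    # transcript-level metadata and interval accumulation
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_cds: dict[str, list[tuple[int, int]]] = {}
    tx_meta: dict[str, dict] = {}

    def _attr(feat, key, default=None):
        vals = feat.attributes.get(key)
        return vals[0] if vals else default

    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS"):
            continue
        if feat.end < feat.start:
            raise ValueError(
                f"{feat.featuretype} with end < start at {feat.seqid}:{feat.start}"
            )
        tid = _attr(feat, "transcript_id")
        if tid is None:
            raise ValueError(
                f"{feat.featuretype} line without transcript_id at "
                f"{feat.seqid}:{feat.start}-{feat.end}"
            )
        gid = _attr(feat, "gene_id")
        if gid is None:
            raise ValueError(f"feature without gene_id (transcript {tid})")
        iv = (feat.start - 1, feat.end)  # GTF 1-based closed -> half-open
        if feat.featuretype == "exon":
            tx_exons.setdefault(tid, []).append(iv)
        else:
            tx_cds.setdefault(tid, []).append(iv)
        if tid not in tx_meta:
            tx_meta[tid] = {
                "gene_id": gid,
                "chrom": feat.seqid,
                "strand": feat.strand,
                "biotype": _attr(feat, "transcript_type")
                or _attr(feat, "transcript_biotype", ""),
                "tsl": _parse_tsl(_attr(feat, "transcript_support_level")),
                "gene_name": _attr(feat, "gene_name", gid),
                "gene_type": _attr(feat, "gene_type")
                or _attr(feat, "gene_biotype", ""),
            }

    genes: dict[str, GeneModel] = {}
    for tid, meta in tx_meta.items():
        exons = sorted(tx_exons.get(tid, []))
        if not exons:
            log.warning("transcript %s has no exons; dropped", tid)
            continue
        tm = TranscriptModel(
            gene_id=meta["gene_id"],
            transcript_id=tid,
            chrom=meta["chrom"],
            strand=meta["strand"],
            exons=exons,
            cds=sorted(tx_cds[tid]) if tid in tx_cds else None,
            biotype=meta["biotype"],
            tsl=meta["tsl"],
        )
        gid = meta["gene_id"]
        if gid not in genes:
            genes[gid] = GeneModel(
                gene_id=gid,
                gene_name=meta["gene_name"],
                chrom=meta["chrom"],
                strand=meta["strand"],
                biotype=meta["gene_type"],
                transcripts=[],
                is_mitochondrial=meta["chrom"] in mito_names,
            )
        genes[gid].transcripts.append(tm)

    for g in genes.values():
        g.transcripts.sort(key=lambda t: t.transcript_id)
    return list(genes.values())


def select_reference_transcript(gene: GeneModel) -> TranscriptModel | None:
    """The gene's longest protein-coding transcript that has a transcript
    support level.

    "Longest" is summed exon (mature transcript) length; ties break by lowest
    TSL, then lexicographically smallest transcript_id.  Returns ``None``
    when no transcript qualifies (no protein-coding transcript with a parsed
    TSL 1-5).
    """
    candidates = [
        t
        for t in gene.transcripts
        if t.biotype == "protein_coding" and t.tsl is not None
    ]
    if not candidates:
        return None
    return min(
        candidates, key=lambda t: (-t.spliced_length, t.tsl, t.transcript_id)
    )


def transcripts_to_gtf_lines(genes: list[GeneModel]) -> list[str]:
    """Serialize gene models back to GTF lines (exon + CDS features only).

    Used for round-trip checks and by the synthetic-data writer.
    """
    lines = []
    for g in genes:
        for t in g.transcripts:
            attrs_common = (
                f'gene_id "{g.gene_id}"; transcript_id "{t.transcript_id}"; '
                f'gene_type "{g.biotype}"; gene_name "{g.gene_name}"; '
                f'transcript_type "{t.biotype}";'
            )
            if t.tsl is not None:
                attrs_common += f' transcript_support_level "{t.tsl}";'
            for i, (s, e) in enumerate(t.exons, 1):
                lines.append(
                    f"{t.chrom}\tsplicechar\texon\t{s + 1}\t{e}\t.\t{t.strand}\t."
                    f"\t{attrs_common} exon_number {i};"
                )
            for s, e in t.cds or []:
                lines.append(
                    f"{t.chrom}\tsplicechar\tCDS\t{s + 1}\t{e}\t.\t{t.strand}\t0"
                    f"\t{attrs_common}"
                )
    return lines
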