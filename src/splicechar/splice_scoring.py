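"""Splice-site strength and branch-point scoring.

Donor and acceptor sites are scored with positional log-odds models trained
on the supplied annotation's own introns.  Window conventions follow the
MaxEntScan tools so published score tables can be plugged in unchanged:

* donor: 9 nt = last 3 exonic + first 6 intronic nt;
* acceptor: 23 nt = last 20 intronic + first 3 exonic nt.

The trained model is a first-order positional model: the score of a window
is ``sum_p log2(probs[p][base_p] / background[base_p])`` in bits.  This is a
calibrated monotone measure of site strength suitable for group
comparisons; it does not reproduce MaxEntScan's maximum-entropy dependency
decomposition (an optional lookup-table mode provides exact parity when the
published tables are supplied).

Branch points are called with a fixed 7-position consensus weight matrix
(branch adenosine at position 5 of the 7-mer, i.e. the window is the 5 nt
upstream of the A, the A, and 1 nt downstream) combined with a
polypyrimidine-tract term, searching a configurable window upstream of the
3' splice site.  The reported quantity is the BPS-3'SS distance: the number
of nucleotides strictly 3' of the branch A.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)

DONOR_EXONIC = 3
DONOR_INTRONIC = 6
DONOR_WINDOW = DONOR_EXONIC + DONOR_INTRONIC  # 9
ACCEPTOR_INTRONIC = 20
ACCEPTOR_EXONIC = 3
ACCEPTOR_WINDOW = ACCEPTOR_INTRONIC + ACCEPTOR_EXONIC  # 23

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

# Branch-point consensus weights (probabilities), 7 positions with the branch
# adenosine at index 5 — a yUnAy/TACTAAC-style consensus.  Versioned with the
# package; position 5 keeps a small floor off-A so scores stay finite.
BP_CONSENSUS = np.array(
    [
        #  A     C     G     T
        [0.15, 0.30, 0.15, 0.40],  # -5
        [0.30, 0.25, 0.15, 0.30],  # -4
        [0.10, 0.45, 0.15, 0.30],  # -3
        [0.15, 0.20, 0.15, 0.50],  # -2
        [0.45, 0.15, 0.25, 0.15],  # -1 (R)
        [0.97, 0.01, 0.01, 0.01],  # branch A
        [0.15, 0.40, 0.15, 0.30],  # +1
    ]
)
BP_BRANCH_INDEX = 5  # index of the branch A within the 7-mer window

UNIFORM_BACKGROUND = {b: 0.25 for b in BASES}


@dataclass
class SpliceSiteModel:
    """Positional log-odds model for donor or acceptor windows."""

    site_kind: str  # "donor" | "acceptor"
    counts: np.ndarray  # (window, 4) raw base counts
    probs: np.ndarray  # (window, 4) pseudocount-smoothed probabilities
    background: dict[str, float]
    pseudocount: float
    n_training: int

    @property
    def window(self) -> int:
        return self.probs.shape[0]

    def score(self, window_seq: str) -> float:
        return score_site(self, window_seq)


def window_length(site_kind: str) -> int:
    if site_kind == "donor":
        return DONOR_WINDOW
    if site_kind == "acceptor":
        return ACCEPTOR_WINDOW
    raise ValueError(f"unknown site kind {site_kind!r}")


def donor_window_interval(intron: tuple[int, int], strand: str) -> tuple[int, int]:
    """Genomic interval of the 9-nt donor window around an intron's 5' end."""
    s, e = intron
    if strand == "+":
        return (s - DONOR_EXONIC, s + DONOR_INTRONIC)
    return (e - DONOR_INTRONIC, e + DONOR_EXONIC)


def acceptor_window_interval(intron: tuple[int, int], strand: str) -> tuple[int, int]:
    """Genomic interval of the 23-nt acceptor window around an intron's 3' end."""
    s, e = intron
    if strand == "+":
        return (e - ACCEPTOR_INTRONIC, e + ACCEPTOR_EXONIC)
    return (s - ACCEPTOR_EXONIC, s + ACCEPTOR_INTRONIC)


def collect_training_sites(
    genes, genome, site_kind: str, require_canonical: bool = True
) -> list[str]:
    """Donor or acceptor windows from every intron of every gene's reference
    transcript, unique by (chrom, strand, intron coordinates).

    Windows containing N, or from introns shorter than the intronic part of
    the window, are skipped; non-GT..AG introns are skipped when
    ``require_canonical`` (counts logged).
    """
    from .annotation import get_sequence, select_reference_transcript

    min_intron = DONOR_INTRONIC if site_kind == "donor" else ACCEPTOR_INTRONIC
    interval_fn = (
        donor_window_interval if site_kind == "donor" else acceptor_window_interval
    )
    seen: set[tuple[str, str, int, int]] = set()
    windows: list[str] = []
    n_short = n_with_n = n_noncanon = 0
    for gene in genes:
        ref = select_reference_transcript(gene)
        if ref is None:
            continue
        for intron in ref.introns:
            key = (ref.chrom, ref.strand, *intron)
            if key in seen:
                continue
            seen.add(key)
            if intron[1] - intron[0] < min_intron:
                n_short += 1
                continue
            if require_canonical:
                iseq = get_sequence(genome, ref.chrom, intron, ref.strand)
                if not (iseq.startswith("GT") and iseq.endswith("AG")):
                    n_noncanon += 1
                    continue
            lo, hi = interval_fn(intron, ref.strand)
            if lo < 0 or hi > genome.lengths[ref.chrom]:
                n_short += 1
                continue
            w = get_sequence(genome, ref.chrom, (lo, hi), ref.strand)
            if "N" in w:
                n_with_n += 1
                continue
            windows.append(w)
    log.info(
        "%s training sites: %d kept, %d too short, %d with N, %d non-canonical",
        site_kind,
        len(windows),
        n_short,
        n_with_n,
        n_noncanon,
    )
    return windows


def genome_background(genome) -> dict[str, float]:
    """Mononucleotide composition of the (double-stranded) genome.

    Counts both strands, i.e. complementary bases are pooled, so the
    background — and hence every score — is invariant under
    reverse-complementing the assembly.  N is excluded."""
    counts = {b: 0 for b in BASES}
    for seq in genome.records.values():
        for b in BASES:
            counts[b] += seq.count(b)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("genome contains no A/C/G/T bases")
    at = (counts["A"] + counts["T"]) / (2 * total)
    gc = (counts["G"] + counts["C"]) / (2 * total)
    return {"A": at, "T": at, "G": gc, "C": gc}


def train_model(
    windows: list[str],
    site_kind: str,
    pseudocount: float = 0.5,
    background: dict[str, float] | None = None,
) -> SpliceSiteModel:
    """Train a positional log-odds model from fixed-length windows.

    ``probs[p][b] = (count[p][b] + pseudocount) / (N + 4 * pseudocount)``.
    """
    if not windows:
        raise ValueError("no training windows")
    wlen = window_length(site_kind)
    counts = np.zeros((wlen, 4), dtype=float)
    for w in windows:
        if len(w) != wlen:
            raise ValueError(
                f"window length {len(w)} != expected {wlen} for {site_kind}"
            )
        for p, b in enumerate(w):
            counts[p, _BASE_INDEX[b]] += 1
    n = len(windows)
    probs = (counts + pseudocount) / (n + 4 * pseudocount)
    return SpliceSiteModel(
        site_kind=site_kind,
        counts=counts,
        probs=probs,
        background=dict(background or UNIFORM_BACKGROUND),
        pseudocount=pseudocount,
        n_training=n,
    )


def score_site(model: SpliceSiteModel, window_seq: str) -> float:
    """Log2-odds score (bits) of one window under the model."""
    if len(window_seq) != model.window:
        raise ValueError(
            f"window length {len(window_seq)} != model window {model.window}"
        )
    total = 0.0
    for p, b in enumerate(window_seq):
        if b not in _BASE_INDEX:
            raise ValueError(f"invalid base {b!r} in scoring window")
        total += math.log2(model.probs[p, _BASE_INDEX[b]] / model.background[b])
    return total


class TableScorer:
    """Lookup scorer over published k-mer -> score tables (MaxEntScan parity
    mode).  Raises on k-mers absent from the table."""

    def __init__(self, table: dict[str, float], site_kind: str):
        if not table:
            raise ValueError("empty score table")
        lengths = {len(k) for k in table}
        if len(lengths) != 1:
            raise ValueError("score table mixes k-mer lengths")
        self.table = table
        self.site_kind = site_kind
        self.window = lengths.pop()

    def score(self, window_seq: str) -> float:
        try:
            return self.table[window_seq]
        except KeyError:
            raise KeyError(f"{window_seq!r} not in score table") from None


def load_external_score_tables(path, site_kind: str) -> TableScorer:
    """Load a plain-text ``NMER<tab>SCORE`` table into a lookup scorer."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected NMER<tab>SCORE")
            kmer, score = parts
            if set(kmer) - set(BASES):
                raise ValueError(f"{path}:{lineno}: invalid k-mer {kmer!r}")
            table[kmer] = float(score)
    return TableScorer(table, site_kind)


@dataclass
class BranchPointCall:
    """Best branch-point candidate in one intron.

    ``bp_offset`` is the BPS-3'SS distance: nucleotides strictly 3' of the
    branch adenosine, up to the intron's 3' end.
    """

    bp_offset: int
    score: float
    sequence_context: str
    ppt_score: float


_BP_LOGODDS = np.log2(BP_CONSENSUS / 0.25)


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def find_branch_point(
    intron_seq: str,
    search_min: int = 15,
    search_max: int = 500,
    agez_ppt_window: int = 25,
    ppt_weight: float = 2.0,
) -> BranchPointCall | None:
    """Scan an intron (5'->3') for its best branch-point adenosine.

    Every A whose distance to the 3' end lies in ``[search_min,
    min(search_max, len-1)]`` and whose 7-mer context fits inside the intron
    is scored as ``consensus log-odds + ppt_weight * pyrimidine fraction`` of
    the ``agez_ppt_window`` nt immediately 3' of the A.  Ties go to the
    candidate closest to the 3' splice site.  Returns ``None`` when no
    candidate exists (short or A-free search windows; logged).
    """
    n = len(intron_seq)
    if n < search_min + BP_BRANCH_INDEX + 2:
        log.debug("intron of %d nt too short for branch-point search", n)
        return None
    enc = _encode(intron_seq)
    # candidate indices: A with full context in-bounds and offset in window
    hi_index = n - 1 - search_min  # largest index (closest to 3'SS)
    lo_index = max(BP_BRANCH_INDEX, n - 1 - min(search_max, n - 1))
    idx = np.where(enc[lo_index : hi_index + 1] == _BASE_INDEX["A"])[0] + lo_index
    idx = idx[idx + (7 - BP_BRANCH_INDEX) <= n]
    if idx.size == 0:
        log.debug("no branch-point candidate A in search window")
        return None
    # consensus log-odds over the 7-mer context
    ctx = idx[:, None] + np.arange(-BP_BRANCH_INDEX, 7 - BP_BRANCH_INDEX)[None, :]
    pwm = _BP_LOGODDS[np.arange(7)[None, :], enc[ctx]].sum(axis=1)
    # polypyrimidine fraction 3' of each candidate A
    is_py = ((enc == _BASE_INDEX["C"]) | (enc == _BASE_INDEX["T"])).astype(np.int32)
    cum = np.concatenate([[0], np.cumsum(is_py)])
    starts = idx + 1
    ends = np.minimum(starts + agez_ppt_window, n)
    widths = np.maximum(ends - starts, 1)
    ppt = (cum[ends] - cum[starts]) / widths
    score = pwm + ppt_weight * ppt
    # best score; ties -> largest index (closest to 3'SS)
    best = np.flatnonzero(score == score.max())[-1]
    i = int(idx[best])
    return BranchPointCall(
        bp_offset=n - 1 - i,
        score=float(score[best]),
        sequence_context=intron_seq[i - BP_BRANCH_INDEX : i + 7 - BP_BRANCH_INDEX],
        ppt_score=float(ppt[best]),
    )
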