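"""Self-contained synthetic dataset generator.

Writes everything the characterization pipeline consumes — genome FASTA,
Gencode-style GTF, five rMATS-style event tables, a gene expression TSV —
plus a ground-truth manifest of every planted quantity, so that every
pipeline stage can be exercised and checked without any external data.

What is emulated
----------------
* multi-exon protein-coding genes laid out non-overlapping on a few
  chromosomes, plus a mitochondrial decoy chromosome;
* donor/acceptor splice-site windows sampled from generator weight
  matrices; event-cohort sites come from a matrix weakened to realize a
  configured log-odds deficit (in bits, under the generator's own matrix);
* exactly one best-scoring branch-point consensus per intron at a drawn
  BPS-3'SS offset (competing adenosines are masked until the pipeline's
  own scanner provably returns the planted offset);
* CDS annotation arranged so that a configured, exact number of
  retained-intron events carry an in-frame stop codon (the rest are
  frame-preserving with no stop);
* rMATS p/FDR values planted strictly on the intended side of the 0.05
  significance filter, with inclusion-difference signs encoding direction;
* an expression table that makes the external control pool well defined.

Effects are planted in generator-matrix bit space; the pipeline's scorer is
trained on the synthetic annotation itself, so recovered differences match
in direction and approximate size, not exactly in bits.
"""

from __future__ import annotations

import json
import logging
import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import reverse_complement
from .splice_scoring import find_branch_point

log = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
STOP_CODONS = {"TAA", "TAG", "TGA"}

# generator donor matrix, positions -3..-1 (exon) +1..+6 (intron); GT fixed
DONOR_PWM = np.array(
    [
        #  A     C     G     T
        [0.33, 0.37, 0.18, 0.12],  # -3
        [0.60, 0.13, 0.14, 0.13],  # -2
        [0.08, 0.04, 0.81, 0.07],  # -1
        [0.001, 0.001, 0.997, 0.001],  # +1 G
        [0.001, 0.001, 0.001, 0.997],  # +2 T
        [0.60, 0.03, 0.34, 0.03],  # +3
        [0.71, 0.08, 0.12, 0.09],  # +4
        [0.07, 0.05, 0.82, 0.06],  # +5
        [0.17, 0.16, 0.15, 0.52],  # +6
    ]
)

# generator acceptor matrix: 20 intronic (ending AG) + 3 exonic
_PPT_ROW = [0.10, 0.32, 0.13, 0.45]
ACCEPTOR_PWM = np.array(
    [_PPT_ROW] * 14
    + [
        [0.25, 0.25, 0.25, 0.25],  # -6 n
        [0.05, 0.65, 0.02, 0.28],  # -5 C-rich
        [0.70, 0.10, 0.10, 0.10],  # -4 branch-distal A? (kept variable)
        [0.05, 0.70, 0.03, 0.22],  # -3 C
        [0.997, 0.001, 0.001, 0.001],  # -2 A
        [0.001, 0.001, 0.997, 0.001],  # -1 G
        [0.25, 0.14, 0.49, 0.12],  # +1
        [0.28, 0.22, 0.24, 0.26],  # +2
        [0.25, 0.25, 0.25, 0.25],  # +3
    ]
)

_FIXED = 0.9  # rows with a max prob above this stay fixed when weakening


@dataclass
class SyntheticConfig:
    """Study conditions for the synthetic dataset.

    Intron lengths are discretized log-normal draws, clipped to the stated
    ranges; the event cohort's retained introns are short (median ~300 nt)
    against long controls (median ~1500 nt).  Splice-site deficits are in
    bits under the generator matrices.
    """

    seed: int = 0
    n_genes: int = 400
    n_chromosomes: int = 4
    n_mito_genes: int = 3
    exons_per_gene: tuple[int, int] = (5, 9)
    exon_len: tuple[int, int] = (90, 240)
    # (log-mean, log-sd, min, max)
    intron_len_control: tuple[float, float, int, int] = (7.313, 0.35, 200, 8000)
    intron_len_event: tuple[float, float, int, int] = (5.704, 0.30, 150, 2000)
    donor_strength_delta_bits: float = 3.0
    acceptor_strength_delta_bits: float = 1.5
    bp_offset_event: tuple[int, int] = (35, 70)
    bp_offset_control: tuple[int, int] = (27, 45)
    gc_event: float = 0.40
    gc_control: float = 0.45
    n_ri_events: int = 40
    n_se_events: int = 40
    n_alt_events: int = 5  # per A5SS / A3SS / MXE kind
    n_multikind_genes: int = 6  # genes carrying both one RI and one SE event
    n_decoy_events: int = 6  # non-significant rows per kind
    frac_ri_with_inframe_stop: float = 0.93
    expression_lognorm: tuple[float, float] = (2.0, 1.5)
    null_mode: bool = False

    def event_intron_params(self):
        return self.intron_len_control if self.null_mode else self.intron_len_event

    def event_bp_range(self):
        return self.bp_offset_control if self.null_mode else self.bp_offset_event

    def event_gc(self):
        return self.gc_control if self.null_mode else self.gc_event

    def deltas(self):
        if self.null_mode:
            return 0.0, 0.0
        return self.donor_strength_delta_bits, self.acceptor_strength_delta_bits


# ---------------------------------------------------------------------------
# matrix utilities


def expected_logodds(sample_pwm: np.ndarray, score_pwm: np.ndarray) -> float:
    """Expected score (bits, uniform background) of windows drawn from
    ``sample_pwm`` under the log-odds of ``score_pwm``."""
    lo = np.log2(score_pwm / 0.25)
    return float((sample_pwm * lo).sum())


def weaken_pwm(pwm: np.ndarray, delta_bits: float) -> np.ndarray:
    """Interpolate variable positions toward uniform so that the expected
    generator log-odds drops by ``delta_bits``.

    Positions with a dominating base (the obligate GT / AG dinucleotides)
    are left untouched, keeping all introns canonical.
    """
    if delta_bits <= 0:
        return pwm.copy()
    variable = pwm.max(axis=1) < _FIXED

    def mixed(lam: float) -> np.ndarray:
        out = pwm.copy()
        out[variable] = (1 - lam) * pwm[variable] + lam * 0.25
        return out

    base = expected_logodds(pwm, pwm)
    max_drop = base - expected_logodds(mixed(1.0), pwm)
    if max_drop <= delta_bits:
        log.warning(
            "requested deficit %.2f bits exceeds attainable %.2f; clamping",
            delta_bits,
            max_drop,
        )
        return mixed(1.0)
    lo_l, hi_l = 0.0, 1.0
    for _ in range(60):
        mid = (lo_l + hi_l) / 2
        drop = base - expected_logodds(mixed(mid), pwm)
        if drop < delta_bits:
            lo_l = mid
        else:
            hi_l = mid
    return mixed((lo_l + hi_l) / 2)


def sample_window(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(BASES[rng.choice(4, p=row)] for row in pwm)


def random_seq(n: int, gc: float, rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(BASES[i] for i in rng.choice(4, size=n, p=p))


def random_coding_seq(n_codons: int, gc: float, rng: np.random.Generator) -> str:
    """Stop-free random coding sequence of ``n_codons`` codons."""
    out = []
    while len(out) < n_codons:
        codon = random_seq(3, gc, rng)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


# ---------------------------------------------------------------------------
# intron construction

BP_CONSENSUS_7MER = "TACTAAC"  # branch A at index 5
_PPT_LEN = 22


class _Intron:
    """Mutable intron under construction (transcript orientation)."""

    def __init__(self, seq: list[str], bp_offset: int):
        self.seq = seq
        self.bp_offset = bp_offset
        self.extra_protected: set[int] = set()  # e.g. a planted stop codon

    def __len__(self):
        return len(self.seq)

    def protected(self) -> set[int]:
        n = len(self.seq)
        i = n - 1 - self.bp_offset
        prot = set(range(0, 6)) | {n - 2, n - 1}
        prot |= set(range(i - 5, i + 2))
        return prot | self.extra_protected


def build_intron(
    length: int,
    gc: float,
    bp_offset: int,
    donor6: str,
    acceptor20: str,
    rng: np.random.Generator,
) -> _Intron:
    """Assemble one intron: random body, planted donor/acceptor window
    parts, branch-point consensus at the drawn offset, and a pyrimidine
    tract immediately 3' of the branch A."""
    seq = list(random_seq(length, gc, rng))
    seq[0:6] = donor6
    seq[length - 20 :] = acceptor20
    i = length - 1 - bp_offset
    seq[i - 5 : i + 2] = BP_CONSENSUS_7MER
    ppt_end = min(i + 2 + _PPT_LEN, length - 20)
    for p in range(i + 2, ppt_end):
        seq[p] = "T" if rng.random() < 0.55 else "C"
    return _Intron(seq, bp_offset)


def mask_competing_branch_points(intron: _Intron, bp_params: dict) -> bool:
    """Mutate competing adenosines until the pipeline's scanner returns the
    planted offset.  Returns True on success."""
    prot = intron.protected()
    for _ in range(40):
        call = find_branch_point("".join(intron.seq), **bp_params)
        if call is not None and call.bp_offset == intron.bp_offset:
            return True
        if call is None:
            return False
        j = len(intron.seq) - 1 - call.bp_offset
        if j not in prot:
            intron.seq[j] = "T"
            continue
        # competitor anchored in a protected window: weaken its context
        ctx = [p for p in range(j - 5, j + 2) if 0 <= p < len(intron.seq) and p not in prot]
        if not ctx:
            return False
        intron.seq[ctx[0]] = "G"
    return False


def remove_frame_stops(
    intron: _Intron, phase: int, tail: str, head: str
) -> bool:
    """Mutate retention-frame stop codons in the intron (including codons
    straddling its junctions) to non-stops.  ``tail``/``head`` are the
    flanking coding bases completing the straddle codons.  Returns False if
    a stop cannot be disrupted without touching an obligate position."""
    prot = intron.protected()
    n = len(intron.seq)
    changed = True
    while changed:
        changed = False
        reading = tail + "".join(intron.seq) + head
        for j in range(0, len(reading) - 2, 3):
            codon = reading[j : j + 3]
            if codon not in STOP_CODONS:
                continue
            # intron positions covered by this codon
            cand = [
                p - len(tail)
                for p in range(j, j + 3)
                if 0 <= p - len(tail) < n and (p - len(tail)) not in prot
            ]
            if not cand:
                return False
            intron.seq[cand[0]] = "C"  # no stop codon contains C
            changed = True
            break
    return True


def plant_frame_stop(intron: _Intron, phase: int) -> int:
    """Write a TAA at the first retention-frame codon past the donor
    window; returns its intron offset."""
    r = (3 - phase) % 3
    p = r
    while p < 9:
        p += 3
    intron.seq[p : p + 3] = "TAA"
    intron.extra_protected |= {p, p + 1, p + 2}
    return p


# ---------------------------------------------------------------------------
# gene construction


@dataclass
class _GenePlan:
    gene_id: str
    role: str  # background / ri / se / multikind / alt / mito
    n_exons: int
    event_kinds: list[str] = field(default_factory=list)
    ri_direction: str | None = None  # increased / decreased
    se_direction: str | None = None
    ri_stop_class: str | None = None  # in_frame_stop / no_ptc
    alt_kind: str | None = None


@dataclass
class _Gene:
    plan: _GenePlan
    chrom: str
    strand: str
    start: int  # genomic start of the transcript span
    exon_lens: list[int]
    intron_lens: list[int]
    exons_tx: list[tuple[int, int]]  # transcript-coordinate exon intervals
    seq_tx: str  # transcript-orientation genomic (unspliced) sequence
    cds_tx: tuple[int, int]  # CDS span in spliced coordinates... see notes
    cds_genomic: list[tuple[int, int]]
    exons_genomic: list[tuple[int, int]]
    intron_records: list[dict]
    ri_intron_index: int | None = None
    se_exon_index: int | None = None


# focal indices by role (transcript order)
_RI_INTRON_IDX = 1  # intron between exons 1 and 2
_SE_EXON_IDX = 2
_MULTI_RI_INTRON_IDX = 1
_MULTI_SE_EXON_IDX = 4


def _draw_intron_len(params, rng) -> int:
    mu, sigma, lo, hi = params
    return int(np.clip(round(float(rng.lognormal(mu, sigma))), lo, hi))


class DatasetGenerator:
    """Builds and writes one synthetic dataset from a config."""

    def __init__(self, config: SyntheticConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        d_delta, a_delta = config.deltas()
        self.donor_weak = weaken_pwm(DONOR_PWM, d_delta)
        self.acceptor_weak = weaken_pwm(ACCEPTOR_PWM, a_delta)
        self.bp_params = {}  # pipeline defaults

    # ---- planning ----------------------------------------------------

    def _plan_genes(self) -> list[_GenePlan]:
        cfg = self.cfg
        n_ri_single = cfg.n_ri_events - cfg.n_multikind_genes
        n_se_single = cfg.n_se_events - cfg.n_multikind_genes
        if n_ri_single < 0 or n_se_single < 0:
            raise ValueError("n_multikind_genes exceeds event counts")
        n_alt_genes = 3 * cfg.n_alt_events
        n_special = (
            n_ri_single + n_se_single + cfg.n_multikind_genes + n_alt_genes
        )
        if n_special + 20 > cfg.n_genes:
            raise ValueError(
                f"n_genes={cfg.n_genes} too small for {n_special} event genes"
            )
        # exact in-frame-stop planting across all RI events
        n_stop = round(cfg.frac_ri_with_inframe_stop * cfg.n_ri_events)
        stop_classes = ["in_frame_stop"] * n_stop + ["no_ptc"] * (
            cfg.n_ri_events - n_stop
        )
        directions_ri = ["increased", "decreased"] * (cfg.n_ri_events // 2 + 1)
        directions_se = ["increased", "decreased"] * (cfg.n_se_events // 2 + 1)
        plans: list[_GenePlan] = []
        k = 0
        ri_i = se_i = 0
        for j in range(n_ri_single):
            plans.append(
                _GenePlan(
                    gene_id=f"G{k:05d}", role="ri",
                    n_exons=int(self.rng.integers(7, 10)),
                    event_kinds=["RI"],
                    ri_direction=directions_ri[ri_i],
                    ri_stop_class=stop_classes[ri_i],
                )
            )
            ri_i += 1
            k += 1
        for j in range(n_se_single):
            plans.append(
                _GenePlan(
                    gene_id=f"G{k:05d}", role="se",
                    n_exons=int(self.rng.integers(8, 10)),
                    event_kinds=["SE"],
                    se_direction=directions_se[se_i],
                )
            )
            se_i += 1
            k += 1
        for j in range(cfg.n_multikind_genes):
            plans.append(
                _GenePlan(
                    gene_id=f"G{k:05d}", role="multikind",
                    n_exons=10,
                    event_kinds=["RI", "SE"],
                    ri_direction=directions_ri[ri_i],
                    ri_stop_class=stop_classes[ri_i],
                    se_direction=directions_se[se_i],
                )
            )
            ri_i += 1
            se_i += 1
            k += 1
        for kind in ("A5SS", "A3SS", "MXE"):
            for j in range(cfg.n_alt_events):
                plans.append(
                    _GenePlan(
                        gene_id=f"G{k:05d}", role="alt",
                        n_exons=int(self.rng.integers(5, 8)),
                        event_kinds=[kind],
                        alt_kind=kind,
                    )
                )
                k += 1
        n_bg = cfg.n_genes - len(plans) - cfg.n_mito_genes
        for j in range(n_bg):
            plans.append(
                _GenePlan(
                    gene_id=f"G{k:05d}", role="background",
                    n_exons=int(
                        self.rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1)
                    ),
                )
            )
            k += 1
        for j in range(cfg.n_mito_genes):
            plans.append(
                _GenePlan(
                    gene_id=f"G{k:05d}", role="mito",
                    n_exons=int(self.rng.integers(4, 7)),
                )
            )
            k += 1
        return plans

    # ---- per-gene assembly -------------------------------------------

    def _focal_ri_index(self, plan) -> int | None:
        if "RI" not in plan.event_kinds:
            return None
        return _MULTI_RI_INTRON_IDX if plan.role == "multikind" else _RI_INTRON_IDX

    def _focal_se_index(self, plan) -> int | None:
        if "SE" not in plan.event_kinds:
            return None
        return _MULTI_SE_EXON_IDX if plan.role == "multikind" else _SE_EXON_IDX

    def _build_gene(self, plan: _GenePlan, chrom: str, start: int, strand: str) -> _Gene:
        cfg = self.cfg
        rng = self.rng
        n_ex = plan.n_exons
        ri_idx = self._focal_ri_index(plan)
        se_idx = self._focal_se_index(plan)

        exon_lens = [int(rng.integers(cfg.exon_len[0], cfg.exon_len[1] + 1)) for _ in range(n_ex)]
        intron_lens = []
        for i in range(n_ex - 1):
            if ri_idx is not None and i == ri_idx:
                L = _draw_intron_len(cfg.event_intron_params(), rng)
            else:
                L = _draw_intron_len(cfg.intron_len_control, rng)
            intron_lens.append(L)

        gc_ctrl = cfg.gc_control
        gc_event = cfg.event_gc()

        # splice-site windows per intron: weakened matrices at the focal
        # sites of event genes, strong elsewhere
        donor_parts, acceptor_parts = [], []
        exon_tail3, exon_head3 = [], []
        weak_donor_flags, weak_acc_flags = [], []
        for i in range(n_ex - 1):
            weak_donor = (ri_idx is not None and i == ri_idx) or (
                se_idx is not None and i == se_idx  # focal exon's own donor
            )
            weak_acc = (ri_idx is not None and i == ri_idx) or (
                se_idx is not None and i == se_idx - 1  # focal exon's own acceptor
            )
            weak_donor_flags.append(weak_donor)
            weak_acc_flags.append(weak_acc)
            dwin = sample_window(self.donor_weak if weak_donor else DONOR_PWM, rng)
            awin = sample_window(
                self.acceptor_weak if weak_acc else ACCEPTOR_PWM, rng
            )
            exon_tail3.append(dwin[:3])
            donor_parts.append(dwin[3:])
            acceptor_parts.append(awin[:20])
            exon_head3.append(awin[20:])

        # intron assembly with planted branch points
        ri_stop_class = plan.ri_stop_class
        bp_offsets = []
        for i in range(n_ex - 1):
            is_event_intron = ri_idx is not None and i == ri_idx
            lo, hi = cfg.event_bp_range() if is_event_intron else cfg.bp_offset_control
            hi = min(hi, intron_lens[i] - 12)
            bp_offsets.append(int(rng.integers(lo, max(lo, hi) + 1)))
            if is_event_intron and ri_stop_class == "no_ptc":
                intron_lens[i] -= intron_lens[i] % 3  # frame-preserving

        # CDS start offset in exon 0; tweaked below for frame constraints
        s0 = 30
        if ri_idx is not None and ri_stop_class == "no_ptc":
            # phase at the focal intron must avoid stop codons inside the
            # obligate donor (frame offset 1) and branch-point windows
            upstream_exonic = sum(exon_lens[: ri_idx + 1])
            q = intron_lens[ri_idx] - 1 - bp_offsets[ri_idx] - 5  # 7-mer start
            for delta in range(3):
                phase = (upstream_exonic - (s0 + delta)) % 3
                r = (3 - phase) % 3
                if r != 1 and r != q % 3:
                    s0 += delta
                    break
            else:  # pragma: no cover - always satisfiable
                raise AssertionError("no admissible reading frame")

        gc_exon = gc_ctrl
        exon_seqs = []
        for i in range(n_ex):
            body = random_seq(exon_lens[i], gc_exon, rng)
            seq = list(body)
            if i > 0:
                seq[:3] = exon_head3[i - 1]
            if i < n_ex - 1:
                seq[-3:] = exon_tail3[i]
            exon_seqs.append(seq)

        # CDS span: s0 into exon 0 through (last exon length - 30), adjusted
        # so the coding length is a codon multiple; terminal TAA planted
        total_exonic = sum(exon_lens)
        cds_end_spliced = total_exonic - 30
        cds_len = cds_end_spliced - s0
        cds_end_spliced -= cds_len % 3
        self._enforce_stop_free_cds(exon_seqs, exon_lens, s0, cds_end_spliced)
        # terminal stop codon
        self._write_spliced(exon_seqs, exon_lens, cds_end_spliced - 3, "TAA")

        introns: list[_Intron] = []
        for i in range(n_ex - 1):
            is_event_intron = ri_idx is not None and i == ri_idx
            gc = gc_event if is_event_intron else gc_ctrl
            phase = (sum(exon_lens[: i + 1]) - s0) % 3 if s0 <= sum(exon_lens[: i + 1]) else 0
            for attempt in range(60):
                if attempt:
                    # a competing branch-point candidate can sit inside the
                    # obligate acceptor/donor windows; redraw their intronic
                    # parts along with the body (exon-side bases stay put)
                    donor_parts[i] = sample_window(
                        self.donor_weak if weak_donor_flags[i] else DONOR_PWM, rng
                    )[3:]
                    acceptor_parts[i] = sample_window(
                        self.acceptor_weak if weak_acc_flags[i] else ACCEPTOR_PWM, rng
                    )[:20]
                intron = build_intron(
                    intron_lens[i], gc, bp_offsets[i],
                    donor_parts[i], acceptor_parts[i], rng,
                )
                if is_event_intron:
                    if not self._shape_event_intron(
                        intron, phase, ri_stop_class, exon_seqs, i
                    ):
                        continue
                if mask_competing_branch_points(intron, self.bp_params):
                    if is_event_intron and ri_stop_class == "no_ptc":
                        # masking may have created a stop; re-verify
                        if not self._frame_stop_free(intron, phase, exon_seqs, i):
                            ok = self._shape_event_intron(
                                intron, phase, ri_stop_class, exon_seqs, i
                            ) and mask_competing_branch_points(intron, self.bp_params)
                            if not ok or not self._frame_stop_free(
                                intron, phase, exon_seqs, i
                            ):
                                continue
                    break
            else:  # pragma: no cover - resampling always converges in practice
                raise RuntimeError(f"could not plant unique branch point (gene {plan.gene_id})")
            introns.append(intron)

        # transcript-orientation unspliced sequence and coordinates
        parts = []
        exons_tx = []
        pos = 0
        for i in range(n_ex):
            exons_tx.append((pos, pos + exon_lens[i]))
            parts.append("".join(exon_seqs[i]))
            pos += exon_lens[i]
            if i < n_ex - 1:
                parts.append("".join(introns[i].seq))
                pos += len(introns[i])
        seq_tx = "".join(parts)
        span = len(seq_tx)

        def tx_to_genomic(iv):
            if strand == "+":
                return (start + iv[0], start + iv[1])
            return (start + span - iv[1], start + span - iv[0])

        exons_genomic = [tx_to_genomic(iv) for iv in exons_tx]
        # CDS genomic intervals: spliced [s0, cds_end_spliced) mapped per exon
        cds_genomic = []
        spliced = 0
        for i, (ts, te) in enumerate(exons_tx):
            elen = te - ts
            lo = max(s0, spliced)
            hi = min(cds_end_spliced, spliced + elen)
            if lo < hi:
                cds_genomic.append(tx_to_genomic((ts + lo - spliced, ts + hi - spliced)))
            spliced += elen

        intron_records = []
        for i, intron in enumerate(introns):
            iv_tx = (exons_tx[i][1], exons_tx[i + 1][0])
            g_iv = tx_to_genomic(iv_tx)
            seq = "".join(intron.seq)
            gc_real = (seq.count("G") + seq.count("C")) / len(seq)
            intron_records.append(
                {
                    "gene_id": plan.gene_id,
                    "transcript_id": f"{plan.gene_id}.t1",
                    "chrom": chrom,
                    "strand": strand,
                    "intron_index": i,
                    "start": g_iv[0],
                    "end": g_iv[1],
                    "length": len(seq),
                    "gc": round(gc_real, 6),
                    "bp_offset": intron.bp_offset,
                    "cohort": "event_ri"
                    if (ri_idx is not None and i == ri_idx)
                    else "control",
                }
            )

        return _Gene(
            plan=plan,
            chrom=chrom,
            strand=strand,
            start=start,
            exon_lens=exon_lens,
            intron_lens=[len(x) for x in introns],
            exons_tx=exons_tx,
            seq_tx=seq_tx,
            cds_tx=(s0, cds_end_spliced),
            cds_genomic=sorted(cds_genomic),
            exons_genomic=sorted(exons_genomic),
            intron_records=intron_records,
            ri_intron_index=ri_idx,
            se_exon_index=se_idx,
        )

    def _shape_event_intron(self, intron, phase, stop_class, exon_seqs, i) -> bool:
        """Apply the retained-intron coding-consequence design."""
        tail = "".join(exon_seqs[i][-3:])[3 - phase :] if phase else ""
        head_len = (3 - ((phase + len(intron)) % 3)) % 3
        head = "".join(exon_seqs[i + 1][:3])[:head_len]
        if stop_class == "no_ptc":
            return remove_frame_stops(intron, phase, tail, head)
        plant_frame_stop(intron, phase)
        return True

    def _frame_stop_free(self, intron, phase, exon_seqs, i) -> bool:
        tail = "".join(exon_seqs[i][-3:])[3 - phase :] if phase else ""
        head_len = (3 - ((phase + len(intron)) % 3)) % 3
        head = "".join(exon_seqs[i + 1][:3])[:head_len]
        reading = tail + "".join(intron.seq) + head
        return not any(
            reading[j : j + 3] in STOP_CODONS for j in range(0, len(reading) - 2, 3)
        )

    def _spliced_to_exon_pos(self, exon_lens, spliced_pos):
        for i, L in enumerate(exon_lens):
            if spliced_pos < L:
                return i, spliced_pos
            spliced_pos -= L
        raise IndexError(spliced_pos)

    def _write_spliced(self, exon_seqs, exon_lens, spliced_pos, text):
        for off, ch in enumerate(text):
            i, p = self._spliced_to_exon_pos(exon_lens, spliced_pos + off)
            exon_seqs[i][p] = ch

    def _enforce_stop_free_cds(self, exon_seqs, exon_lens, s0, cds_end) -> None:
        """Mutate one base (to C) of every stop codon in the spliced CDS.

        Junction-window bases (exon last 3 / first 3) are touched only when
        a codon offers nothing else; C never creates a stop and is tolerated
        at every junction position.
        """
        n_ex = len(exon_lens)
        changed = True
        while changed:
            changed = False
            spliced = "".join("".join(s) for s in exon_seqs)
            for j in range(s0, cds_end - 3, 3):
                if spliced[j : j + 3] not in STOP_CODONS:
                    continue
                positions = []
                for off in range(3):
                    i, p = self._spliced_to_exon_pos(exon_lens, j + off)
                    in_tail = p >= exon_lens[i] - 3 and i < n_ex - 1
                    in_head = p < 3 and i > 0
                    rank = 0 if not (in_tail or in_head) else (1 if in_head else 2)
                    positions.append((rank, i, p))
                positions.sort()
                _, i, p = positions[0]
                exon_seqs[i][p] = "C"
                changed = True
                break

    # ---- dataset assembly --------------------------------------------

    def generate(self, outdir) -> dict:
        cfg = self.cfg
        rng = self.rng
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "rmats").mkdir(exist_ok=True)

        plans = self._plan_genes()
        # shuffle gene placement so roles are not positionally clustered
        order = rng.permutation(len(plans))
        chrom_cursor = {f"chr{i + 1}": 0 for i in range(cfg.n_chromosomes)}
        chrom_cursor["chrM"] = 0
        chrom_parts = {c: [] for c in chrom_cursor}
        genes: list[_Gene] = []
        nuclear = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
        for idx_pos, pi in enumerate(order):
            plan = plans[pi]
            chrom = "chrM" if plan.role == "mito" else nuclear[idx_pos % len(nuclear)]
            gap = int(rng.integers(200, 500))
            chrom_parts[chrom].append(random_seq(gap, 0.45, rng))
            chrom_cursor[chrom] += gap
            strand = "+" if rng.random() < 0.5 else "-"
            gene = self._build_gene(plan, chrom, chrom_cursor[chrom], strand)
            written = gene.seq_tx if strand == "+" else reverse_complement(gene.seq_tx)
            chrom_parts[chrom].append(written)
            chrom_cursor[chrom] += len(written)
            genes.append(gene)
        for c in chrom_cursor:
            tail = random_seq(int(rng.integers(200, 400)), 0.45, rng)
            chrom_parts[c].append(tail)
        chrom_seqs = {c: "".join(parts) for c, parts in chrom_parts.items()}

        self._write_fasta(outdir / "genome.fa", chrom_seqs)
        self._write_gtf(outdir / "annotation.gtf", genes, rng)
        events = self._make_events(genes, rng)
        self._write_rmats(outdir / "rmats", events)
        expr = self._make_expression(genes, rng)
        expr.to_csv(outdir / "expression.tsv", sep="\t", index=False)

        intron_rows = [r for g in genes for r in g.intron_records]
        manifest_introns = pd.DataFrame(intron_rows)
        manifest_introns.to_csv(outdir / "manifest_introns.tsv", sep="\t", index=False)
        manifest_events = pd.DataFrame(events)
        manifest_events.to_csv(outdir / "manifest_events.tsv", sep="\t", index=False)
        with open(outdir / "config.json", "w") as fh:
            json.dump(asdict(cfg), fh, indent=1, sort_keys=True)

        return {
            "fasta": outdir / "genome.fa",
            "gtf": outdir / "annotation.gtf",
            "rmats_dir": outdir / "rmats",
            "expression": outdir / "expression.tsv",
            "manifest_introns": outdir / "manifest_introns.tsv",
            "manifest_events": outdir / "manifest_events.tsv",
        }

    # ---- writers ------------------------------------------------------

    @staticmethod
    def _write_fasta(path, chrom_seqs):
        with open(path, "w") as fh:
            for name in sorted(chrom_seqs):
                fh.write(f">{name}\n")
                seq = chrom_seqs[name]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")

    def _write_gtf(self, path, genes: list[_Gene], rng) -> None:
        lines = []
        for g in genes:
            gid = g.plan.gene_id
            tid = f"{gid}.t1"
            name = f"SYN{gid[1:]}"
            span = (g.exons_genomic[0][0], g.exons_genomic[-1][1])
            base_attr = (
                f'gene_id "{gid}"; gene_type "protein_coding"; gene_name "{name}";'
            )
            lines.append(
                f"{g.chrom}\tsynth\tgene\t{span[0] + 1}\t{span[1]}\t.\t{g.strand}\t.\t{base_attr}"
            )
            tx_attr = (
                f'gene_id "{gid}"; transcript_id "{tid}"; gene_type "protein_coding"; '
                f'gene_name "{name}"; transcript_type "protein_coding"; '
                f'transcript_support_level "1";'
            )
            lines.append(
                f"{g.chrom}\tsynth\ttranscript\t{span[0] + 1}\t{span[1]}\t.\t{g.strand}\t.\t{tx_attr}"
            )
            for i, (s, e) in enumerate(g.exons_genomic, 1):
                lines.append(
                    f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx_attr} exon_number {i};"
                )
            for s, e in g.cds_genomic:
                lines.append(
                    f"{g.chrom}\tsynth\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\t{tx_attr}"
                )
            # a minority of genes carry a second, shorter transcript so that
            # reference-transcript selection has real work to do
            if g.plan.role == "background" and rng.random() < 0.1 and len(g.exons_genomic) > 3:
                tid2 = f"{gid}.t2"
                tsl2 = "2" if rng.random() < 0.7 else "NA"
                tx2_attr = (
                    f'gene_id "{gid}"; transcript_id "{tid2}"; gene_type "protein_coding"; '
                    f'gene_name "{name}"; transcript_type "protein_coding"; '
                    f'transcript_support_level "{tsl2}";'
                )
                sub = g.exons_genomic[1:]
                for i, (s, e) in enumerate(sub, 1):
                    lines.append(
                        f"{g.chrom}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{tx2_attr} exon_number {i};"
                    )
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")

    # ---- event tables -------------------------------------------------

    def _make_events(self, genes: list[_Gene], rng) -> list[dict]:
        events = []
        counter = {k: 0 for k in ("SE", "RI", "A5SS", "A3SS", "MXE")}

        def stats_for(significant: bool, direction_sign: int):
            if significant:
                p = float(rng.uniform(1e-6, 0.04))
                fdr = float(rng.uniform(1e-6, 0.049))
            else:
                mode = rng.integers(3)
                p = float(rng.uniform(0.05, 0.9)) if mode != 0 else float(rng.uniform(1e-4, 0.049))
                fdr = float(rng.uniform(0.05, 0.9)) if mode != 1 else float(rng.uniform(1e-4, 0.049))
            mag = float(rng.uniform(0.1, 0.6))
            ild = direction_sign * mag
            return p, fdr, round(ild, 4)

        def add(kind, gene: _Gene, coords: dict, significant, direction_sign, extra=None):
            p, fdr, ild = stats_for(significant, direction_sign)
            row = {
                "ID": counter[kind],
                "kind": kind,
                "GeneID": gene.plan.gene_id,
                "geneSymbol": f"SYN{gene.plan.gene_id[1:]}",
                "chr": gene.chrom,
                "strand": gene.strand,
                "PValue": p,
                "FDR": fdr,
                "IncLevelDifference": ild,
                "significant": significant,
                **coords,
            }
            if extra:
                row.update(extra)
            counter[kind] += 1
            events.append(row)

        background = [g for g in genes if g.plan.role == "background"]
        decoy_pool = list(background)
        rng.shuffle(decoy_pool)
        decoy_iter = iter(decoy_pool)

        for g in genes:
            ex = g.exons_genomic
            if g.ri_intron_index is not None:
                # transcript-order exon indices flanking the focal intron
                i = g.ri_intron_index
                tx_exons = ex if g.strand == "+" else list(reversed(ex))
                up, down = tx_exons[i], tx_exons[i + 1]
                left, right = sorted([up, down])
                sign = -1 if g.plan.ri_direction == "increased" else +1
                cls = g.plan.ri_stop_class
                add(
                    "RI", g,
                    {
                        "riExonStart_0base": left[0],
                        "riExonEnd": right[1],
                        "upstreamES": up[0],
                        "upstreamEE": up[1],
                        "downstreamES": down[0],
                        "downstreamEE": down[1],
                    },
                    True, sign,
                    extra={
                        "direction": g.plan.ri_direction,
                        "consequence": cls,
                        "intron_start": left[1],
                        "intron_end": right[0],
                    },
                )
            if g.se_exon_index is not None:
                i = g.se_exon_index
                tx_exons = ex if g.strand == "+" else list(reversed(ex))
                up, focal, down = tx_exons[i - 1], tx_exons[i], tx_exons[i + 1]
                sign = +1 if g.plan.se_direction == "increased" else -1
                add(
                    "SE", g,
                    {
                        "exonStart_0base": focal[0],
                        "exonEnd": focal[1],
                        "upstreamES": up[0],
                        "upstreamEE": up[1],
                        "downstreamES": down[0],
                        "downstreamEE": down[1],
                    },
                    True, sign,
                    extra={"direction": g.plan.se_direction},
                )
            if g.plan.alt_kind:
                kind = g.plan.alt_kind
                tx_exons = ex if g.strand == "+" else list(reversed(ex))
                sign = -1 if rng.random() < 0.5 else 1
                if kind == "A5SS":
                    e1, e2 = tx_exons[1], tx_exons[2]
                    add(kind, g, {
                        "longExonStart_0base": e1[0], "longExonEnd": e1[1] + 30,
                        "shortES": e1[0], "shortEE": e1[1],
                        "flankingES": e2[0], "flankingEE": e2[1],
                    }, True, sign)
                elif kind == "A3SS":
                    e1, e2 = tx_exons[1], tx_exons[2]
                    add(kind, g, {
                        "longExonStart_0base": e2[0] - 30, "longExonEnd": e2[1],
                        "shortES": e2[0], "shortEE": e2[1],
                        "flankingES": e1[0], "flankingEE": e1[1],
                    }, True, sign)
                else:
                    e0, e1, e2, e3 = tx_exons[0], tx_exons[1], tx_exons[2], tx_exons[3]
                    add(kind, g, {
                        "1stExonStart_0base": e1[0], "1stExonEnd": e1[1],
                        "2ndExonStart_0base": e2[0], "2ndExonEnd": e2[1],
                        "upstreamES": e0[0], "upstreamEE": e0[1],
                        "downstreamES": e3[0], "downstreamEE": e3[1],
                    }, True, sign)

        # non-significant decoy rows (their genes stay external-eligible)
        for kind in ("SE", "RI", "A5SS", "A3SS", "MXE"):
            for _ in range(self.cfg.n_decoy_events):
                try:
                    g = next(decoy_iter)
                except StopIteration:
                    break
                ex = g.exons_genomic
                tx_exons = ex if g.strand == "+" else list(reversed(ex))
                sign = -1 if rng.random() < 0.5 else 1
                if kind == "SE":
                    up, focal, down = tx_exons[0], tx_exons[1], tx_exons[2]
                    add(kind, g, {
                        "exonStart_0base": focal[0], "exonEnd": focal[1],
                        "upstreamES": up[0], "upstreamEE": up[1],
                        "downstreamES": down[0], "downstreamEE": down[1],
                    }, False, sign)
                elif kind == "RI":
                    up, down = tx_exons[0], tx_exons[1]
                    left, right = sorted([up, down])
                    add(kind, g, {
                        "riExonStart_0base": left[0], "riExonEnd": right[1],
                        "upstreamES": up[0], "upstreamEE": up[1],
                        "downstreamES": down[0], "downstreamEE": down[1],
                    }, False, sign)
                elif kind in ("A5SS", "A3SS"):
                    e1, e2 = tx_exons[1], tx_exons[2]
                    if kind == "A5SS":
                        coords = {
                            "longExonStart_0base": e1[0], "longExonEnd": e1[1] + 20,
                            "shortES": e1[0], "shortEE": e1[1],
                            "flankingES": e2[0], "flankingEE": e2[1],
                        }
                    else:
                        coords = {
                            "longExonStart_0base": e2[0] - 20, "longExonEnd": e2[1],
                            "shortES": e2[0], "shortEE": e2[1],
                            "flankingES": e1[0], "flankingEE": e1[1],
                        }
                    add(kind, g, coords, False, sign)
                else:
                    e0, e1, e2, e3 = tx_exons[0], tx_exons[1], tx_exons[2], tx_exons[3]
                    add(kind, g, {
                        "1stExonStart_0base": e1[0], "1stExonEnd": e1[1],
                        "2ndExonStart_0base": e2[0], "2ndExonEnd": e2[1],
                        "upstreamES": e0[0], "upstreamEE": e0[1],
                        "downstreamES": e3[0], "downstreamEE": e3[1],
                    }, False, sign)
        return events

    _RMATS_COLUMNS = {
        "SE": ["exonStart_0base", "exonEnd", "upstreamES", "upstreamEE",
               "downstreamES", "downstreamEE"],
        "RI": ["riExonStart_0base", "riExonEnd", "upstreamES", "upstreamEE",
               "downstreamES", "downstreamEE"],
        "A5SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                 "flankingES", "flankingEE"],
        "A3SS": ["longExonStart_0base", "longExonEnd", "shortES", "shortEE",
                 "flankingES", "flankingEE"],
        "MXE": ["1stExonStart_0base", "1stExonEnd", "2ndExonStart_0base",
                "2ndExonEnd", "upstreamES", "upstreamEE",
                "downstreamES", "downstreamEE"],
    }

    def _write_rmats(self, rmats_dir: Path, events: list[dict]) -> None:
        for kind, coord_cols in self._RMATS_COLUMNS.items():
            rows = [e for e in events if e["kind"] == kind]
            cols = ["ID", "GeneID", "geneSymbol", "chr", "strand"] + coord_cols + [
                "PValue", "FDR", "IncLevel1", "IncLevel2", "IncLevelDifference",
            ]
            table = []
            for e in rows:
                d = e["IncLevelDifference"]
                rec = {c: e.get(c, "") for c in cols}
                rec["GeneID"] = f'"{e["GeneID"]}"'
                rec["IncLevel1"] = round(0.5 + d / 2, 4)
                rec["IncLevel2"] = round(0.5 - d / 2, 4)
                table.append(rec)
            df = pd.DataFrame(table, columns=cols)
            # one NA row per table exercises the missing-value rule
            if len(df):
                na_row = dict(df.iloc[-1])
                na_row["ID"] = int(df["ID"].max()) + 1
                na_row["PValue"] = "NA"
                na_row["FDR"] = "NA"
                df = pd.concat([df, pd.DataFrame([na_row])], ignore_index=True)
            df.to_csv(rmats_dir / f"{kind}.MATS.JCEC.txt", sep="\t", index=False)

    def _make_expression(self, genes: list[_Gene], rng) -> pd.DataFrame:
        mu, sigma = self.cfg.expression_lognorm
        vals = rng.lognormal(mu, sigma, size=len(genes))
        # mitochondrial decoys sit at the very top of the ranking
        for i, g in enumerate(genes):
            if g.plan.role == "mito":
                vals[i] = vals.max() * (10 + rng.random())
        return pd.DataFrame(
            {
                "gene_id": [g.plan.gene_id for g in genes],
                "expression": np.round(vals, 4),
            }
        ).sort_values("gene_id", ignore_index=True)


def generate_dataset(config: SyntheticConfig, outdir) -> dict:
    """Generate a complete dataset; returns the paths of the written files."""
    return DatasetGenerator(config).generate(outdir)


def random_intron_with_branch_point(
    length: int, bp_offset: int, rng: np.random.Generator, gc: float = 0.45
) -> str:
    """A single intron with a unique best branch point at ``bp_offset``.

    The body is adenosine-free so the planted consensus is the only
    competitive candidate; used as a recovery oracle for the scanner.
    """
    if not 12 <= bp_offset <= length - 12:
        raise ValueError("bp_offset out of range for this length")
    p = np.array([0.0, gc / 2, gc / 2, 1 - gc])
    p = p / p.sum()
    seq = list("".join(BASES[i] for i in rng.choice(4, size=length, p=p)))
    seq[0:2] = "GT"
    seq[-2:] = "AG"
    i = length - 1 - bp_offset
    seq[i - 5 : i + 2] = BP_CONSENSUS_7MER
    for q in range(i + 2, min(i + 2 + _PPT_LEN, length - 2)):
        seq[q] = "T" if rng.random() < 0.55 else "C"
    return "".join(seq)


# ---------------------------------------------------------------------------
# dataset mirroring (strand-symmetry oracle)


def mirror_dataset(indir, outdir) -> dict:
    """Reverse-complement every chromosome and flip all coordinates/strands.

    The mirrored dataset describes the identical transcripts, so every
    strand-aware measurement must be unchanged.  Mirroring twice restores
    the original byte-for-byte.
    """
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "rmats").mkdir(exist_ok=True)

    from .annotation import load_genome

    genome = load_genome(indir / "genome.fa")
    lengths = genome.lengths
    DatasetGenerator._write_fasta(
        outdir / "genome.fa",
        {c: reverse_complement(s) for c, s in genome.records.items()},
    )

    flip_strand = {"+": "-", "-": "+"}
    gtf_out = []
    with open(indir / "annotation.gtf") as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                gtf_out.append(line.rstrip("\n"))
                continue
            f = line.rstrip("\n").split("\t")
            L = lengths[f[0]]
            start1, end1 = int(f[3]), int(f[4])
            f[3], f[4] = str(L - end1 + 1), str(L - start1 + 1)
            f[6] = flip_strand[f[6]]
            gtf_out.append("\t".join(f))
    (outdir / "annotation.gtf").write_text("\n".join(gtf_out) + "\n")

    for table in sorted((indir / "rmats").glob("*.txt")):
        df = pd.read_csv(table, sep="\t", dtype=str, keep_default_na=False)
        Ls = df["chr"].map(lengths)
        coord_cols = [
            c for c in df.columns
            if c.endswith(("Start_0base", "End", "ES", "EE")) and c not in ("chr",)
        ]
        # pair start/end columns by prefix
        pairs = []
        for c in coord_cols:
            if c.endswith("Start_0base"):
                pairs.append((c, c[: -len("Start_0base")] + "End"))
            elif c.endswith("ES"):
                pairs.append((c, c[:-2] + "EE"))
        out = df.copy()
        for s_col, e_col in pairs:
            s = df[s_col].astype(int)
            e = df[e_col].astype(int)
            out[s_col] = (Ls - e).astype(int)
            out[e_col] = (Ls - s).astype(int)
        out["strand"] = df["strand"].map(flip_strand)
        out.to_csv(outdir / "rmats" / table.name, sep="\t", index=False)

    shutil.copy(indir / "expression.tsv", outdir / "expression.tsv")
    if (indir / "config.json").exists():
        shutil.copy(indir / "config.json", outdir / "config.json")

    for name in ("manifest_introns.tsv", "manifest_events.tsv"):
        p = indir / name
        if not p.exists():
            continue
        df = pd.read_csv(p, sep="\t")
        if {"chrom", "start", "end"} <= set(df.columns):
            Ls = df["chrom"].map(lengths)
            s, e = df["start"].copy(), df["end"].copy()
            df["start"], df["end"] = Ls - e, Ls - s
            df["strand"] = df["strand"].map(flip_strand)
        df.to_csv(outdir / name, sep="\t", index=False)

    return {
        "fasta": outdir / "genome.fa",
        "gtf": outdir / "annotation.gtf",
        "rmats_dir": outdir / "rmats",
        "expression": outdir / "expression.tsv",
    }
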