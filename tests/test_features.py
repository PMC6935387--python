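"""Per-item features: GC, retained-intron coding consequences (against a
translate-and-find-first-stop oracle), and manifest agreement."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from splicechar.annotation import GenomeSequence, TranscriptModel
from splicechar.features import (
    FRAME_UNAVAILABLE,
    FRAMESHIFT_PTC,
    IN_FRAME_STOP,
    NO_PTC,
    classify_ri_consequence,
    gc_content,
)


class TestGcContent:
    @pytest.mark.parametrize(
        "seq,expected",
        [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5), ("ACGT", 0.5)],
    )
    def test_values(self, seq, expected):
        assert gc_content(seq) == pytest.approx(expected)

    def test_empty_and_all_n_error(self):
        with pytest.raises(ValueError):
            gc_content("")
        with pytest.raises(ValueError):
            gc_content("NNN")


def make_case(exon_seqs, intron_seqs, cds_start, cds_end_from_3p, strand="+"):
    """Assemble a single-gene genome from transcript-orientation pieces.

    ``cds_start`` is the CDS offset into the spliced transcript and
    ``cds_end_from_3p`` the number of spliced nt left out at the 3' end.
    Returns (genome, transcript).
    """
    tx_parts, exons_tx = [], []
    pos = 0
    for i, ex in enumerate(exon_seqs):
        exons_tx.append((pos, pos + len(ex)))
        tx_parts.append(ex)
        pos += len(ex)
        if i < len(intron_seqs):
            tx_parts.append(intron_seqs[i])
            pos += len(intron_seqs[i])
    seq_tx = "".join(tx_parts)
    total_exonic = sum(len(e) for e in exon_seqs)
    cds_end = total_exonic - cds_end_from_3p

    def to_genomic(iv):
        if strand == "+":
            return iv
        return (len(seq_tx) - iv[1], len(seq_tx) - iv[0])

    exons = sorted(to_genomic(iv) for iv in exons_tx)
    # CDS spliced [cds_start, cds_end) mapped to genomic intervals
    cds = []
    spliced = 0
    for (ts, te) in exons_tx:
        lo, hi = max(cds_start, spliced), min(cds_end, spliced + te - ts)
        if lo < hi:
            cds.append(to_genomic((ts + lo - spliced, ts + hi - spliced)))
        spliced += te - ts
    written = seq_tx if strand == "+" else str(Seq(seq_tx).reverse_complement())
    genome = GenomeSequence(records={"c": written})
    tx = TranscriptModel(
        gene_id="g", transcript_id="t", chrom="c", strand=strand,
        exons=exons, cds=sorted(cds), biotype="protein_coding", tsl=1,
    )
    return genome, tx


class TestClassifyRiConsequence:
    def test_immediate_in_frame_stop(self):
        genome, tx = make_case(
            ["ATGGCCGCC", "GCCGCCGCCTAA"], ["TAAGCCGCC"], 0, 0
        )
        intron = tx.introns[0]
        assert classify_ri_consequence(tx, intron, genome) == IN_FRAME_STOP

    def test_frame_preserving_stop_free_intron(self):
        genome, tx = make_case(
            ["ATGGCCGCC", "GCCGCCGCCTAA"], ["GTCCCCCAG"], 0, 0
        )
        assert classify_ri_consequence(tx, tx.introns[0], genome) == NO_PTC

    def test_frameshift_creates_downstream_ptc(self):
        # 10 nt intron shifts the frame by one; reading continues
        # ...CCA | G-AA | TAA -> stop inside the downstream exon
        genome, tx = make_case(
            ["ATGGCCGCC", "AATAAGCCGCCC"], ["GTCCCCCCAG"], 0, 0
        )
        assert classify_ri_consequence(tx, tx.introns[0], genome) == FRAMESHIFT_PTC

    def test_no_cds_is_frame_unavailable(self):
        genome, tx = make_case(["ATGGCCGCC", "GCCGCC"], ["GTCCCAG"], 0, 0)
        tx.cds = None
        assert classify_ri_consequence(tx, tx.introns[0], genome) == FRAME_UNAVAILABLE

    def test_intron_outside_cds_is_frame_unavailable(self):
        genome, tx = make_case(
            ["AAAAAAGGG", "ATGGCCTAA"], ["GTCCCAG"], 12, 0
        )
        assert classify_ri_consequence(tx, tx.introns[0], genome) == FRAME_UNAVAILABLE

    def test_foreign_intron_is_hard_error(self):
        genome, tx = make_case(["ATGGCC", "GCCTAA"], ["GTCCCAG"], 0, 0)
        with pytest.raises(ValueError):
            classify_ri_consequence(tx, (0, 3), genome)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_agrees_with_translation_oracle(self, strand):
        """500 random retained-intron constructs classified identically by
        the annotation-arithmetic path and by brute-force translation of
        the retained mRNA."""
        rng = np.random.default_rng(202)
        bases = np.array(list("ACGT"))
        agree = 0
        n = 250  # per strand; the two strands together cover 500 constructs
        for _ in range(n):
            exon_seqs = [
                "".join(rng.choice(bases, size=int(rng.integers(30, 80))))
                for _ in range(3)
            ]
            intron_seqs = [
                "GT" + "".join(rng.choice(bases, size=int(rng.integers(10, 60)))) + "AG"
                for _ in range(2)
            ]
            cds_start = int(rng.integers(0, 10))
            cds_tail = int(rng.integers(0, 10))
            total = sum(len(e) for e in exon_seqs)
            cds_len = total - cds_tail - cds_start
            cds_tail += cds_len % 3  # keep the CDS a codon multiple
            genome, tx = make_case(exon_seqs, intron_seqs, cds_start, cds_tail, strand)
            which = int(rng.integers(0, 2))
            intron_tx = tx.introns_transcript_order()[which]
            got = classify_ri_consequence(tx, intron_tx, genome)
            expected = self._oracle(
                exon_seqs, intron_seqs, cds_start,
                sum(len(e) for e in exon_seqs) - cds_tail, which,
            )
            agree += got == expected
        assert agree == n

    @staticmethod
    def _oracle(exon_seqs, intron_seqs, cds_start, cds_end, which):
        """Translate the retained-intron mRNA and locate the first stop."""
        spliced = "".join(exon_seqs)
        # spliced position where the retained intron is inserted
        insert_at = sum(len(e) for e in exon_seqs[: which + 1])
        if not (cds_start < insert_at < cds_end):
            return FRAME_UNAVAILABLE
        intron = intron_seqs[which]
        retained = (
            spliced[cds_start:insert_at] + intron + spliced[insert_at:cds_end]
        )
        prot = str(Seq(retained[: len(retained) - len(retained) % 3]).translate())
        intron_lo = insert_at - cds_start
        intron_hi = intron_lo + len(intron)
        # first stop from the intron onward (random fixture exons may carry
        # stops upstream of it; those are not retention consequences)
        codon_start = None
        for aa_pos, aa in enumerate(prot):
            if aa == "*" and 3 * aa_pos + 3 > intron_lo:
                codon_start = 3 * aa_pos
                break
        if codon_start is None:
            return NO_PTC
        if codon_start < intron_hi and codon_start + 3 > intron_lo:
            return IN_FRAME_STOP
        if len(intron) % 3 == 0:
            return NO_PTC
        return FRAMESHIFT_PTC if codon_start + 3 < len(retained) else NO_PTC


class TestManifestAgreement:
    """The pipeline's extracted features match the generator's manifest."""

    def test_event_ri_features_match_planting(self, pipeline_run, dataset):
        ri = pd.read_csv(pipeline_run["outdir"] / "features_ri.tsv", sep="\t")
        mi = pd.read_csv(dataset["manifest_introns"], sep="\t")
        me = pd.read_csv(dataset["manifest_events"], sep="\t")
        events = ri[ri.group.isin(["IRI", "DRI"])]
        planted = (
            mi[mi.cohort == "event_ri"]
            .rename(columns={"bp_offset": "bp_true"})
            .set_index("gene_id")[["length", "gc", "bp_true"]]
        )
        assert len(events) == len(planted)
        merged = events.merge(planted, left_on="gene_id", right_index=True)
        assert (merged.bp_offset == merged.bp_true).all()
        assert (merged.focal_length == merged.length).all()
        assert (abs(merged.focal_gc - merged.gc) < 0.02).all()
        ri_truth = me[(me.kind == "RI") & me.significant]
        mm = events.merge(
            ri_truth[["GeneID", "consequence", "direction"]],
            left_on="gene_id", right_on="GeneID",
        )
        assert (mm.ri_consequence == mm.consequence).all()
        assert (
            mm.group == mm.direction.map({"increased": "IRI", "decreased": "DRI"})
        ).all()

    def test_control_branch_points_match_planting(self, pipeline_run, dataset):
        ri = pd.read_csv(pipeline_run["outdir"] / "features_ri.tsv", sep="\t")
        mi = pd.read_csv(dataset["manifest_introns"], sep="\t")
        constructs = pd.read_csv(pipeline_run["outdir"] / "constructs.tsv", sep="\t")
        eie = constructs[constructs["shape"] == "EIE"]
        by_coord = mi.set_index(["chrom", "start", "end"])
        controls = ri[ri.group.isin(["ICI", "ECI"])].reset_index(drop=True)
        eie = eie.reset_index(drop=True)
        assert len(controls) == len(eie)
        for fv, c in zip(controls.itertuples(), eie.itertuples()):
            role, iv = c.segments.split(";")[1].split(":")
            start, end = map(int, iv.split("-"))
            truth = by_coord.loc[(c.chrom, start, end)]
            assert fv.bp_offset == truth.bp_offset
            assert fv.focal_length == truth.length

    def test_se_focal_length_matches_rmats_coordinates(self, pipeline_run):
        se = pd.read_csv(pipeline_run["outdir"] / "features_se.tsv", sep="\t")
        ev = se[se.group.isin(["ISE", "DSE"])]
        assert len(ev) > 0
        assert (ev.focal_length > 0).all()
        assert ev.upstream_intron_len.notna().all()
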