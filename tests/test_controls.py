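"""Control-construct generation: footprints, candidate enumeration,
seeded sampling, and external gene selection."""

import numpy as np
import pandas as pd
import pytest

from splicechar.annotation import (
    GeneModel,
    TranscriptModel,
    load_annotation,
    load_genome,
    select_reference_transcript,
)
from splicechar.controls import (
    SHAPE_EIE,
    SHAPE_EIEIE,
    build_external_controls,
    enumerate_internal_candidates,
    event_footprints,
    sample_one,
    select_external_genes,
)
from splicechar.events import EventKind, SpliceEvent, filter_events, parse_rmats_table


def make_tx(n_exons, exon_len=50, intron_len=100, strand="+", tid="t1", gene="g1"):
    exons = []
    pos = 0
    for _ in range(n_exons):
        exons.append((pos, pos + exon_len))
        pos += exon_len + intron_len
    return TranscriptModel(
        gene_id=gene, transcript_id=tid, chrom="chr1", strand=strand,
        exons=exons, biotype="protein_coding", tsl=1,
    )


def ri_event(upstream, downstream, gene="g1"):
    return SpliceEvent(
        event_id="RI:0", kind=EventKind.RI, gene_id=gene, chrom="chr1",
        strand="+",
        coords={
            "ri_exon": (upstream[0], downstream[1]),
            "upstream_exon": upstream,
            "downstream_exon": downstream,
        },
        p_value=0.01, fdr=0.01, inc_level_diff=-0.3,
    )


class TestFootprints:
    def test_ri_footprint_spans_flanks(self):
        ev = ri_event((0, 50), (200, 260))
        assert event_footprints([ev]) == [(0, 260)]

    def test_one_per_event(self):
        evs = [ri_event((0, 50), (200, 260)), ri_event((400, 450), (600, 660))]
        assert len(event_footprints(evs)) == 2

    def test_empty(self):
        assert event_footprints([]) == []


class TestInternalCandidates:
    def test_three_exon_transcript_fully_blocked(self):
        # event in intron 1: its footprint covers E1-I1-E2, and both E-I-E
        # windows share an exon with it
        tx = make_tx(3)
        footprints = [(0, 200)]  # E1 [0,50) .. E2 [150,200)
        assert enumerate_internal_candidates(tx, footprints, SHAPE_EIE) == []

    def test_four_exon_transcript_single_candidate(self):
        tx = make_tx(4)
        footprints = [(0, 200)]
        cands = enumerate_internal_candidates(tx, footprints, SHAPE_EIE)
        assert len(cands) == 1
        roles = [r for r, _ in cands[0].segments]
        assert roles == ["exon", "intron", "exon"]
        assert cands[0].segments[0][1] == tx.exons[2]
        assert cands[0].segments[2][1] == tx.exons[3]

    def test_eieie_needs_three_clear_exons(self):
        # event on exon 2 (footprint E1..E3): 5 exons -> none, 6 exons -> one
        footprints = [(0, 350)]  # E1 [0,50) .. E3 [300,350)
        assert enumerate_internal_candidates(make_tx(5), footprints, SHAPE_EIEIE) == []
        cands = enumerate_internal_candidates(make_tx(6), footprints, SHAPE_EIEIE)
        assert len(cands) == 1
        exon_ivs = [iv for role, iv in cands[0].segments if role == "exon"]
        assert exon_ivs == [make_tx(6).exons[i] for i in (3, 4, 5)]

    def test_segments_alternate_and_abut(self):
        cands = enumerate_internal_candidates(make_tx(6), [], SHAPE_EIEIE)
        for c in cands:
            roles = [r for r, _ in c.segments]
            assert roles == ["exon", "intron", "exon", "intron", "exon"]
            for (_, a), (_, b) in zip(c.segments, c.segments[1:]):
                assert a[1] == b[0]


class TestSampleOne:
    def test_forced_choice(self):
        cands = enumerate_internal_candidates(make_tx(4), [(0, 200)], SHAPE_EIE)
        assert sample_one(cands, np.random.default_rng(0)) is cands[0]

    def test_empty_returns_none(self):
        assert sample_one([], np.random.default_rng(0)) is None

    def test_uniformity(self):
        cands = enumerate_internal_candidates(make_tx(6), [], SHAPE_EIE)
        assert len(cands) == 5
        rng = np.random.default_rng(123)
        counts = np.zeros(5)
        for _ in range(10_000):
            pick = sample_one(cands, rng)
            counts[cands.index(pick)] += 1
        freqs = counts / 10_000
        assert np.all(np.abs(freqs - 0.2) < 0.02)

    def test_seed_reproducibility(self):
        cands = enumerate_internal_candidates(make_tx(6), [], SHAPE_EIE)
        a = sample_one(cands, np.random.default_rng(42))
        b = sample_one(cands, np.random.default_rng(42))
        assert a is b


class TestExternalSelection:
    def _genes(self):
        out = {}
        for i, (chrom, n_ex) in enumerate(
            [("chr1", 5), ("chrM", 5), ("chr1", 2), ("chr1", 5), ("chr1", 5)]
        ):
            gid = f"g{i}"
            tx = make_tx(n_ex, tid=f"{gid}.t", gene=gid)
            tx.chrom = chrom
            out[gid] = GeneModel(
                gid, gid, chrom, "+", "protein_coding", [tx],
                is_mitochondrial=chrom == "chrM",
            )
        return out

    def _expr(self):
        return pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(5)],
             "expression": [50.0, 100.0, 40.0, 30.0, 20.0]}
        )

    def test_mitochondrial_excluded(self):
        ranked = select_external_genes(self._expr(), self._genes(), set(), SHAPE_EIE, n=5)
        assert "g1" not in ranked  # top-expressed but on chrM

    def test_event_genes_excluded(self):
        ranked = select_external_genes(
            self._expr(), self._genes(), {"g0"}, SHAPE_EIE, n=5
        )
        assert "g0" not in ranked

    def test_few_exon_genes_excluded_for_eieie(self):
        ranked = select_external_genes(self._expr(), self._genes(), set(), SHAPE_EIEIE, n=5)
        assert "g2" not in ranked  # only 2 exons

    def test_ranked_by_expression(self):
        ranked = select_external_genes(self._expr(), self._genes(), set(), SHAPE_EIE, n=2)
        assert ranked == ["g0", "g2"]  # g1 is mitochondrial

    def test_build_one_window_per_gene(self):
        genes = self._genes()
        rng = np.random.default_rng(0)
        built = build_external_controls(["g0", "g3"], genes, SHAPE_EIEIE, rng)
        assert len(built) == 2
        assert all(c.origin == "external" for c in built)


class TestFixtureInvariants:
    """Exhaustive validity checks on the bundled synthetic fixture."""

    def test_internal_controls_avoid_all_event_footprints(self, pipeline_run, dataset):
        constructs = pd.read_csv(pipeline_run["outdir"] / "constructs.tsv", sep="\t")
        events = pd.read_csv(pipeline_run["outdir"] / "events_filtered.tsv", sep="\t")
        internal = constructs[constructs.origin == "internal"]
        assert len(internal) > 0
        for _, c in internal.iterrows():
            segs = [s.split(":")[1] for s in c.segments.split(";")]
            span = (int(segs[0].split("-")[0]), int(segs[-1].split("-")[1]))
            gene_events = events[events.gene_id == c.gene_id]
            assert len(gene_events) > 0
            for _, e in gene_events.iterrows():
                assert span[1] <= e.span_start or e.span_end <= span[0]

    def test_segments_are_annotated_exons_and_introns(self, pipeline_run, genes):
        constructs = pd.read_csv(pipeline_run["outdir"] / "constructs.tsv", sep="\t")
        by_tid = {t.transcript_id: t for g in genes for t in g.transcripts}
        for _, c in constructs.iterrows():
            tx = by_tid[c.transcript_id]
            exon_set, intron_set = set(tx.exons), set(tx.introns)
            for s in c.segments.split(";"):
                role, iv = s.split(":")
                start, end = map(int, iv.split("-"))
                assert (start, end) in (exon_set if role == "exon" else intron_set)

    def test_external_pool_excludes_event_and_mito_genes(self, pipeline_run, genes):
        constructs = pd.read_csv(pipeline_run["outdir"] / "constructs.tsv", sep="\t")
        events = pd.read_csv(pipeline_run["outdir"] / "events_filtered.tsv", sep="\t")
        external = constructs[constructs.origin == "external"]
        mito = {g.gene_id for g in genes if g.is_mitochondrial}
        assert len(external) > 0
        assert set(external.gene_id) & set(events.gene_id) == set()
        assert set(external.gene_id) & mito == set()
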