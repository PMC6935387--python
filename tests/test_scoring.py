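"""Splice-site model training/scoring and branch-point prediction."""

import math

import numpy as np
import pytest

from splicechar.annotation import load_annotation, load_genome
from splicechar.splice_scoring import (
    acceptor_window_interval,
    collect_training_sites,
    donor_window_interval,
    find_branch_point,
    load_external_score_tables,
    score_site,
    train_model,
)
from splicechar.synthetic import mirror_dataset, random_intron_with_branch_point


class TestWindows:
    def test_donor_window_plus_strand(self):
        assert donor_window_interval((50, 200), "+") == (47, 56)

    def test_donor_window_minus_strand(self):
        assert donor_window_interval((50, 200), "-") == (194, 203)

    def test_acceptor_window_plus_strand(self):
        assert acceptor_window_interval((50, 200), "+") == (180, 203)

    def test_short_and_noncanonical_introns_skipped(self, genes, genome):
        windows = collect_training_sites(genes, genome, "donor")
        assert windows and all(len(w) == 9 for w in windows)
        # every training window comes from a GT..AG intron, so positions
        # 3-4 are always GT
        assert all(w[3:5] == "GT" for w in windows)


class TestTrainModel:
    def test_degenerate_training_gives_indicators(self):
        m = train_model(["CAGGTAAGT"] * 10, "donor", pseudocount=0.0)
        for p, b in enumerate("CAGGTAAGT"):
            assert m.probs[p, "ACGT".index(b)] == 1.0

    def test_no_training_data_error(self):
        with pytest.raises(ValueError):
            train_model([], "donor")

    def test_mixed_length_error(self):
        with pytest.raises(ValueError):
            train_model(["CAGGTAAGT", "CAGGT"], "donor")

    def test_rows_normalized(self, genes, genome):
        windows = collect_training_sites(genes, genome, "acceptor")
        m = train_model(windows, "acceptor")
        assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-9)


class TestScoreSite:
    def test_uniform_model_scores_zero(self):
        m = train_model(["CAGGTAAGT"], "donor")
        m.probs[:] = 0.25
        assert score_site(m, "ACGTACGTA") == pytest.approx(0.0)

    def test_indicator_model_scores_two_bits_per_position(self):
        m = train_model(["CAGGTAAGT"] * 5, "donor", pseudocount=0.0)
        assert score_site(m, "CAGGTAAGT") == pytest.approx(18.0)

    def test_matches_independent_logodds_sum(self, genes, genome):
        """The scorer equals a brute-force per-position log-odds sum."""
        windows = collect_training_sites(genes, genome, "donor")
        m = train_model(windows, "donor")
        rng = np.random.default_rng(0)
        for _ in range(100):
            w = "".join(rng.choice(list("ACGT"), size=9))
            expected = sum(
                math.log2(m.probs[p, "ACGT".index(b)] / m.background[b])
                for p, b in enumerate(w)
            )
            assert abs(score_site(m, w) - expected) < 1e-9

    def test_monotone_in_probability(self):
        m = train_model(["CAGGTAAGT"] * 5, "donor")
        low = score_site(m, "AAGGTAAGT")
        m.probs[0, 0] *= 2  # raise P(A at position 0)
        assert score_site(m, "AAGGTAAGT") > low

    def test_invalid_symbols_rejected(self):
        m = train_model(["CAGGTAAGT"], "donor")
        with pytest.raises(ValueError):
            score_site(m, "CAGGTANGT")
        with pytest.raises(ValueError):
            score_site(m, "CAGGT")


class TestExternalTables:
    def test_lookup(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("CAGGTAAGT\t10.86\n")
        scorer = load_external_score_tables(p, "donor")
        assert scorer.score("CAGGTAAGT") == 10.86

    def test_missing_kmer_error(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("CAGGTAAGT\t10.86\n")
        with pytest.raises(KeyError):
            load_external_score_tables(p, "donor").score("AAAAAAAAA")

    def test_empty_table_error(self, tmp_path):
        p = tmp_path / "t.txt"
        p.write_text("")
        with pytest.raises(ValueError):
            load_external_score_tables(p, "donor")


class TestFindBranchPoint:
    def test_planted_consensus_recovered(self):
        seq = list("C" * 80)
        # branch A (index 5 of TACTAAC) 30 nt from the 3' end
        i = 80 - 1 - 30
        seq[i - 5 : i + 2] = "TACTAAC"
        call = find_branch_point("".join(seq))
        assert call.bp_offset == 30
        assert call.sequence_context == "TACTAAC"

    def test_no_adenosine_returns_none(self):
        assert find_branch_point("C" * 60) is None

    def test_too_short_returns_none(self):
        assert find_branch_point("CTGAC") is None

    def test_tie_breaks_toward_three_prime_end(self):
        seq = list("C" * 100)
        for off in (40, 25):
            i = 100 - 1 - off
            seq[i - 5 : i + 2] = "TACTAAC"
        call = find_branch_point("".join(seq), ppt_weight=0.0)
        assert call.bp_offset == 25

    def test_offsets_respect_search_window(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            length = int(rng.integers(60, 600))
            intron = "".join(rng.choice(list("ACGT"), size=length))
            call = find_branch_point(intron, search_min=15, search_max=500)
            if call is not None:
                assert 15 <= call.bp_offset <= 500

    def test_recovery_on_unique_planted_introns(self):
        rng = np.random.default_rng(77)
        hits = 0
        for _ in range(50):
            off = int(rng.integers(20, 201))
            length = off + int(rng.integers(30, 150))
            intron = random_intron_with_branch_point(length, off, rng)
            call = find_branch_point(intron)
            hits += call is not None and call.bp_offset == off
        assert hits == 50


class TestStrandSymmetry:
    def test_training_windows_identical_on_mirrored_annotation(
        self, dataset, genome, genes, tmp_path
    ):
        """Models trained on a genome and on its reverse-complemented mirror
        (with flipped annotation) are identical."""
        mirror_dataset(dataset["dir"], tmp_path / "m")
        m_genome = load_genome(tmp_path / "m" / "genome.fa")
        m_genes = load_annotation(tmp_path / "m" / "annotation.gtf")
        for kind in ("donor", "acceptor"):
            w = sorted(collect_training_sites(genes, genome, kind))
            wm = sorted(collect_training_sites(m_genes, m_genome, kind))
            assert w == wm
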