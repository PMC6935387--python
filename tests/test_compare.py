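"""Group statistics, multiple-testing adjustment, and k-mer enrichment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicechar.compare import (
    VERDICT_HIGHER,
    VERDICT_LOWER,
    VERDICT_NONE,
    adjust_pvalues,
    compare_groups,
    fraction_below,
    kmer_enrichment,
    stop_codon_fraction,
    summarize_feature_table,
)


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0
        adjust_pvalues([res])
        assert res.verdict == VERDICT_NONE

    def test_separated_normals_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(18, 1, 120)
        b = rng.normal(15, 1, 120)
        res = compare_groups(a, b)
        assert res.p_value < 1e-10
        adjust_pvalues([res])
        assert res.verdict == VERDICT_HIGHER

    def test_small_group_error(self):
        with pytest.raises(ValueError):
            compare_groups([1.0], [1.0, 2.0])

    def test_ks_flag_attached(self):
        rng = np.random.default_rng(2)
        res = compare_groups(rng.normal(0, 1, 200), rng.uniform(0, 1, 200))
        assert res.ks_normal_a in (True, False)


class TestAdjustPvalues:
    def _res(self, p, mean_a=1.0):
        r = compare_groups([mean_a, mean_a + 0.1], [0.0, 0.1])
        r.p_value = p
        return r

    def test_single_bonferroni_unchanged(self):
        (r,) = adjust_pvalues([self._res(0.03)], method="bonferroni")
        assert r.p_adjusted == pytest.approx(0.03)

    def test_bonferroni_multiplies(self):
        results = [self._res(0.03)] + [self._res(0.5) for _ in range(9)]
        adjust_pvalues(results, method="bonferroni")
        assert results[0].p_adjusted == pytest.approx(0.30)
        assert results[0].verdict == VERDICT_NONE

    def test_bh_step_up_hand_computed(self):
        results = [self._res(p) for p in (0.01, 0.02, 0.03, 0.5)]
        adjust_pvalues(results, method="bh")
        assert [r.p_adjusted for r in results] == pytest.approx(
            [0.04, 0.04, 0.04, 0.5]
        )

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_bonferroni_never_decreases(self, ps):
        results = [self._res(p) for p in ps]
        adjust_pvalues(results, method="bonferroni")
        assert all(r.p_adjusted >= r.p_value - 1e-12 for r in results)


class TestFractionBelow:
    def test_strict_inequality(self):
        assert fraction_below([100, 400, 600], 500) == pytest.approx(2 / 3)
        assert fraction_below([500, 600], 500) == 0.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            fraction_below([], 500)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        values = rng.lognormal(6, 1, 200).tolist()
        fracs = [fraction_below(values, t) for t in (100, 500, 1000, 5000)]
        assert fracs == sorted(fracs)


class TestStopCodonFraction:
    def test_counting(self):
        calls = ["in_frame_stop"] * 93 + ["no_ptc"] * 7
        assert stop_codon_fraction(calls) == pytest.approx(0.93)


class TestSummarizeFeatureTable:
    def test_planted_deficit_yields_lower_verdict(self):
        rng = np.random.default_rng(4)
        grouped = {
            "donor_score": {
                "IRI": list(rng.normal(5, 1, 120)),
                "ICI": list(rng.normal(8, 1, 120)),
                "ECI": list(rng.normal(8, 1, 120)),
            }
        }
        cells, _ = summarize_feature_table(grouped, ["IRI"], "ICI", "ECI")
        assert cells[0]["verdict"] == "lower than external and internal controls"

    def test_null_yields_no_difference(self):
        rng = np.random.default_rng(8)
        grouped = {
            "donor_score": {
                g: list(rng.normal(8, 1, 80)) for g in ("IRI", "ICI", "ECI")
            }
        }
        cells, _ = summarize_feature_table(grouped, ["IRI"], "ICI", "ECI")
        assert cells[0]["verdict"] == "no significant difference"

    def test_small_group_not_computed(self):
        grouped = {"x": {"IRI": [1.0], "ICI": [1.0, 2.0], "ECI": [1.0, 2.0]}}
        cells, _ = summarize_feature_table(grouped, ["IRI"], "ICI", "ECI")
        assert cells[0]["verdict"] == "not_computed"


class TestKmerEnrichment:
    @staticmethod
    def _random_seqs(rng, n, length, forbid=None):
        out = []
        while len(out) < n:
            s = "".join(rng.choice(list("ACGT"), size=length))
            if forbid and forbid in s:
                continue
            out.append(s)
        return out

    def test_planted_motif_is_top_hit(self):
        rng = np.random.default_rng(10)
        motif = "GTCATG"
        bg = self._random_seqs(rng, 50, 40, forbid=motif)
        fg = []
        for s in self._random_seqs(rng, 50, 40, forbid=motif):
            pos = int(rng.integers(0, len(s) - len(motif)))
            fg.append(s[:pos] + motif + s[pos + len(motif):])
        n_perm = 500
        hits = kmer_enrichment(fg, bg, n_perm=n_perm, rng=np.random.default_rng(11))
        kmers = {h.kmer: h for h in hits}
        assert motif in kmers
        assert kmers[motif].p_perm == pytest.approx(1 / (1 + n_perm))
        assert kmers[motif].fg_freq == 1.0 and kmers[motif].bg_freq == 0.0

    def test_null_gives_no_hits(self):
        rng = np.random.default_rng(12)
        fg = self._random_seqs(rng, 30, 60)
        bg = self._random_seqs(rng, 30, 60)
        hits = kmer_enrichment(fg, bg, n_perm=300, rng=np.random.default_rng(13))
        assert hits == []

    def test_too_short_sequences_error(self):
        with pytest.raises(ValueError):
            kmer_enrichment(["ACGT"], ["ACGT"], k_min=5)

    def test_permutation_pvalues_valid_under_null(self):
        """Empirically P(p_perm <= a) <= a + 1/(1+n_perm) for a k-mer whose
        occurrence is independent of the (null) group labels."""
        alpha, n_perm, reps = 0.2, 99, 60
        marker = "CCCCC"
        below = used = 0
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)

            def seqs(n):
                out = []
                for s in self._random_seqs(rng, n, 30, forbid=marker):
                    if rng.random() < 0.5:  # present in ~half of all seqs
                        s = marker + s[len(marker):]
                    out.append(s)
                return out

            hits = kmer_enrichment(
                seqs(12), seqs(12), k_min=5, k_max=5, n_perm=n_perm,
                rng=np.random.default_rng(2000 + rep), alpha=1.1,
            )
            by_kmer = {h.kmer: h for h in hits}
            if marker in by_kmer:
                used += 1
                below += by_kmer[marker].p_perm <= alpha
        assert used >= 40
        bound = alpha + 1 / (1 + n_perm)
        assert below / used <= bound + 3 * np.sqrt(bound * (1 - bound) / used)
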