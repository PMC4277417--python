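"""Allelic-imbalance statistics: tests, thresholds, flags, summaries."""

import numpy as np
import pytest
from scipy import stats

from asekit import ase_stats as ast
from asekit.formats_io import GeneModel, TranscriptModel, Variant
from asekit.variant_prep import SnpCluster


def make_counts(lib_reps):
    """lib_reps: {lib: [(ref, alt), ...]} -> AlleleCounts."""
    ac = ast.AlleleCounts()
    for lib, reps in lib_reps.items():
        for i, (r, a) in enumerate(reps):
            ac.add(lib, f"R{i + 1}", r, a)
    return ac


class TestBinomialAi:
    def test_balanced_is_one(self):
        assert ast.binomial_ai(10, 10) == 1.0

    def test_extreme_tail_closed_form(self):
        assert ast.binomial_ai(20, 0) == pytest.approx(2 * 0.5 ** 20,
                                                       rel=1e-12)

    def test_moderate_value(self):
        # 2 * sum_{k=12}^{20} C(20,k) / 2^20
        assert ast.binomial_ai(12, 8) == pytest.approx(0.503445, abs=1e-5)

    def test_symmetry_and_monotonicity(self):
        for n in (5, 20, 41):
            prev = None
            for d in range(0, n + 1):
                hi = (n + d) // 2 if (n + d) % 2 == 0 else None
                if hi is None:
                    continue
                p = ast.binomial_ai(hi, n - hi)
                assert p == ast.binomial_ai(n - hi, hi)
                if prev is not None:
                    assert p <= prev + 1e-12
                prev = p

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            ast.binomial_ai(0, 0)

    def test_matches_scipy_binomtest_sample(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            ref = int(rng.integers(0, 80))
            alt = int(rng.integers(0, 80))
            if ref + alt == 0:
                continue
            expected = stats.binomtest(ref, ref + alt, 0.5).pvalue
            assert ast.binomial_ai(ref, alt) == pytest.approx(expected,
                                                              abs=1e-12)


class TestSnpAi:
    def test_defined_above_floor(self):
        res = ast.snp_ai("s", make_counts({"L1": [(30, 10)]}))
        assert res.p_values["L1"] == pytest.approx(
            ast.binomial_ai(30, 10))
        assert res.directions["L1"] == "ref>alt"

    def test_undefined_below_floor(self):
        res = ast.snp_ai("s", make_counts({"L1": [(12, 7)]}))
        assert res.p_values["L1"] is None

    def test_per_library_rule(self):
        res = ast.snp_ai("s", make_counts({"L1": [(30, 10)],
                                           "L2": [(5, 5)]}))
        assert res.p_values["L1"] is not None
        assert res.p_values["L2"] is None

    def test_replicates_summed_before_test(self):
        res = ast.snp_ai("s", make_counts({"L1": [(6, 4), (9, 5)]}))
        assert res.p_values["L1"] == pytest.approx(ast.binomial_ai(15, 9))


class TestTranscriptSnpCoverage:
    def _fixture(self):
        t = TranscriptModel("t1", "c1", "+", exons=[(1, 1000)])
        k1 = ("c1", 100, "C", "T")
        k2 = ("c1", 150, "A", "G")   # same cluster as k1
        k3 = ("c1", 400, "G", "A")
        counts = {k1: make_counts({"L1": [(30, 10)]}),
                  k2: make_counts({"L1": [(25, 15)]}),
                  k3: make_counts({"L1": [(15, 5)]})}
        clusters = [SnpCluster([100, 150], 100), SnpCluster([400], 400)]
        return t, clusters, counts

    def test_sums_representatives_only(self):
        t, clusters, counts = self._fixture()
        res = ast.transcript_snp_coverage_ai(t, clusters, counts, ["L1"])
        assert res.counts["L1"] == (45, 15)  # k1 + k3, k2 excluded
        assert res.p_values["L1"] == pytest.approx(ast.binomial_ai(45, 15))

    def test_dedup_never_exceeds_naive_sum(self):
        t, clusters, counts = self._fixture()
        res = ast.transcript_snp_coverage_ai(t, clusters, counts, ["L1"])
        naive = tuple(sum(c.library_sum("L1")[i] for c in counts.values())
                      for i in (0, 1))
        assert res.counts["L1"][0] <= naive[0]
        assert res.counts["L1"][1] <= naive[1]

    def test_undefined_when_no_member_reaches_floor(self):
        t = TranscriptModel("t1", "c1", "+", exons=[(1, 1000)])
        counts = {("c1", 100, "C", "T"): make_counts({"L1": [(9, 6)]}),
                  ("c1", 400, "G", "A"): make_counts({"L1": [(8, 6)]})}
        clusters = [SnpCluster([100], 100), SnpCluster([400], 400)]
        res = ast.transcript_snp_coverage_ai(t, clusters, counts, ["L1"])
        assert res.counts["L1"] == (17, 12)  # summed but untested
        assert res.p_values["L1"] is None

    def test_empty_snp_set(self):
        t = TranscriptModel("t1", "c1", "+", exons=[(1, 1000)])
        res = ast.transcript_snp_coverage_ai(t, [], {}, ["L1"])
        assert res.p_values["L1"] is None
        assert res.counts["L1"] == (0, 0)


class TestTranscriptReadCount:
    def test_rounds_half_up_then_tests(self):
        res = ast.transcript_read_count_ai("t", {"L1": (30.4, 9.6)})
        assert res.counts["L1"] == (30, 10)
        assert res.p_values["L1"] == pytest.approx(ast.binomial_ai(30, 10))

    def test_below_floor_undefined(self):
        res = ast.transcript_read_count_ai("t", {"L1": (7.2, 4.4)})
        assert res.counts["L1"] == (7, 4)
        assert res.p_values["L1"] is None

    def test_balanced_is_one(self):
        res = ast.transcript_read_count_ai("t", {"L1": (10.0, 10.0)})
        assert res.p_values["L1"] == 1.0

    def test_negative_error(self):
        with pytest.raises(ValueError):
            ast.transcript_read_count_ai("t", {"L1": (-1.0, 5.0)})


class TestGeneAggregate:
    def test_read_counts_sum_over_transcripts(self):
        g = GeneModel("g", "c1", "+", [
            TranscriptModel("a", "c1", "+", [(1, 100)]),
            TranscriptModel("b", "c1", "+", [(1, 100)])])
        ra = ast.transcript_read_count_ai("a", {"L1": (30.0, 10.0)})
        rb = ast.transcript_read_count_ai("b", {"L1": (20.0, 20.0)})
        res = ast.gene_read_count_ai(g, [ra, rb])
        assert res.counts["L1"] == (50, 30)
        assert res.p_values["L1"] == pytest.approx(ast.binomial_ai(50, 30))

    def test_single_transcript_gene_equals_transcript(self):
        g = GeneModel("g", "c1", "+",
                      [TranscriptModel("a", "c1", "+", [(1, 100)])])
        ra = ast.transcript_read_count_ai("a", {"L1": (30.0, 10.0)})
        res = ast.gene_read_count_ai(g, [ra])
        assert res.counts == ra.counts
        assert res.p_values == ra.p_values

    def test_shared_snp_counted_once(self):
        # both isoforms contain the same SNP; gene sums it once
        t1 = TranscriptModel("a", "c1", "+", [(1, 500)])
        t2 = TranscriptModel("b", "c1", "+", [(1, 600)])
        g = GeneModel("g", "c1", "+", [t1, t2])
        key = ("c1", 100, "C", "T")
        counts = {key: make_counts({"L1": [(30, 10)]})}
        clusters = {"a": [SnpCluster([100], 100)],
                    "b": [SnpCluster([100], 100)]}
        res = ast.gene_snp_coverage_ai(g, clusters, counts, ["L1"])
        assert res.counts["L1"] == (30, 10)


class TestRanks:
    def _gene(self, ids):
        return GeneModel("g", "c1", "+",
                         [TranscriptModel(i, "c1", "+", [(1, 10)])
                          for i in ids])

    def test_descending_totals(self):
        ranks = ast.rank_transcripts(self._gene(["a", "b", "c"]),
                                     {"a": 100, "b": 50, "c": 0})
        assert ranks == {"a": 1, "b": 2, "c": 3}

    def test_tie_breaks_lexically(self):
        ranks = ast.rank_transcripts(self._gene(["b", "a"]),
                                     {"a": 50, "b": 50})
        assert ranks == {"a": 1, "b": 2}

    def test_single_transcript_rank_one(self):
        assert ast.rank_transcripts(self._gene(["a"]), {"a": 7}) == {"a": 1}


class TestReplicateDiscordance:
    def test_opposite_significant_replicate_flags(self):
        # replicate (30,10) vs rest (20,60): chi2 ~ 27.43, p ~ 1.6e-7
        ac = make_counts({"L1": [(30, 10), (10, 30), (10, 30)]})
        # library sum (50,70): direction alt>ref; replicate 1 is ref>alt
        chi2, p, _, _ = stats.chi2_contingency([[30, 10], [20, 60]],
                                               correction=False)
        assert chi2 == pytest.approx(27.43, abs=0.01)
        assert ast.flag_replicate_discordance(ac)["L1"] is True

    def test_proportional_replicates_do_not_flag(self):
        ac = make_counts({"L1": [(10, 30), (20, 60)]})
        assert ast.flag_replicate_discordance(ac)["L1"] is False

    def test_opposite_but_insignificant(self):
        # (3,2) opposite to rest (40,60): p > 0.05
        ac = make_counts({"L1": [(3, 2), (40, 60)]})
        _, p, _, _ = stats.chi2_contingency([[3, 2], [40, 60]],
                                            correction=False)
        assert p > 0.05
        assert ast.flag_replicate_discordance(ac)["L1"] is False

    def test_single_replicate_vacuously_false(self):
        ac = make_counts({"L1": [(40, 2)]})
        assert ast.flag_replicate_discordance(ac)["L1"] is False


class TestOppositeSnps:
    def _res(self, p, direction, lib="L1"):
        r = ast.AiResult("s", "snp", "snp_coverage")
        r.p_values[lib] = p
        r.directions[lib] = direction
        return r

    def test_opposite_ai_snps_flag(self):
        assert ast.flag_opposite_snps(
            [self._res(0.01, "ref>alt"), self._res(0.03, "alt>ref")])

    def test_same_direction_no_flag(self):
        assert not ast.flag_opposite_snps(
            [self._res(0.01, "ref>alt"), self._res(0.03, "ref>alt")])

    def test_requires_both_significant(self):
        assert not ast.flag_opposite_snps(
            [self._res(0.01, "ref>alt"), self._res(0.2, "alt>ref")])

    def test_across_libraries_not_mixed(self):
        # opposite directions but in different libraries: no flag
        assert not ast.flag_opposite_snps(
            [self._res(0.01, "ref>alt", "L1"),
             self._res(0.01, "alt>ref", "L2")])


class TestBiasAndSubstitutions:
    def test_bias_percent(self):
        acs = [make_counts({"L1": [(514, 486)]})]
        assert ast.compute_bias(acs) == pytest.approx(51.4)

    def test_equal_is_fifty(self):
        assert ast.compute_bias(
            [make_counts({"L1": [(10, 10)]})]) == pytest.approx(50.0)

    def test_unmasked_style_split(self):
        assert ast.compute_bias(
            [make_counts({"L1": [(585, 415)]})]) == pytest.approx(58.5)

    def test_zero_total_error(self):
        with pytest.raises(ValueError):
            ast.compute_bias([])

    def test_substitution_class_groups_complements(self):
        assert ast.substitution_class("C", "T") == \
            ast.substitution_class("G", "A") == "CT/GA"
        assert ast.substitution_class("A", "G") == \
            ast.substitution_class("T", "C")


class TestOverview:
    def test_entity_counts_match_direct_oracle(self, study_results):
        ov = study_results.overview
        genes_with_snp = sum(
            1 for g in study_results.genes.values()
            if any(v.is_snp and v.chrom == g.chrom
                   and g.span[0] <= v.pos <= g.span[1]
                   for v in study_results.variants))
        assert ov["genes_with_snp"] == genes_with_snp
        assert ov["n_genes"] == len(study_results.genes)

    def test_effect_percent_is_ai_over_covered(self, study_results):
        for row in study_results.overview["effect_table"].values():
            if row["covered"]:
                assert row["ai_percent"] == pytest.approx(
                    100.0 * row["ai"] / row["covered"])
            assert row["covered"] <= row["count"] * len(
                study_results.libraries)

    def test_substitution_percentages_sum_to_100(self, study_results):
        pct = study_results.overview["substitution_percent"]
        assert sum(pct.values()) == pytest.approx(100.0)
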