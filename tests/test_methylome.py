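"""Context classification, weighted levels, flank calls and the tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nuptools.methylome import (
    CONTEXTS,
    MethylationTable,
    chi_square_counts,
    classify_context,
    compare_age_bins,
    compare_wt_mutant,
    flank_methylation,
    rank_sum_test,
    summarize_interval,
    weighted_methylation,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _brute_force_context(seq, pos, strand):
    """Independent enumerator: spell out the site's strand 5'->3' and apply
    the textbook rules character by character."""
    if strand == "+":
        window = seq[pos : pos + 3]
    else:
        window = "".join(_COMP.get(c, "N") for c in reversed(seq[max(0, pos - 2) : pos + 1]))
    if len(window) < 2:
        return None
    if window[1] == "G":
        return "CpG"
    if window[1] not in "ACT" or len(window) < 3:
        return None
    if window[2] == "G":
        return "CpHpG"
    if window[2] in "ACT":
        return "CpHpH"
    return None


def _table(rows):
    return MethylationTable(
        pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "unmeth"])
    )


class TestClassifyContext:
    @pytest.mark.parametrize(
        "seq,pos,strand,expected",
        [
            ("ACGT", 1, "+", "CpG"),
            ("CAGT", 0, "+", "CpHpG"),
            ("CTTT", 0, "+", "CpHpH"),
            ("TTGAA", 2, "-", "CpHpH"),  # minus strand reads C,A,A
            ("ACGT", 2, "-", "CpG"),  # symmetric CpG from the G
            ("AC", 1, "+", None),  # window off the end
            ("ACNT", 1, "+", None),  # N in window
        ],
    )
    def test_examples(self, seq, pos, strand, expected):
        assert classify_context(seq, "chr", pos, strand) == expected

    def test_not_a_cytosine_raises(self):
        with pytest.raises(ValueError):
            classify_context("AAGT", "chr", 0, "+")
        with pytest.raises(ValueError):
            classify_context("AAGT", "chr", 0, "-")  # plus base A, not G

    def test_out_of_range_raises(self):
        with pytest.raises(ValueError):
            classify_context("ACGT", "chr", 9, "+")

    def test_exhaustive_trinucleotides_both_strands(self):
        """All 4^3 trinucleotides, embedded both ways, match the brute-force
        enumerator on every cytosine position of either strand."""
        for tri in map("".join, itertools.product("ACGT", repeat=3)):
            seq = "AA" + tri + "TT"
            for pos in range(len(seq)):
                if seq[pos] == "C":
                    assert classify_context(seq, "c", pos, "+") == _brute_force_context(
                        seq, pos, "+"
                    ), (tri, pos, "+")
                if seq[pos] == "G":
                    assert classify_context(seq, "c", pos, "-") == _brute_force_context(
                        seq, pos, "-"
                    ), (tri, pos, "-")

    def test_symmetric_cpg_dinucleotide(self):
        seq = "TTCGTT"
        assert classify_context(seq, "c", 2, "+") == "CpG"
        assert classify_context(seq, "c", 3, "-") == "CpG"


class TestWeightedMethylation:
    def test_pooled_ratio(self):
        assert weighted_methylation([(5, 0), (0, 5)]) == pytest.approx(0.5)

    def test_all_unmethylated_is_zero_not_none(self):
        assert weighted_methylation([(0, 4)]) == 0.0

    def test_zero_coverage_is_undefined(self):
        assert weighted_methylation([]) is None
        assert weighted_methylation([(0, 0)]) is None

    def test_pooling_is_associative(self, rng):
        pairs = [(int(a), int(b)) for a, b in rng.integers(0, 30, size=(50, 2))]
        whole = weighted_methylation(pairs)
        c1 = sum(p[0] for p in pairs[:20]), sum(p[1] for p in pairs[:20])
        c2 = sum(p[0] for p in pairs[20:]), sum(p[1] for p in pairs[20:])
        assert weighted_methylation([c1, c2]) == pytest.approx(whole)

    def test_binomial_recovery_at_known_level(self, rng):
        """1000 sites at true level 0.3, coverage 20 -> pooled 0.30 +/- 0.02."""
        cov = rng.poisson(20, 1000)
        meth = rng.binomial(cov, 0.3)
        level = weighted_methylation(list(zip(meth.tolist(), (cov - meth).tolist())))
        assert level == pytest.approx(0.30, abs=0.02)


class TestSummarizeInterval:
    def test_single_cpg_site(self):
        table = _table([("chr1", 10, "+", "CpG", 3, 1)])
        s = summarize_interval(table, "chr1", 0, 100)
        assert s.level("CpG") == pytest.approx(0.75)
        assert s.level("CpHpG") is None and s.level("CpHpH") is None

    def test_empty_interval_has_no_data(self):
        table = _table([("chr1", 500, "+", "CpG", 3, 1)])
        s = summarize_interval(table, "chr1", 0, 100)
        assert not s.has_data
        assert all(s.level(c) is None for c in CONTEXTS)

    def test_half_open_interval_bounds(self):
        table = _table(
            [("chr1", 9, "+", "CpG", 1, 0), ("chr1", 10, "+", "CpG", 0, 1),
             ("chr1", 19, "+", "CpG", 0, 1), ("chr1", 20, "+", "CpG", 1, 0)]
        )
        s = summarize_interval(table, "chr1", 10, 20)
        cl = s.contexts["CpG"]
        assert cl.n_sites == 2 and cl.meth == 0 and cl.total == 2

    def test_missing_context_classified_from_reference(self):
        table = MethylationTable(
            pd.DataFrame(
                [("chr1", 1, "+", None, 4, 0)],
                columns=["chrom", "pos", "strand", "context", "meth", "unmeth"],
            )
        )
        s = summarize_interval(table, "chr1", 0, 4, reference={"chr1": "ACGT"})
        assert s.level("CpG") == pytest.approx(1.0)


class TestFlankMethylation:
    def test_high_low_threshold_is_inclusive(self):
        table = _table(
            [("chr1", 500, "+", "CpG", 5, 5), ("chr1", 2500, "+", "CpG", 5, 5)]
        )
        rep = flank_methylation(table, "chr1", 1000, 2000, flank=1000)
        assert rep.combined["CpG"].level == pytest.approx(0.5)
        assert rep.labels["CpG"] == "High"
        assert rep.labels["all"] == "High"

    def test_chromosome_start_truncates_five_prime(self):
        table = _table([("chr1", 150, "+", "CpG", 2, 2)])
        rep = flank_methylation(table, "chr1", 0, 100, flank=1000, chrom_length=200)
        assert not rep.five_prime.has_data
        assert rep.combined["CpG"].total == rep.three_prime.contexts["CpG"].total

    def test_low_background_labelled_low(self, small_sim):
        """With a 0.02-0.08 flank background, essentially every flank is Low."""
        truth = small_sim.truth
        labels = []
        for ins in truth.insertions:
            rep = flank_methylation(
                small_sim.methylome_wt, ins.chrom, ins.start, ins.end,
                chrom_length=len(small_sim.genome[ins.chrom]),
            )
            if rep.labels["all"] is not None:
                labels.append(rep.labels["all"])
        assert labels
        assert labels.count("Low") / len(labels) >= 0.95


def _exact_perm_p(x, y):
    """Independent oracle: enumerate group relabelings of the rank-sum."""
    pooled = np.array(list(x) + list(y), float)
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    obs = ranks[:n1].sum()
    vals = np.array(
        [ranks[list(c)].sum() for c in itertools.combinations(range(len(pooled)), n1)]
    )
    ge = np.mean(vals >= obs)
    le = np.mean(vals <= obs)
    return min(1.0, 2 * min(ge, le))


class TestRankSum:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_small_samples_match_exact_permutation(self, seed):
        r = np.random.default_rng(seed)
        x = r.integers(0, 5, int(r.integers(3, 9))).astype(float)  # heavy ties
        y = r.integers(0, 6, int(r.integers(3, 9))).astype(float)
        _u, p = rank_sum_test(x, y)
        assert p == pytest.approx(_exact_perm_p(x, y), abs=1e-12)

    def test_identical_samples_p_near_one(self):
        x = [0.1, 0.2, 0.3, 0.4, 0.5]
        _u, p = rank_sum_test(x, list(x))
        assert p == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_large_sample_asymptotic_matches_scipy(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 70)
        u, p = rank_sum_test(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(float(ref.statistic))
        assert p == pytest.approx(float(ref.pvalue))


class TestChiSquare:
    def test_matches_direct_formula_on_toy_table(self):
        """[[10,90],[50,50]]: Sum (O-E)^2/E computed by hand-style loop."""
        table = [[10, 90], [50, 50]]
        arr = np.array(table, float)
        expected = np.outer(arr.sum(1), arr.sum(0)) / arr.sum()
        by_hand = float(((arr - expected) ** 2 / expected).sum())
        stat, p, dof = chi_square_counts(table)
        assert stat == pytest.approx(by_hand)
        assert stat == pytest.approx(38.095238, abs=1e-5)
        assert dof == 1

    def test_equal_pooled_counts_statistic_zero(self):
        stat, p, _ = chi_square_counts([[30, 70], [30, 70]])
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)


class TestCompareAgeBins:
    def test_identical_bins_not_significant(self):
        levels = {"young": [0.1, 0.2, 0.3, 0.4], "old": [0.1, 0.2, 0.3, 0.4]}
        counts = {"young": (30, 70), "old": (30, 70)}
        rep = compare_age_bins(levels, counts)
        assert rep["chi2"]["statistic"] == pytest.approx(0.0)
        assert rep["wilcoxon"][("young", "old")]["p"] == pytest.approx(1.0)
        assert rep["wilcoxon"][("young", "old")]["significance"] == "n.s."

    def test_requires_two_nonempty_bins(self):
        with pytest.raises(ValueError):
            compare_age_bins({"young": [0.1], "old": []})

    def test_zero_read_bin_excluded_from_chi2(self):
        levels = {"young": [0.5, 0.6], "middle": [0.1, 0.2], "old": [0.3]}
        counts = {"young": (10, 10), "middle": (5, 15), "old": (0, 0)}
        rep = compare_age_bins(levels, counts)
        assert rep["chi2"]["bins"] == ["young", "middle"]


class TestCompareWtMutant:
    def _summaries(self, table, intervals):
        return {
            name: summarize_interval(table, chrom, s, e, interval_id=name)
            for name, chrom, s, e in intervals
        }

    def test_mutant_copy_gives_zero_deltas(self):
        rows = [("chr1", p, "+", "CpG", 5, 5) for p in range(10, 200, 17)]
        table = _table(rows)
        ivs = [(f"n{i}", "chr1", i * 20, i * 20 + 20) for i in range(8)]
        wt = self._summaries(table, ivs)
        tests, deltas = compare_wt_mutant(wt, dict(wt))
        assert (deltas["delta"] == 0).all()
        assert tests["CpG"]["p"] == pytest.approx(1.0)
        assert tests["CpG"]["significance"] == "n.s."

    def test_disjoint_ids_rejected(self):
        rows = [("chr1", 10, "+", "CpG", 5, 5)]
        table = _table(rows)
        a = self._summaries(table, [("a", "chr1", 0, 20)])
        b = self._summaries(table, [("b", "chr1", 0, 20)])
        with pytest.raises(ValueError):
            compare_wt_mutant(a, b)


class TestTableIO:
    def test_tsv_roundtrip_is_one_based_on_disk(self, tmp_path):
        table = _table([("chr1", 10, "+", "CpG", 3, 1), ("chr1", 11, "-", "CpG", 2, 2)])
        path = tmp_path / "calls.tsv"
        table.write_tsv(path)
        text = path.read_text().splitlines()
        assert text[0].split("\t")[:2] == ["chrom", "pos"]
        assert text[1].split("\t")[1] == "11"  # 0-based 10 -> 1-based 11
        back = MethylationTable.read_tsv(path)
        pd.testing.assert_frame_equal(back.frame, table.frame)
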