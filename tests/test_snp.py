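"""Pileup parsing, the six-rule filter cascade, and summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from denovotx import simulate as sim, snp
from denovotx.core import Contig
from denovotx.snp import PileupColumn, SnpFilterConfig


def make_column(ref="A", counts=None, snp_qual=150, rms=150, pos=5):
    counts = counts if counts is not None else {"A": 13, "G": 7}
    from collections import Counter

    depth = sum(counts.values())
    return PileupColumn(
        ref_name="c1", pos=pos, ref_base=ref, consensus_base=ref,
        consensus_qual=30, snp_qual=snp_qual, rms_map_qual=rms, depth=depth,
        read_bases="", base_quals="", allele_counts=Counter(counts))


class TestParse:
    @pytest.mark.parametrize(
        "bases, ref, expected",
        [(".,..", "A", {"A": 4}), (".,Gg", "A", {"A": 2, "G": 2}),
         ("^I.$", "C", {"C": 1}), (".+2AC,", "T", {"T": 2}),
         (".-1A,", "G", {"G": 2})],
    )
    def test_decode_read_bases(self, bases, ref, expected):
        assert dict(snp.decode_read_bases(bases, ref)) == expected

    def test_parse_line(self):
        line = "c1\t5\tA\tA\t30\t25\t60\t4\t.,..\tIIII"
        (col,) = snp.parse_pileup([line])
        assert col.pos == 5 and col.depth == 4
        assert dict(col.allele_counts) == {"A": 4} and col.alt_reads == 0

    def test_depth_mismatch_reports_line_number(self):
        good = "c1\t1\tA\tA\t30\t25\t60\t2\t..\tII"
        bad = "c1\t2\tA\tA\t30\t25\t60\t3\t..\tII"
        with pytest.raises(ValueError, match="line 2"):
            list(snp.parse_pileup([good, bad]))

    def test_wrong_column_count(self):
        with pytest.raises(ValueError, match="10 columns"):
            list(snp.parse_pileup(["c1\t1\tA"]))


class TestInitialCut:
    @pytest.mark.parametrize(
        "counts, qual, kept",
        [({"A": 3, "G": 1}, 19, False), ({"A": 3, "G": 1}, 20, True),
         ({"A": 4}, 200, False)],
    )
    def test_boundaries(self, counts, qual, kept):
        col = make_column(counts=counts, snp_qual=qual)
        assert bool(list(snp.initial_score_cut([col]))) is kept


class TestCascade:
    def test_passing_example(self):
        call = snp.apply_cascade(make_column(counts={"A": 13, "G": 7}))
        assert call.passed and call.maf == pytest.approx(0.35)
        assert call.alt_allele == "G" and call.subst_class == "transition"

    def test_low_depth_fails_rule2_only(self):
        call = snp.apply_cascade(make_column(counts={"A": 6, "G": 3}))
        assert not call.passed and call.failed_criteria == [2]

    def test_triallelic_fails_rules_4_and_6(self):
        call = snp.apply_cascade(make_column(counts={"A": 10, "G": 6, "T": 4}))
        assert call.failed_criteria == [4, 6]

    def test_zero_depth_errors(self):
        with pytest.raises(ValueError):
            snp.apply_cascade(make_column(counts={}))

    def test_score_mode_sum(self):
        col = make_column(snp_qual=60, rms=60)
        assert snp.apply_cascade(col).failed_criteria == [1]
        cfg = SnpFilterConfig(score_mode="sum")
        assert snp.apply_cascade(col, cfg).passed  # 120 > 100

    def test_strict_biallelic_counts_singletons(self):
        # an error singleton next to a true biallelic site
        col = make_column(counts={"A": 30, "G": 9, "T": 1})
        assert snp.apply_cascade(col).passed  # T has < 3 reads: ignored
        cfg = SnpFilterConfig(strict_biallelic=True)
        assert 4 in snp.apply_cascade(col, cfg).failed_criteria

    def test_pass_fail_is_order_independent(self):
        # every rule is evaluated; failed ids are the full set
        col = make_column(counts={"A": 5, "G": 2}, snp_qual=50)
        call = snp.apply_cascade(col)
        assert call.failed_criteria == [1, 2, 3]

    @given(
        depth=st.integers(min_value=1, max_value=80),
        alt_frac=st.floats(min_value=0.0, max_value=0.5),
        quals=st.tuples(st.integers(0, 255), st.integers(0, 255)),
    )
    @settings(max_examples=200, derandomize=True)
    def test_tightening_thresholds_never_passes_more(self, depth, alt_frac, quals):
        alt = int(alt_frac * depth)
        counts = {"A": depth - alt}
        if alt:
            counts["G"] = alt
        col = make_column(counts=counts, snp_qual=quals[0], rms=quals[1])
        base = snp.apply_cascade(col, SnpFilterConfig()).passed
        for tighter in (
            SnpFilterConfig(min_depth=20),
            SnpFilterConfig(min_maf=0.2),
            SnpFilterConfig(min_scores=200),
        ):
            # anything passing the tighter thresholds passes the defaults
            assert base or not snp.apply_cascade(col, tighter).passed


@pytest.mark.parametrize(
    "ref, alt, expected",
    [("A", "G", "transition"), ("G", "A", "transition"), ("C", "T", "transition"),
     ("A", "C", "transversion"), ("A", "T", "transversion"),
     ("G", "C", "transversion")],
)
def test_classify_substitution(ref, alt, expected):
    assert snp.classify_substitution(ref, alt) == expected


def test_classify_substitution_rejects_identical():
    with pytest.raises(ValueError):
        snp.classify_substitution("A", "A")


@pytest.mark.parametrize(
    "total_bp, n, expected",
    [(18_701_412, 16_648, 1_123), (15_903_039, 9_335, 1_704), (1000, 1, 1000),
     (15, 10, 2)],  # 1.5 rounds half-up
)
def test_snp_frequency(total_bp, n, expected):
    assert snp.snp_frequency(total_bp, n) == expected


def test_snp_frequency_zero_is_na_not_error():
    assert snp.snp_frequency(1000, 0) is None


class TestSummarize:
    def test_ts_tv_partition(self):
        cols = [
            make_column(counts={"A": 13, "G": 7}, pos=1),   # ts
            make_column(counts={"A": 13, "G": 7}, pos=2),   # ts
            make_column(counts={"A": 13, "G": 7}, pos=3),   # ts
            make_column(ref="A", counts={"A": 13, "C": 7}, pos=4),  # tv
            make_column(ref="A", counts={"A": 13, "T": 7}, pos=5),  # tv
            make_column(counts={"A": 6, "G": 3}, pos=6),    # fails depth
        ]
        calls = [snp.apply_cascade(c) for c in cols]
        s = snp.summarize(calls, kept_contig_total_bp=10_000)
        assert (s.n_ts, s.n_tv, s.n_filtered) == (3, 2, 5)
        assert s.n_ts + s.n_tv == s.n_filtered
        assert s.n_putative == 6 >= s.n_filtered
        assert s.freq_bp_per_snp == 2000

    def test_no_pass_calls(self):
        calls = [snp.apply_cascade(make_column(counts={"A": 6, "G": 3}))]
        s = snp.summarize(calls, kept_contig_total_bp=1000)
        assert s.n_filtered == 0 and s.freq_bp_per_snp is None
        assert "n/a" in snp.summary_table(s)


class TestPlantedRecovery:
    def test_planted_snps_recovered_from_generated_pileup(self):
        rng = np.random.default_rng(12)
        contig = Contig("c1", sim.random_dna(rng, 2000))
        planted = []
        for pos in (100, 500, 900, 1300, 1700):
            ref = contig.seq[pos - 1]
            alt = next(b for b in "ACGT" if b != ref)
            planted.append(sim.PlantedSnp("c1", pos, ref, alt, 0.5, 40))
        text, _ = sim.make_pileup(contig, planted, depth_mean=20,
                                  error_rate=0.0, seed=7)
        calls, summary = snp.filter_pileup(text)
        passed_pos = {c.pos for c in calls if c.passed}
        # recovery is conditional on the realized column satisfying the rules
        for col in snp.parse_pileup(text):
            if col.pos in {p.pos for p in planted}:
                call = snp.apply_cascade(col)
                assert call.passed == (col.pos in passed_pos)
                if (col.depth >= 10 and call.maf >= 0.05 and col.alt_reads >= 3
                        and col.snp_qual > 100 and col.rms_map_qual > 100):
                    assert call.passed

    def test_factorial_benchmark_exact_rule_ids(self):
        text, truth = sim.make_snp_benchmark(5, n_columns=2000, n_pass=24,
                                             n_violations=24)
        calls, _ = snp.filter_pileup(text)
        by_pos = {c.pos: c for c in calls}
        for pos, kind, rule in truth:
            call = by_pos[pos]
            if kind == "pass":
                assert call.passed, (pos, call.failed_criteria)
            else:
                assert call.failed_criteria == [rule], (pos, rule, call.failed_criteria)


def test_filter_pipeline_tables():
    text, _ = sim.make_snp_benchmark(6, n_columns=500, n_pass=5, n_violations=6)
    calls, summary = snp.filter_pileup(text, kept_contig_total_bp=500)
    out = snp.calls_table(calls)
    assert out.startswith("CHROM\tPOS\tREF\tALT")
    assert snp.summary_table(summary).count("\n") >= 5
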