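import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccgpipe.annotation import Exon, Gene, GeneAnnotation
from ccgpipe.counts import CountMatrix
from ccgpipe.quantify import (
    apply_influence_filter,
    chip_background_filter,
    count_exonic,
    count_terminal_window,
    filter_low_expression,
    influence_factor,
    sample_background_windows,
    size_factors,
)

from conftest import make_reads


class TestCountExonic:
    def test_reads_inside_single_exon_gene(self, two_gene_annotation):
        reads = make_reads([("chr1", 1500 + i, 1550 + i, "t00", "+") for i in range(5)])
        cm = count_exonic(reads, two_gene_annotation)
        assert cm.data.loc["gA", "t00"] == 5
        assert cm.data.loc["gB", "t00"] == 0

    def test_intronic_read_not_counted(self):
        ann = GeneAnnotation(
            [Gene("g", "chr1", "+", 0, 1000, exons=[Exon(0, 200), Exon(800, 1000)])]
        )
        reads = make_reads([("chr1", 500, 550, "t00", "+")])  # in the intron
        cm = count_exonic(reads, ann)
        assert cm.data.loc["g", "t00"] == 0
        assert cm.unassigned["t00"] == 1

    def test_five_prime_rule_minus_strand(self, two_gene_annotation):
        # read [2980, 3010) straddles gA's end (3000): the plus-strand 5'
        # base (2980) is inside, the minus-strand 5' base (3009) is not
        plus = make_reads([("chr1", 2980, 3010, "t00", "+")])
        minus = make_reads([("chr1", 2980, 3010, "t00", "-")])
        assert count_exonic(plus, two_gene_annotation).data.loc["gA", "t00"] == 1
        assert count_exonic(minus, two_gene_annotation).data.loc["gA", "t00"] == 0
        # and the mirror: minus 5' base inside, plus 5' base before the gene
        minus_in = make_reads([("chr1", 980, 1010, "t00", "-")])
        assert count_exonic(minus_in, two_gene_annotation).data.loc["gA", "t00"] == 1

    def test_overlap_read_counts_both_genes(self, overlapping_annotation):
        reads = make_reads([("chr1", 2700, 2750, "t00", "+")])
        cm = count_exonic(reads, overlapping_annotation)
        assert cm.data.loc["gA", "t00"] == 1
        assert cm.data.loc["gB", "t00"] == 1
        assert cm.overlap_counts.loc["gA", "t00"] == 1

    def test_hand_enumerated_overlap_fixture(self, overlapping_annotation):
        # 12 reads: 4 only in gA [1000,2500), 3 in the overlap [2500,3000),
        # 3 only in gB [3000,5000), 2 outside both genes
        rows = (
            [("chr1", 1100 + 100 * i, 1150 + 100 * i, "t00", "+") for i in range(4)]
            + [("chr1", 2600 + 50 * i, 2650 + 50 * i, "t00", "+") for i in range(3)]
            + [("chr1", 3500 + 200 * i, 3550 + 200 * i, "t00", "+") for i in range(3)]
            + [("chr1", 9000, 9050, "t00", "+"), ("chr1", 12000, 12050, "t00", "+")]
        )
        cm = count_exonic(make_reads(rows), overlapping_annotation)
        assert cm.data.loc["gA", "t00"] == 7  # 4 + 3 overlap
        assert cm.data.loc["gB", "t00"] == 6  # 3 + 3 overlap
        assert cm.unassigned["t00"] == 2

    def test_unknown_chromosome_goes_to_unassigned(self, two_gene_annotation):
        reads = make_reads(
            [("chrX", 100, 150, "t00", "+"), ("chr1", 1500, 1550, "t00", "+")]
        )
        cm = count_exonic(reads, two_gene_annotation)
        assert cm.data.loc["gA", "t00"] == 1
        assert cm.unassigned["t00"] == 1

    def test_conservation_for_disjoint_genes(self, two_gene_annotation):
        rng = np.random.default_rng(0)
        pos = rng.integers(0, 19000, size=300)
        reads = make_reads([("chr1", int(p), int(p) + 50, "t00", "+") for p in pos])
        cm = count_exonic(reads, two_gene_annotation)
        assert cm.data["t00"].sum() + cm.unassigned["t00"] == 300


class TestTerminalWindow:
    def test_plus_strand_window(self, two_gene_annotation):
        # gA spans [1000,3000)+ so window = [2500,3000)
        inside = make_reads([("chr1", 2600, 2650, "t00", "+")])
        outside = make_reads([("chr1", 2400, 2450, "t00", "+")])
        assert count_terminal_window(inside, two_gene_annotation).data.loc["gA", "t00"] == 1
        assert count_terminal_window(outside, two_gene_annotation).data.loc["gA", "t00"] == 0

    def test_minus_strand_window(self, two_gene_annotation):
        # gB spans [5000,8000)- so window = [5000,5500)
        inside = make_reads([("chr1", 5200, 5250, "t00", "+")])
        cm = count_terminal_window(inside, two_gene_annotation)
        assert cm.data.loc["gB", "t00"] == 1

    def test_short_gene_whole_span(self):
        ann = GeneAnnotation([Gene("g", "chr1", "+", 1000, 1300)])
        reads = make_reads([("chr1", 1010, 1060, "t00", "+")])
        assert count_terminal_window(reads, ann).data.loc["g", "t00"] == 1

    def test_invalid_window(self, two_gene_annotation):
        with pytest.raises(ValueError):
            count_terminal_window(make_reads([]), two_gene_annotation, window_bp=0)


class TestInfluenceFactor:
    def test_no_overlap_identity(self):
        assert influence_factor(100, 1000, 0, 0) == 1.0

    def test_hand_value(self):
        # (100/1000) / (40/800) = 2.0
        assert influence_factor(100, 1000, 60, 200) == pytest.approx(2.0)

    def test_all_reads_in_overlap_infinite(self):
        assert influence_factor(50, 500, 50, 250) == float("inf")

    @pytest.mark.parametrize("args", [(100, 1000, 150, 200), (100, 500, 50, 600)])
    def test_invalid(self, args):
        with pytest.raises(ValueError):
            influence_factor(*args)

    @given(
        G=st.integers(1, 10_000),
        O=st.integers(0, 10_000),
        c=st.floats(0.1, 100.0),
    )
    @settings(max_examples=100, deadline=None)
    def test_scale_invariance(self, G, O, c):
        O = min(O, G)
        f1 = influence_factor(G, 1000, O, 300)
        f2 = influence_factor(G * c, 1000, O * c, 300)
        if np.isfinite(f1):
            assert f2 == pytest.approx(f1, rel=1e-9)
        else:
            assert not np.isfinite(f2)


class TestInfluenceFilter:
    def _matrix(self, ann, gA_total, gA_overlap, gB_total, gB_overlap):
        data = pd.DataFrame({"t00": [gA_total, gB_total]}, index=["gA", "gB"])
        ov = pd.DataFrame({"t00": [gA_overlap, gB_overlap]}, index=["gA", "gB"])
        return CountMatrix(data, overlap_counts=ov)

    def test_factor_exactly_two_retained(self, overlapping_annotation):
        # gA: L_G=2000, L_O=500 -> (G/2000)/((G-O)/1500) = 2 when O = 5G/8
        cm = self._matrix(overlapping_annotation, 80, 50, 10, 0)
        kept, report = apply_influence_filter(cm, overlapping_annotation)
        assert "gA" in kept.gene_ids
        assert report.removed.empty

    def test_factor_above_two_removed(self, overlapping_annotation):
        cm = self._matrix(overlapping_annotation, 80, 60, 10, 0)
        kept, report = apply_influence_filter(cm, overlapping_annotation)
        assert "gA" not in kept.gene_ids
        assert report.removed["gene_id"].tolist() == ["gA"]

    def test_gene_without_partner_retained(self, two_gene_annotation):
        data = pd.DataFrame({"t00": [5, 5]}, index=["gA", "gB"])
        kept, _ = apply_influence_filter(CountMatrix(data), two_gene_annotation)
        assert kept.gene_ids == ["gA", "gB"]


class TestSizeFactors:
    def test_identical_columns_unit_factors(self):
        data = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
        np.testing.assert_allclose(size_factors(CountMatrix(data)), [1.0, 1.0])

    def test_doubled_sample(self):
        data = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        f = size_factors(CountMatrix(data))
        np.testing.assert_allclose(f, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12)

    def test_zero_gene_excluded(self):
        data = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
        with_zero = pd.concat(
            [data, pd.DataFrame({"a": [0], "b": [5]})], ignore_index=True
        )
        np.testing.assert_allclose(
            size_factors(CountMatrix(data)),
            size_factors(CountMatrix(with_zero)),
        )

    def test_all_zero_errors(self):
        data = pd.DataFrame({"a": [0, 3], "b": [5, 0]})
        with pytest.raises(ValueError):
            size_factors(CountMatrix(data))

    def test_rescaling_property(self):
        rng = np.random.default_rng(1)
        data = pd.DataFrame(rng.poisson(50, size=(40, 3)), columns=list("abc"))
        f0 = size_factors(CountMatrix(data))
        scaled = data.copy()
        scaled["b"] = scaled["b"] * 3
        f1 = size_factors(CountMatrix(scaled))
        # sample b's factor scales by 3^(2/3), others shrink by 3^(-1/3)
        # (geometric-mean reference absorbs one third of the change)
        np.testing.assert_allclose(f1["b"] / f0["b"] * (f1["a"] / f0["a"]) ** -1,
                                   3.0, rtol=1e-9)


class TestLowExpressionFilter:
    def _norm(self, values):
        df = pd.DataFrame({"a": values, "b": values})
        return CountMatrix(df, normalized=True)

    def test_removes_two_smallest_of_ten(self):
        cm = self._norm([5, 1, 9, 2, 8, 7, 6, 4, 3, 10])
        kept, report = filter_low_expression(cm, 0.2)
        assert len(kept) == 8
        assert sorted(report.removed["gene_id"]) == [1, 3]  # means 1 and 2

    def test_quantile_zero_identity(self):
        cm = self._norm([3, 1, 2])
        kept, report = filter_low_expression(cm, 0.0)
        assert len(kept) == 3 and report.removed.empty

    def test_tie_break_stable_input_order(self):
        cm = self._norm([5.0] * 10)
        kept, report = filter_low_expression(cm, 0.2)
        assert report.removed["gene_id"].tolist() == [0, 1]

    def test_requires_normalized(self):
        cm = CountMatrix(pd.DataFrame({"a": [1, 2]}))
        with pytest.raises(ValueError):
            filter_low_expression(cm)


class TestChipBackground:
    def _annotation(self):
        return GeneAnnotation(
            [Gene("g1", "chr1", "+", 10_000, 12_000),
             Gene("g2", "chr1", "+", 40_000, 42_000)],
            chrom_sizes={"chr1": 100_000},
        )

    def test_zero_background_keeps_all(self):
        ann = self._annotation()
        reads = make_reads([("chr1", 11_600, 11_650, "t00", "+")])
        cm = count_terminal_window(reads, ann)
        kept, report, cutoff = chip_background_filter(
            cm, reads, ann, n_windows=20, min_gene_distance=1000, seed=0
        )
        assert cutoff == 0.0
        assert len(kept) == 2

    def test_uniform_background_cutoff(self):
        ann = self._annotation()
        # uniform intergenic density: one read per 100 bp everywhere outside genes
        rows = [
            ("chr1", p, p + 50, "t00", "+")
            for p in range(0, 100_000, 100)
            if not (10_000 <= p < 12_000 or 40_000 <= p < 42_000)
        ]
        # g1 terminal window gets 10 reads (above), g2 gets 1 (below cutoff 5)
        rows += [("chr1", 11_500 + 10 * i, 11_550 + 10 * i, "t00", "+") for i in range(10)]
        rows += [("chr1", 41_900, 41_950, "t00", "+")]
        reads = make_reads(rows)
        cm = count_terminal_window(reads, ann)
        kept, report, cutoff = chip_background_filter(
            cm, reads, ann, n_windows=40, min_gene_distance=1000, seed=1
        )
        assert cutoff == pytest.approx(5.0, abs=1.0)  # 500 bp * 1/100 bp
        assert kept.gene_ids == ["g1"]
        assert report.removed["gene_id"].tolist() == ["g2"]

    def test_seeded_windows_reproducible(self):
        ann = self._annotation()
        w1 = sample_background_windows(ann, 30, 1000, seed=5)
        w2 = sample_background_windows(ann, 30, 1000, seed=5)
        assert w1 == w2
        starts = sorted(s for _, s, _ in w1)
        assert all(b - a >= 500 for a, b in zip(starts, starts[1:]))

    def test_too_many_windows_errors(self):
        ann = self._annotation()
        with pytest.raises(ValueError, match="too small"):
            sample_background_windows(ann, 10_000, 1000, seed=0)


def test_filters_commute_with_relabeling():
    rng = np.random.default_rng(3)
    data = pd.DataFrame(
        rng.poisson(100, size=(20, 3)), columns=list("abc"),
        index=[f"g{i}" for i in range(20)],
    )
    cm = CountMatrix(data).normalize()
    kept1, _ = filter_low_expression(cm, 0.25)
    perm = rng.permutation(20)
    cm2 = CountMatrix(data.iloc[perm], normalized=True)
    kept2, _ = filter_low_expression(cm2, 0.25)
    assert set(kept1.gene_ids) == set(kept2.gene_ids)


class TestSamInput:
    SAM = (
        "@HD\tVN:1.6\tSO:coordinate\n"
        "@SQ\tSN:chr1\tLN:20000\n"
        "t00/r1\t0\tchr1\t1501\t60\t50M\t*\t0\t0\t*\t*\n"
        "t00/r2\t16\tchr1\t2951\t60\t50M\t*\t0\t0\t*\t*\n"
        "t02/r3\t0\tchr1\t5100\t60\t50M\t*\t0\t0\t*\t*\n"
    )

    def test_sam_reads_counted_like_bed(self, tmp_path, two_gene_annotation):
        from ccgpipe.counts import reads_from_sam

        p = tmp_path / "reads.sam"
        p.write_text(self.SAM)
        reads = reads_from_sam(p)
        # sample labels from query-name prefixes, 0-based half-open coords
        assert reads["name"].tolist() == ["t00", "t00", "t02"]
        assert reads["start"].tolist() == [1500, 2950, 5099]
        cm = count_exonic(reads, two_gene_annotation)
        assert cm.data.loc["gA", "t00"] == 2  # 5' bases 1500 and 2999
        assert cm.data.loc["gB", "t02"] == 1
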