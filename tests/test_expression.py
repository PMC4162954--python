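"""Differential-expression filtering, fold-change dialects, BH and concordance."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mirreg.expression import (
    ConcordanceReport,
    DERecord,
    DuplicateFeatureError,
    FeatureKind,
    FoldChangeDialectError,
    KindMismatchError,
    MissingFDRError,
    Thresholds,
    benjamini_hochberg,
    classify_cross_cell_line,
    filter_gene_de,
    filter_mirna_de,
    harmonise_mirna_id,
    log2_to_signed_fold,
    relative_quantification,
    signed_fold_to_log2,
)


def mirna(fid, fc, p, line="A"):
    return DERecord(fid, FeatureKind.MIRNA, line, fc, p)


def gene(fid, fc, p, fdr, line="A"):
    return DERecord(fid, FeatureKind.GENE, line, fc, p, fdr)


class TestSignedFold:
    @pytest.mark.parametrize("fold, expected", [
        (2.0, 1.0),
        (1.0, 0.0),
        (-1.0, 0.0),
        (-2.0, -1.0),
        (-3.63, -1.860),  # 3.63-fold down
    ])
    def test_conversion(self, fold, expected):
        assert signed_fold_to_log2(fold) == pytest.approx(expected, abs=1e-3)

    @pytest.mark.parametrize("bad", [0.0, 0.5, -0.9, float("nan"), float("inf")])
    def test_rejects_dialect_violations(self, bad):
        with pytest.raises(FoldChangeDialectError):
            signed_fold_to_log2(bad)

    def test_error_names_offending_row(self):
        with pytest.raises(FoldChangeDialectError, match="row 7"):
            signed_fold_to_log2(0.3, label="7")

    @given(st.floats(min_value=1.0, max_value=100.0, exclude_min=True))
    def test_round_trip(self, fold):
        for signed in (fold, -fold):
            back = log2_to_signed_fold(signed_fold_to_log2(signed))
            assert back == pytest.approx(signed, abs=1e-6)

    def test_unit_folds_collapse_to_no_change(self):
        # +1 and -1 both mean "unchanged"; the inverse maps log2fc 0 to +1
        assert log2_to_signed_fold(signed_fold_to_log2(-1.0)) == 1.0


class TestRelativeQuantification:
    @pytest.mark.parametrize("ddct, expected", [
        (0.0, 1.0),
        (1.0, 0.5),
        (3.943, 0.065),  # ~6.5% residual expression after knockdown
    ])
    def test_values(self, ddct, expected):
        assert relative_quantification(ddct) == pytest.approx(expected, abs=1e-3)

    def test_monotone_decreasing_and_positive(self):
        values = [relative_quantification(x) for x in (-2, 0, 2, 10)]
        assert all(v > 0 for v in values)
        assert values == sorted(values, reverse=True)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            relative_quantification(float("nan"))


def bh_oracle(ps):
    """Independent step-up enumeration: adj_i = min over j with p_j >= p_i of m*p_j/rank_j."""
    m = len(ps)
    order = sorted(range(m), key=lambda i: ps[i])
    adj = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, m * ps[i] / rank_from_top)
        adj[i] = running
    return adj


class TestBenjaminiHochberg:
    @pytest.mark.parametrize("ps, expected", [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([0.5, 0.5, 0.5], [0.5, 0.5, 0.5]),
    ])
    def test_known_values(self, ps, expected):
        assert benjamini_hochberg(ps) == pytest.approx(expected)

    @given(st.lists(st.sampled_from([0.001, 0.01, 0.02, 0.05, 0.2, 0.5, 0.9, 1.0]),
                    min_size=1, max_size=6))
    def test_matches_step_up_oracle(self, ps):
        assert benjamini_hochberg(ps) == pytest.approx(bh_oracle(ps))

    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=20))
    def test_adjusted_at_least_raw_and_bounded(self, ps):
        adj = benjamini_hochberg(ps)
        assert all(0 <= a <= 1 for a in adj)
        assert all(a >= p - 1e-12 for a, p in zip(adj, ps))

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_empty(self):
        assert benjamini_hochberg([]) == []


class TestFilters:
    def test_mirna_boundary_inclusive(self, thresholds):
        records = [mirna("m1", -1.0, 0.05), mirna("m2", -1.0, 0.051)]
        kept = filter_mirna_de(records, thresholds)
        assert [r.feature_id for r in kept] == ["m1"]

    def test_mirna_count_and_order(self, thresholds):
        records = [mirna(f"m{i}", 1.0, p) for i, p in enumerate(
            [0.2, 0.01, 0.6, 0.04, 0.05, 0.7, 0.9, 0.03, 0.8, 0.99])]
        kept = filter_mirna_de(records, thresholds)
        assert len(kept) == 4
        assert [r.feature_id for r in kept] == ["m1", "m3", "m4", "m7"]

    def test_mirna_rejects_gene_records(self, thresholds):
        with pytest.raises(KindMismatchError):
            filter_mirna_de([gene("g", 1.0, 0.01, 0.01)], thresholds)

    @pytest.mark.parametrize("fc, p, fdr, kept", [
        (1.0, 0.01, 0.05, True),   # all boundaries inclusive
        (0.9, 0.001, 0.01, False),  # below 2-fold
        (2.0, 0.02, 0.01, False),   # p above cut-off
        (-1.5, 0.005, 0.06, False),  # fdr above cut-off
        (-1.0, 0.01, 0.05, True),
    ])
    def test_gene_thresholds(self, thresholds, fc, p, fdr, kept):
        result = filter_gene_de([gene("g", fc, p, fdr)], thresholds)
        assert bool(result) is kept

    def test_gene_count(self, thresholds):
        records = ([gene(f"s{i}", 1.5, 0.001, 0.01) for i in range(7)]
                   + [gene(f"n{i}", 0.5, 0.001, 0.01) for i in range(8)]
                   + [gene(f"q{i}", 1.5, 0.5, 0.01) for i in range(5)])
        assert len(filter_gene_de(records, thresholds)) == 7

    def test_gene_missing_fdr_named(self, thresholds):
        with pytest.raises(MissingFDRError, match="gX"):
            filter_gene_de([DERecord("gX", FeatureKind.GENE, "A", 1.0, 0.01)],
                           thresholds)

    def test_filters_idempotent(self, thresholds):
        mirnas = [mirna(f"m{i}", -1.0, p) for i, p in enumerate([0.01, 0.2, 0.05])]
        genes = [gene(f"g{i}", fc, 0.001, 0.01) for i, fc in enumerate([1.5, 0.3, -2.0])]
        once_m = filter_mirna_de(mirnas, thresholds)
        once_g = filter_gene_de(genes, thresholds)
        assert filter_mirna_de(once_m, thresholds) == once_m
        assert filter_gene_de(once_g, thresholds) == once_g


class TestHarmonisation:
    @pytest.mark.parametrize("a, b", [
        ("hsa-miR-148a", "mir-148a"),
        ("hsa-mir-135b", "MIR-135B"),
        ("miR-9*", "hsa-miR-9*"),
    ])
    def test_equivalent_spellings(self, a, b):
        assert harmonise_mirna_id(a) == harmonise_mirna_id(b)

    @pytest.mark.parametrize("a, b", [
        ("miR-9", "miR-9*"),          # star strand preserved
        ("miR-125b-5p", "miR-125b-3p"),  # arm suffixes preserved
        ("miR-181a", "miR-181a-2*"),
    ])
    def test_distinct_mirnas_stay_distinct(self, a, b):
        assert harmonise_mirna_id(a) != harmonise_mirna_id(b)


class TestConcordance:
    def test_published_direction_examples(self):
        # miR-135b* falls in both lines; miR-181a-2* flips sign between them
        a = [mirna("miR-135b*", signed_fold_to_log2(-3.04), 0.01, "2102Ep"),
             mirna("miR-181a-2*", signed_fold_to_log2(3.05), 0.01, "2102Ep")]
        b = [mirna("hsa-miR-135b*", signed_fold_to_log2(-2.33), 0.01, "NTera-2"),
             mirna("miR-181a-2*", signed_fold_to_log2(-4.47), 0.01, "NTera-2")]
        report = classify_cross_cell_line(a, b)
        assert report.mutual_same_direction == {"mir-135b*"}
        assert report.opposite_direction == {"mir-181a-2*"}

    def test_disjoint_sets(self):
        report = classify_cross_cell_line([mirna("m1", 1.0, 0.01)],
                                          [mirna("m2", 1.0, 0.01)])
        assert report.shared == frozenset()
        assert report.exclusive_a == {"m1"}
        assert report.exclusive_b == {"m2"}

    def test_duplicate_ids_rejected(self):
        dup = [mirna("miR-1", 1.0, 0.01), mirna("hsa-miR-1", -1.0, 0.01)]
        with pytest.raises(DuplicateFeatureError):
            classify_cross_cell_line(dup, [])

    @given(st.data())
    def test_partition_invariant(self, data):
        ids = [f"m{i}" for i in range(12)]
        ids_a = data.draw(st.lists(st.sampled_from(ids), unique=True, max_size=12))
        ids_b = data.draw(st.lists(st.sampled_from(ids), unique=True, max_size=12))
        sign = st.sampled_from([-1.0, 1.0])
        a = [mirna(i, data.draw(sign), 0.01) for i in ids_a]
        b = [mirna(i, data.draw(sign), 0.01) for i in ids_b]
        report = classify_cross_cell_line(a, b)
        union = (report.exclusive_a | report.exclusive_b
                 | report.mutual_same_direction | report.opposite_direction)
        assert union == set(ids_a) | set(ids_b)
        total = (len(report.exclusive_a) + len(report.exclusive_b)
                 + len(report.mutual_same_direction) + len(report.opposite_direction))
        assert total == len(union)
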