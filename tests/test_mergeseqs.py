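import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asvpost import (
    AsvpostError,
    AsvRecord,
    Dataset,
    FeatureTable,
    MergePolicy,
    SplitPair,
    merge_features,
    overlap_merge,
    split_concatenated,
)

dna = st.text(alphabet="ACGT", min_size=1, max_size=60)


class TestSplitConcatenated:
    def test_splits_internal_spacer(self):
        pair = split_concatenated("ACGT" + "N" * 10 + "TTGG")
        assert pair == SplitPair(left="ACGT", right="TTGG", spacer_len=10)

    @pytest.mark.parametrize(
        "seq",
        [
            "ACGTNACGT",                      # run shorter than the threshold
            "NNNNNNACGT",                     # run at the 5' edge
            "ACGTNNNNNN",                     # run at the 3' edge
            "ACGT",                           # no N at all
            "AC" + "N" * 6 + "GG" + "N" * 6 + "TT",  # two runs: ambiguous
        ],
    )
    def test_non_splittable_returns_none(self, seq):
        assert split_concatenated(seq, spacer_min_run=5) is None

    def test_fragment_with_stray_n_not_split(self):
        assert split_concatenated("ACNGT" + "N" * 8 + "TTGG") is None

    def test_custom_min_run(self):
        assert split_concatenated("ACGTNNNACGT", spacer_min_run=3) == SplitPair(
            "ACGT", "ACGT", 3
        )

    @given(left=dna.filter(lambda s: "N" not in s), right=dna, run=st.integers(5, 15))
    @settings(max_examples=50, deadline=None)
    def test_split_inverts_concatenation(self, left, right, run):
        pair = split_concatenated(left + "N" * run + right, spacer_min_run=5)
        assert pair == SplitPair(left, right, run)


class TestOverlapMerge:
    def test_recovers_template_from_overlapping_fragments(self):
        template = "ACGTACGGTTACCAGATCAGATCAGGCA"  # 28-mer
        pair = SplitPair(left=template[:20], right=template[8:], spacer_len=10)
        merged = overlap_merge(pair, MergePolicy(min_overlap=12))
        assert merged == template
        assert len(merged) == 20 + 20 - 12

    def test_identical_fragments_merge_to_themselves(self):
        x = "ACGTACGTACGTACG"
        assert overlap_merge(SplitPair(x, x, 10)) == x

    def test_overlap_below_minimum_not_merged(self):
        left = "GATTACAGATTACAGATCA"
        right = left[-11:] + "GGGGCCCCAAA"  # exact 11-base junction only
        pair = SplitPair(left, right, 10)
        assert overlap_merge(pair, MergePolicy(min_overlap=12)) is None

    def test_longest_acceptable_overlap_preferred(self):
        # left suffix of length 16 matches the right prefix as well as a
        # shorter internal repeat; the longest wins
        left = "TTTT" + "ACGT" * 4
        right = "ACGT" * 4 + "GGGG"
        merged = overlap_merge(SplitPair(left, right, 10), MergePolicy(min_overlap=4))
        assert merged == "TTTT" + "ACGT" * 4 + "GGGG"

    def test_mismatch_tolerance_keeps_left_base(self):
        left = "GGGGGGGGACGTACGTACGTA"  # 21
        right = "CCGTACGTACGTATTTTTTT"   # overlap 13 with 1 mismatch at pos 0
        pair = SplitPair(left, right, 10)
        assert overlap_merge(pair, MergePolicy(min_overlap=12)) is None
        merged = overlap_merge(
            pair, MergePolicy(min_overlap=12, max_mismatch_fraction=0.1)
        )
        assert merged == left + right[13:]

    @given(
        core=st.text(alphabet="ACGT", min_size=12, max_size=30),
        lpad=st.text(alphabet="ACGT", min_size=1, max_size=20),
        rpad=st.text(alphabet="ACGT", min_size=1, max_size=20),
    )
    @settings(max_examples=50, deadline=None)
    def test_merged_length_law(self, core, lpad, rpad):
        left, right = lpad + core, core + rpad
        merged = overlap_merge(SplitPair(left, right, 10))
        assert merged is not None
        true_overlap = len(left) + len(right) - len(merged)
        assert len(merged) == len(left) + len(right) - true_overlap
        assert true_overlap >= len(core)  # repeats can only lengthen the match


def build_dataset(records, counts, taxonomy=None):
    table = FeatureTable.from_arrays(
        np.array(counts), [r.id for r in records],
        [f"S{j}" for j in range(np.array(counts).shape[1])],
    )
    return Dataset(table=table, sequences=records, taxonomy=taxonomy).validate()


class TestMergeFeatures:
    def test_collapse_sums_counts_and_keeps_dominant_id(self):
        template = "ACGTACGGTTACCAGATCAGATCAGGCA"
        left, right = template[:20], template[8:]
        records = [
            AsvRecord("big", left + "N" * 10 + right),
            AsvRecord("small", left + "N" * 12 + right),
        ]
        ds = build_dataset(records, [[5, 0], [3, 2]])
        out, report = merge_features(ds)
        assert out.table.feature_ids == ["big"]
        assert out.table.counts.tolist() == [[8, 2]]
        assert out.sequences == [AsvRecord("big", template)]
        assert report.n_merged == 2
        assert report.n_collapsed == 1

    def test_collapse_tie_keeps_first_in_input_order(self):
        records = [
            AsvRecord("first", "ACGTACGTACGTACGT"),
            AsvRecord("second", "ACGTACGTACGTACGT"),
        ]
        ds = build_dataset(records, [[2, 1], [1, 2]])  # equal totals
        out, _ = merge_features(ds)
        assert out.table.feature_ids == ["first"]

    def test_passthrough_without_spacer(self):
        records = [AsvRecord("plain", "ACGTACGTACGT")]
        ds = build_dataset(records, [[4]])
        out, report = merge_features(ds)
        assert report.n_passthrough == 1
        assert out.sequences == records

    def test_non_overlapping_pair_stays_concatenated(self):
        records = [AsvRecord("gap", "ACGTACGTACGTACG" + "N" * 10 + "TTTTGGGGCCCCAAA")]
        ds = build_dataset(records, [[4]])
        out, report = merge_features(ds)
        assert report.n_kept_concatenated == 1
        assert out.sequences[0].sequence == records[0].sequence

    def test_outcome_counts_partition_features(self):
        template = "ACGTACGGTTACCAGATCAGATCAGGCA"
        records = [
            AsvRecord("m", template[:20] + "N" * 10 + template[8:]),
            AsvRecord("g", "AAAAAAAAAAAAAAA" + "N" * 10 + "CCCCCCCCCCCCCCC"),
            AsvRecord("p", "ACGTACGTACGT"),
        ]
        ds = build_dataset(records, [[1], [1], [1]])
        _, report = merge_features(ds)
        assert (
            report.n_merged + report.n_kept_concatenated + report.n_passthrough
            == 3
        )
        assert dict(report.outcomes) == {
            "m": "merged",
            "g": "kept_concatenated",
            "p": "passthrough",
        }

    def test_column_totals_conserved_and_idempotent(self):
        rng = np.random.default_rng(11)
        from asvpost import simulate_concatenated_pairs

        records, _ = simulate_concatenated_pairs(
            30, read_len=60, overlap_range=(-10, 30), seed=5
        )
        counts = rng.integers(0, 500, size=(30, 4))
        ds = build_dataset(records, counts)
        once, _ = merge_features(ds)
        assert (
            once.table.counts.sum(axis=0) == ds.table.counts.sum(axis=0)
        ).all()
        twice, report2 = merge_features(once)
        assert twice.table == once.table
        assert [r.sequence for r in twice.sequences] == [
            r.sequence for r in once.sequences
        ]
        assert report2.n_merged == 0 and report2.n_collapsed == 0

    def test_taxonomy_of_kept_id_retained(self):
        records = [
            AsvRecord("a", "ACGTACGTACGTACGT"),
            AsvRecord("b", "ACGTACGTACGTACGT"),
        ]
        taxonomy = pd.DataFrame(
            {"Kingdom": ["Bacteria", "Fungi"]}, index=["a", "b"]
        )
        ds = build_dataset(records, [[1, 0], [9, 9]], taxonomy=taxonomy)
        out, _ = merge_features(ds)
        assert out.table.feature_ids == ["b"]
        assert out.taxonomy.loc["b", "Kingdom"] == "Fungi"

    def test_requires_sequences(self):
        table = FeatureTable.from_arrays(np.array([[1]]), ["a"], ["s"])
        with pytest.raises(AsvpostError, match="sequences"):
            merge_features(Dataset(table=table))
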