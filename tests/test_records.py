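"""Record model, vocabulary construction, bucketing, encoding, and file I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from haloehr.records import (
    BucketScheme,
    MalformedRecordError,
    OutOfRangeError,
    PatientRecord,
    RecordMatrix,
    UnknownCodeError,
    Visit,
    build_vocabulary,
    decode_record,
    discretize_value,
    encode_record,
    equal_frequency_edges,
    read_records,
    read_vocabulary,
    reconstitute_value,
    write_records,
    write_vocabulary,
)


class TestVocabulary:
    def test_counts_all_code_kinds(self, toy_records):
        scheme = BucketScheme("gap_days", [0.0, 10.0, 30.0])
        vocab = build_vocabulary(toy_records, [scheme], seed=0)
        # 2 medical + 1 label + 2 buckets + start + end
        assert vocab.size == 7

    def test_minimal_vocabulary(self):
        recs = [PatientRecord("p", set(), [Visit({"A"})])]
        vocab = build_vocabulary(recs, [], seed=0)
        assert vocab.size == 3
        assert set(vocab.kinds) == {"medical", "start", "end"}

    def test_simulated_cohort_count(self):
        from haloehr.simulate import desk_config, simulate_cohort

        cfg = desk_config(n_codes=100, n_labels=4)
        recs = simulate_cohort(cfg, 300, seed=0)
        vocab = build_vocabulary(recs, [], seed=0)
        # all 100 codes and 4 labels observed at n=300, plus start/end
        assert vocab.size == 106

    def test_deterministic_under_seed(self, toy_records):
        v1 = build_vocabulary(toy_records, [], seed=42)
        v2 = build_vocabulary(toy_records, [], seed=42)
        assert v1.code_strings == v2.code_strings
        v3 = build_vocabulary(toy_records * 3, [], seed=7)
        assert v3.size == v1.size  # duplicates collapse

    def test_duplicate_code_strings_rejected(self):
        recs = [PatientRecord("p", {"A"}, [Visit({"A"})])]  # label == medical code
        with pytest.raises(ValueError):
            build_vocabulary(recs, [], seed=0)

    def test_special_codes_lead_the_order(self, toy_records):
        vocab = build_vocabulary(toy_records, [], seed=0)
        assert vocab.kind_of(0) == "start"
        assert vocab.kind_of(1) == "end"

    def test_unknown_code_raises(self, tiny_vocab):
        with pytest.raises(UnknownCodeError):
            tiny_vocab.id_of("nope")


class TestBuckets:
    def test_heart_rate_93_is_bucket_7(self, heart_scheme):
        assert discretize_value(93, heart_scheme) == 7

    def test_left_edge_is_bucket_1(self, heart_scheme):
        assert discretize_value(heart_scheme.edges[0], heart_scheme) == 1

    def test_out_of_range_raises(self, heart_scheme):
        with pytest.raises(OutOfRangeError):
            discretize_value(400.0, heart_scheme)
        with pytest.raises(OutOfRangeError):
            discretize_value(-1.0, heart_scheme)

    @settings(max_examples=200, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=399.999))
    def test_matches_linear_scan_oracle(self, value):
        scheme = BucketScheme("hr", [0, 40, 50, 60, 90, 100, 250, 400.0])
        k = discretize_value(value, scheme)
        # independent oracle: scan edges left to right
        expect = next(i + 1 for i in range(scheme.n_buckets)
                      if scheme.edges[i] <= value < scheme.edges[i + 1])
        assert k == expect

    def test_reconstitute_containment_and_roundtrip(self, heart_scheme):
        rng = np.random.default_rng(0)
        for k in range(1, heart_scheme.n_buckets + 1):
            v = reconstitute_value(k, heart_scheme, rng)
            assert heart_scheme.edges[k - 1] <= v < heart_scheme.edges[k]
            assert discretize_value(v, heart_scheme) == k

    def test_reconstitute_uniform_mean(self):
        scheme = BucketScheme("x", [0.0, 10.0])
        rng = np.random.default_rng(1)
        draws = np.array([reconstitute_value(1, scheme, rng) for _ in range(100_000)])
        # uniform on [0,10): mean 5, sd 10/sqrt(12); 3 sigma of the mean
        assert abs(draws.mean() - 5.0) < 3 * (10 / np.sqrt(12)) / np.sqrt(draws.size)

    def test_invalid_index_raises(self, heart_scheme):
        with pytest.raises(OutOfRangeError):
            reconstitute_value(0, heart_scheme, np.random.default_rng(0))
        with pytest.raises(OutOfRangeError):
            reconstitute_value(99, heart_scheme, np.random.default_rng(0))

    def test_equal_frequency_edges_cover_data(self):
        rng = np.random.default_rng(2)
        values = rng.lognormal(3, 0.5, size=500)
        edges = equal_frequency_edges(values, 5)
        scheme = BucketScheme("v", edges)
        ks = [discretize_value(v, scheme) for v in values]
        counts = np.bincount(ks)[1:]
        assert counts.sum() == 500  # every value falls in range


class TestEncoding:
    def test_hand_constructed_layout(self, tiny_vocab):
        rec = PatientRecord("p", {"L1"}, [Visit({"A"}), Visit({"A", "B"})])
        rm = encode_record(rec, tiny_vocab, (), t_max=4)
        M = rm.matrix
        ones = {(r, c) for r, c in zip(*np.nonzero(M))}
        expect = {
            (0, tiny_vocab.id_of("<start>")),
            (1, tiny_vocab.id_of("L1")),
            (2, tiny_vocab.id_of("A")),
            (3, tiny_vocab.id_of("A")), (3, tiny_vocab.id_of("B")),
            (4, tiny_vocab.id_of("<end>")),
        }
        assert ones == expect
        assert rm.true_length == 2

    def test_zero_visit_record(self, tiny_vocab):
        rm = encode_record(PatientRecord("p", {"L1"}, []), tiny_vocab, (), t_max=3)
        assert rm.true_length == 0
        assert rm.matrix[2, tiny_vocab.end_id] == 1
        assert rm.matrix[3:].sum() == 0

    def test_start_end_rows_have_single_one(self, small_cohort, small_vocab):
        cfg, records = small_cohort
        for rec in records[:40]:
            rm = encode_record(rec, small_vocab, cfg.schemes, t_max=cfg.max_visits)
            assert rm.matrix[0].sum() == 1
            assert rm.matrix[rm.true_length + 2].sum() == 1
            assert rm.matrix[rm.true_length + 3:].sum() == 0

    def test_roundtrip_on_simulated_records(self, small_cohort, small_vocab):
        cfg, records = small_cohort
        rng = np.random.default_rng(5)
        for rec in records[:40]:
            rm = encode_record(rec, small_vocab, cfg.schemes, t_max=cfg.max_visits)
            back = decode_record(rm, small_vocab, cfg.schemes, rng)
            assert back.labels == rec.labels
            assert len(back.visits) == len(rec.visits)
            for v0, v1 in zip(rec.visits, back.visits):
                assert v0.codes == v1.codes
                # continuous values agree up to bucket resolution
                assert len(v0.labs) == len(v1.labs)
                if v0.gap_days is None:
                    assert v1.gap_days is None

    def test_reencode_after_decode_is_identical(self, small_cohort, small_vocab):
        cfg, records = small_cohort
        rng = np.random.default_rng(6)
        for rec in records[:30]:
            rm = encode_record(rec, small_vocab, cfg.schemes, t_max=cfg.max_visits)
            back = decode_record(rm, small_vocab, cfg.schemes, rng)
            rm2 = encode_record(back, small_vocab, cfg.schemes, t_max=cfg.max_visits)
            np.testing.assert_array_equal(rm.matrix, rm2.matrix)

    def test_truncation_keeps_earliest_and_appends_end(self, tiny_vocab):
        rec = PatientRecord("p", set(), [Visit({"A"}), Visit({"B"}), Visit({"A"})])
        rm = encode_record(rec, tiny_vocab, (), t_max=2)
        assert rm.true_length == 2
        assert rm.matrix[2, tiny_vocab.id_of("A")] == 1
        assert rm.matrix[4, tiny_vocab.end_id] == 1

    def test_unknown_code_named_in_error(self, tiny_vocab):
        rec = PatientRecord("p", set(), [Visit({"ZZZ"})])
        with pytest.raises(UnknownCodeError, match="ZZZ"):
            encode_record(rec, tiny_vocab, (), t_max=3)

    def test_degenerate_empty_visits_preserved(self, tiny_vocab):
        rec = PatientRecord("p", set(), [Visit(set()), Visit({"A"})])
        rm = encode_record(rec, tiny_vocab, (), t_max=4)
        back = decode_record(rm, tiny_vocab, (), np.random.default_rng(0))
        assert [v.codes for v in back.visits] == [set(), {"A"}]

    def test_decode_without_end_flags_truncated(self, tiny_vocab):
        M = np.zeros((5, tiny_vocab.size))
        M[0, tiny_vocab.start_id] = 1
        M[2, tiny_vocab.id_of("A")] = 1
        M[3, tiny_vocab.id_of("B")] = 1
        M[4, tiny_vocab.id_of("A")] = 1
        with pytest.warns(UserWarning, match="truncated"):
            rec = decode_record(RecordMatrix(M, 3), tiny_vocab, ())
        assert rec.truncated
        assert len(rec.visits) == 3

    def test_two_gap_buckets_resolved_to_lowest_with_warning(self):
        scheme = BucketScheme("gap_days", [0.0, 10.0, 30.0])
        vocab = build_vocabulary(
            [PatientRecord("p", set(), [Visit({"A"}), Visit({"A"}, gap_days=5.0)])],
            [scheme], seed=0)
        M = np.zeros((5, vocab.size))
        M[0, vocab.start_id] = 1
        M[2, vocab.id_of("A")] = 1
        M[3, vocab.id_of(scheme.bucket_code(1))] = 1
        M[3, vocab.id_of(scheme.bucket_code(2))] = 1
        M[4, vocab.end_id] = 1
        with pytest.warns(UserWarning, match="gap buckets"):
            rec = decode_record(RecordMatrix(M, 2), vocab, [scheme],
                                np.random.default_rng(0))
        assert 0.0 <= rec.visits[1].gap_days < 10.0


class TestIO:
    def test_records_roundtrip(self, tmp_path, toy_records):
        path = tmp_path / "r.jsonl"
        write_records(path, toy_records)
        back = read_records(path)
        assert back == toy_records

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.jsonl"
        path.write_text("")
        assert read_records(path) == []

    def test_malformed_line_cites_line_number(self, tmp_path, toy_records):
        path = tmp_path / "bad.jsonl"
        write_records(path, toy_records)
        lines = path.read_text().splitlines()
        lines.insert(1, "{not json")
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(MalformedRecordError, match="line 2"):
            read_records(path)

    def test_vocabulary_roundtrip(self, tmp_path, small_vocab):
        path = tmp_path / "vocab.tsv"
        write_vocabulary(path, small_vocab)
        back = read_vocabulary(path)
        assert back.code_strings == small_vocab.code_strings
        assert back.kinds == small_vocab.kinds
        assert back.content_hash() == small_vocab.content_hash()

    def test_continuous_record_roundtrip(self, tmp_path, small_cohort):
        _, records = small_cohort
        path = tmp_path / "c.jsonl"
        write_records(path, records[:20])
        assert read_records(path) == records[:20]
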