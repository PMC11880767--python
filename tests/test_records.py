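"""Dataset I/O, identity, deduplication, splitting, stratification."""

import math

import numpy as np
import pytest

from kcatnet.errors import (
    EmptyDatasetError,
    FormatError,
    KcatError,
    SplitError,
    StratificationError,
)
from kcatnet.records import (
    KcatRecord,
    deduplicate,
    pairwise_identity,
    read_dataset,
    similarity_bin_label,
    split_dataset,
    stratify_by_similarity,
    write_dataset,
)


def _rec(rid, seq, smiles="CCO", kcat=10.0):
    return KcatRecord(record_id=rid, sequence=seq, smiles=smiles, kcat=kcat)


class TestKcatRecord:
    def test_log_kcat_derived(self):
        assert _rec("a", "MKV").log_kcat == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("kcat", [0.0, -1.0, float("nan"), float("inf")])
    def test_invalid_kcat_rejected(self, kcat):
        with pytest.raises(KcatError):
            _rec("a", "MKV", kcat=kcat)

    def test_empty_sequence_rejected(self):
        with pytest.raises(KcatError):
            _rec("a", "")

    def test_ec_class_range(self):
        with pytest.raises(KcatError):
            KcatRecord(record_id="a", sequence="MKV", smiles="O", kcat=1.0, ec_class=8)


class TestReadDataset:
    def _write(self, tmp_path, rows, header="record_id\tsequence\tsmiles\tkcat"):
        path = tmp_path / "d.tsv"
        path.write_text("\n".join([header] + rows) + "\n")
        return path

    def test_roundtrip_and_stable_ids(self, tmp_path):
        rows = [f"r{i}\tMKVA\tCCO\t{10**i}" for i in range(3)]
        path = self._write(tmp_path, rows)
        records1, report = read_dataset(path)
        records2, _ = read_dataset(path)
        assert report.n_accepted == 3 and report.n_rejected == 0
        assert [r.record_id for r in records1] == [r.record_id for r in records2]
        assert records1[1].log_kcat == pytest.approx(1.0)

    def test_nonpositive_kcat_rejected_with_report(self, tmp_path):
        path = self._write(tmp_path, ["a\tMKV\tCCO\t0", "b\tMKV\tCCO\t5", "c\tMKV\tCCO\tbad"])
        records, report = read_dataset(path)
        assert [r.record_id for r in records] == ["b"]
        assert report.n_rejected == 2
        assert {i for i, _ in report.rejected} == {0, 2}

    def test_missing_column_named(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("record_id\tsequence\tkcat\na\tMKV\t1\n")
        with pytest.raises(FormatError, match="smiles"):
            read_dataset(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "d.tsv"
        path.write_text("")
        with pytest.raises(EmptyDatasetError):
            read_dataset(path)

    def test_write_read_roundtrip(self, tmp_path):
        records = [_rec("a", "MKVA", kcat=3.5), _rec("b", "MKVC", smiles="O")]
        write_dataset(records, tmp_path / "out.tsv")
        back, _ = read_dataset(tmp_path / "out.tsv")
        assert [(r.record_id, r.sequence, r.smiles) for r in back] == [
            ("a", "MKVA", "CCO"),
            ("b", "MKVC", "O"),
        ]
        assert back[0].kcat == pytest.approx(3.5, rel=1e-12)


class TestPairwiseIdentity:
    def test_identical(self):
        assert pairwise_identity("ACDE", "ACDE") == 1.0

    def test_single_mismatch(self):
        # global alignment: 3 matches over alignment length 4
        assert pairwise_identity("ACDE", "ACDF") == pytest.approx(0.75)

    def test_symmetry_on_random_pairs(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(50):
            a = "".join(rng.choice(alphabet, size=rng.integers(5, 30)))
            b = "".join(rng.choice(alphabet, size=rng.integers(5, 30)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)

    def test_empty_sequence_error(self):
        with pytest.raises(KcatError):
            pairwise_identity("", "ACDE")


class TestDeduplicate:
    def test_keep_longest_among_near_identical(self, rng):
        base = "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=100))
        longer = base + "AC"  # identity 100/102 > 0.9
        records = [_rec("short", base), _rec("long", longer)]
        kept, removed = deduplicate(records)
        assert [r.record_id for r in kept] == ["long"]
        assert [r.record_id for r in removed] == ["short"]

    def test_below_threshold_both_kept(self, rng):
        a = "".join(rng.choice(list("ACDEFG"), size=60))
        b = "".join(rng.choice(list("HIKLMN"), size=60))
        kept, removed = deduplicate([_rec("a", a), _rec("b", b)])
        assert len(kept) == 2 and not removed

    def test_distinct_substrates_never_merged(self):
        records = [_rec("a", "MKVAMKVA", smiles="CCO"), _rec("b", "MKVAMKVA", smiles="O")]
        kept, _ = deduplicate(records)
        assert len(kept) == 2

    def test_idempotent_and_partition(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        base = "".join(rng.choice(alphabet, size=80))
        records = [
            _rec("a", base),
            _rec("b", base + "GG"),
            _rec("c", "".join(rng.choice(alphabet, size=80))),
            _rec("d", base[:40], smiles="O"),
        ]
        kept, removed = deduplicate(records)
        assert {r.record_id for r in kept} | {r.record_id for r in removed} == {
            r.record_id for r in records
        }
        assert not ({r.record_id for r in kept} & {r.record_id for r in removed})
        kept2, removed2 = deduplicate(kept)
        assert [r.record_id for r in kept2] == [r.record_id for r in kept]
        assert not removed2


class TestSplitDataset:
    def _records(self, n, rng):
        return [_rec(f"r{i:03d}", "MKVA") for i in range(n)]

    def test_exact_ratio_sizes(self, rng):
        split = split_dataset(self._records(100, rng), seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (80, 10, 10)

    def test_rounding_remainder_to_train(self, rng):
        split = split_dataset(self._records(11, rng), seed=1)
        assert (len(split.train), len(split.validation), len(split.test)) == (9, 1, 1)

    def test_deterministic_given_seed(self, rng):
        records = self._records(50, rng)
        a = split_dataset(records, seed=7)
        b = split_dataset(records, seed=7)
        assert a.train == b.train and a.validation == b.validation and a.test == b.test
        c = split_dataset(records, seed=8)
        assert a.train != c.train

    def test_partition_exact(self, rng):
        records = self._records(37, rng)
        split = split_dataset(records, seed=3)
        all_ids = split.train + split.validation + split.test
        assert sorted(all_ids) == sorted(r.record_id for r in records)

    def test_too_few_records(self, rng):
        with pytest.raises(SplitError):
            split_dataset(self._records(2, rng), seed=1)

    def test_bad_ratios(self, rng):
        with pytest.raises(SplitError):
            split_dataset(self._records(10, rng), ratios=(0.5, 0.4, 0.2), seed=1)


class TestStratify:
    def test_identical_sequence_in_top_bin(self):
        train = [_rec("t", "MKVAMKVAMKVA")]
        test = [_rec("x", "MKVAMKVAMKVA")]
        bins = stratify_by_similarity(test, train)
        assert {b.label: b.record_ids for b in bins}["90-100%"] == ["x"]

    def test_boundary_half_goes_to_middle_bin(self):
        assert similarity_bin_label(0.5) == "50-90%"
        assert similarity_bin_label(0.9) == "90-100%"
        assert similarity_bin_label(0.49999) == "0-50%"

    def test_bins_partition_test_set(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        train = [_rec(f"t{i}", "".join(rng.choice(alphabet, size=40))) for i in range(5)]
        test = [_rec(f"x{i}", "".join(rng.choice(alphabet, size=40))) for i in range(8)]
        bins = stratify_by_similarity(test, train)
        ids = [rid for b in bins for rid in b.record_ids]
        assert sorted(ids) == sorted(r.record_id for r in test)
        # invariance to train ordering
        bins2 = stratify_by_similarity(test, list(reversed(train)))
        assert [b.record_ids for b in bins] == [b.record_ids for b in bins2]

    def test_empty_train_error(self):
        with pytest.raises(StratificationError):
            stratify_by_similarity([_rec("x", "MKVA")], [])
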