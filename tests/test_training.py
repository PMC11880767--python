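"""Metrics formulas, training loop behaviour, grouped evaluation, t-tests."""

import math

import numpy as np
import pytest
from scipy import stats as scipy_stats
from sklearn.metrics import r2_score

from kcatnet.errors import ConfigError, ShapeError, StatisticsError, TrainingError
from kcatnet.features import build_vocabularies, featurize_records
from kcatnet.network import KcatNetwork, ModelConfig
from kcatnet.records import EnzymeType, KcatRecord
from kcatnet.synthetic import make_synthetic_dataset
from kcatnet.training import (
    TrainConfig,
    compare_groups,
    compute_metrics,
    grouped_metrics,
    multi_round_evaluate,
    train,
)


class TestComputeMetrics:
    def test_hand_case(self):
        report = compute_metrics([0, 1, 2], [0, 1, 1])
        assert report.r2 == pytest.approx(0.5)
        assert report.rmse == pytest.approx(math.sqrt(1 / 3))
        assert report.pcc == pytest.approx(math.sqrt(3) / 2)  # ≈ 0.86603

    def test_perfect_prediction(self):
        report = compute_metrics([1.0, 2.0, 3.5], [1.0, 2.0, 3.5])
        assert report.r2 == 1.0 and report.rmse == 0.0 and report.pcc == pytest.approx(1.0)

    def test_mean_predictor_has_zero_r2(self):
        y = [0.0, 1.0, 2.0, 5.0]
        report = compute_metrics(y, [np.mean(y)] * 4)
        assert report.r2 == pytest.approx(0.0)
        assert report.pcc is None  # constant predictions

    def test_agrees_with_reference_implementations(self, rng):
        y = rng.normal(size=50)
        p = y + rng.normal(scale=0.5, size=50)
        report = compute_metrics(y, p)
        assert report.r2 == pytest.approx(r2_score(y, p), abs=1e-12)
        assert report.pcc == pytest.approx(scipy_stats.pearsonr(y, p).statistic, abs=1e-12)

    def test_constant_y_exp_keeps_rmse(self):
        report = compute_metrics([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
        assert report.r2 is None and report.pcc is None
        assert report.rmse == pytest.approx(math.sqrt(2 / 3))
        assert report.notes

    def test_length_mismatch(self):
        with pytest.raises(ShapeError):
            compute_metrics([1, 2, 3], [1, 2])

    def test_pcc_affine_invariance_r2_not(self, rng):
        y = rng.normal(size=30)
        p = y + rng.normal(scale=0.3, size=30)
        base = compute_metrics(y, p)
        scaled = compute_metrics(y, 3.0 * p + 7.0)
        assert scaled.pcc == pytest.approx(base.pcc, abs=1e-12)
        assert scaled.r2 != pytest.approx(base.r2, abs=1e-6)


class TestCompareGroups:
    def test_identical_groups(self):
        t, p = compare_groups([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_separated_groups_significant(self):
        a = [0.0, 0.001, -0.001, 0.0005]
        b = [1.0, 1.001, 0.999, 1.0005]
        t, p = compare_groups(a, b)
        assert p < 0.01

    def test_welch_matches_scipy_oracle(self, rng):
        a, b = rng.normal(size=12), rng.normal(loc=0.8, size=9)
        t, p = compare_groups(a, b)
        ref = scipy_stats.ttest_ind(a, b, equal_var=False)
        assert t == pytest.approx(ref.statistic) and p == pytest.approx(ref.pvalue)

    def test_swap_flips_sign_same_p(self, rng):
        a, b = rng.normal(size=8), rng.normal(loc=1.0, size=8)
        t1, p1 = compare_groups(a, b)
        t2, p2 = compare_groups(b, a)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_degenerate_variances_rejected(self):
        with pytest.raises(StatisticsError):
            compare_groups([1.0, 1.0, 1.0], [2.0, 2.0])

    def test_small_groups_rejected(self):
        with pytest.raises(StatisticsError):
            compare_groups([1.0], [2.0, 3.0])


@pytest.fixture(scope="module")
def small_run():
    records, structures = make_synthetic_dataset(16, seed=31)
    config = ModelConfig(seed=31, mode="substrate_only")
    seq_vocab, env_vocab = build_vocabularies(records, config)
    feats = featurize_records(records, seq_vocab, env_vocab, config, structures=structures)
    return records, structures, config, seq_vocab, env_vocab, feats


class TestTrain:
    def test_loss_history_and_determinism(self, small_run):
        _, _, config, seq_vocab, env_vocab, feats = small_run
        tc = TrainConfig(epochs=4, batch_size=8, seed=2)

        def run():
            net = KcatNetwork(config, seq_vocab, env_vocab)
            return train(net, feats[:12], feats[12:], tc)

        h1, h2 = run(), run()
        assert len(h1["train_loss"]) == 4 and len(h1["val_loss"]) <= 4
        assert np.allclose(h1["train_loss"], h2["train_loss"], atol=1e-9)
        assert np.allclose(h1["val_loss"], h2["val_loss"], atol=1e-9)

    def test_early_stopping_shortens_history(self, small_run):
        _, _, config, seq_vocab, env_vocab, feats = small_run
        net = KcatNetwork(config, seq_vocab, env_vocab)
        history = train(
            net, feats[:12], feats[12:], TrainConfig(epochs=40, seed=2, patience=2)
        )
        assert len(history["val_loss"]) <= 40

    def test_empty_train_set_rejected(self, small_run):
        _, _, config, seq_vocab, env_vocab, _ = small_run
        net = KcatNetwork(config, seq_vocab, env_vocab)
        with pytest.raises(TrainingError):
            train(net, [], None, TrainConfig(epochs=1))

    def test_invalid_config(self):
        with pytest.raises(ConfigError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ConfigError):
            TrainConfig(epochs=0)


class TestMultiRound:
    def test_round_count_and_structure(self):
        records, structures = make_synthetic_dataset(30, seed=41)
        report = multi_round_evaluate(
            records,
            ModelConfig(seed=41, mode="substrate_only"),
            TrainConfig(epochs=1, seed=41, rounds=2),
            structures=structures,
        )
        assert len(report["rounds"]) == 2
        assert {"seed", "train_r2", "test_r2"} <= set(report["rounds"][0])
        assert report["mean_test_r2"] == pytest.approx(
            np.mean([r["test_r2"] for r in report["rounds"]])
        )

    def test_single_round_equals_direct_run(self):
        from kcatnet.pipeline import fit_pipeline

        records, structures = make_synthetic_dataset(30, seed=43)
        mc = ModelConfig(seed=43, mode="substrate_only")
        tc = TrainConfig(epochs=1, seed=43, rounds=1)
        report = multi_round_evaluate(records, mc, tc, structures=structures)
        direct = fit_pipeline(
            records, model_config=mc, train_config=tc, structures=structures
        )
        assert report["rounds"][0]["test_r2"] == pytest.approx(
            direct.test_metrics.r2, abs=1e-12
        )


class TestGroupedMetrics:
    def _records(self, n, rng, enzyme_types=None):
        out = []
        for i in range(n):
            out.append(
                KcatRecord(
                    record_id=f"g{i}",
                    sequence="MKVAMKVA",
                    smiles="CCO",
                    kcat=float(10 ** rng.normal()),
                    enzyme_type=(enzyme_types[i] if enzyme_types else "unknown"),
                    ec_class=(i % 2) + 1,
                )
            )
        return out

    def test_single_group_equals_ungrouped(self, rng):
        records = self._records(6, rng)
        preds = rng.normal(size=6)
        grouped = grouped_metrics(records, preds, "enzyme_type")
        overall = compute_metrics([r.log_kcat for r in records], preds)
        assert len(grouped) == 1
        assert grouped[0].r2 == pytest.approx(overall.r2)
        assert grouped[0].n == 6

    def test_two_groups_partition_n(self, rng):
        types = ["wild_type"] * 4 + ["mutant"] * 5
        records = self._records(9, rng, enzyme_types=types)
        grouped = grouped_metrics(records, rng.normal(size=9), "enzyme_type")
        assert sum(g.n for g in grouped) == 9
        assert {g.group for g in grouped} == {"wild_type", "mutant"}

    def test_small_group_flagged_skipped(self, rng):
        types = ["wild_type"] * 5 + ["mutant"]
        records = self._records(6, rng, enzyme_types=types)
        grouped = grouped_metrics(records, rng.normal(size=6), "enzyme_type")
        mutant = next(g for g in grouped if g.group == "mutant")
        assert mutant.r2 is None and mutant.notes

    def test_unknown_group_key(self, rng):
        with pytest.raises(ConfigError):
            grouped_metrics(self._records(4, rng), rng.normal(size=4), "organism")

    def test_similarity_bin_requires_train(self, rng):
        with pytest.raises(ConfigError):
            grouped_metrics(self._records(4, rng), rng.normal(size=4), "similarity_bin")
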