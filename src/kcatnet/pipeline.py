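"""End-to-end orchestration: split → vocabularies → featurize → train → evaluate.

`fit_pipeline` is the one place the whole training pipeline is wired
together; the statsmodels-style API, the CLI and multi-round evaluation all
delegate here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .features import FeaturizedRecord, build_vocabularies, featurize_records
from .network import KcatNetwork, ModelConfig
from .records import DatasetSplit, KcatRecord, split_dataset
from .structure import ProteinStructure
from .training import MetricsReport, TrainConfig, compute_metrics, train

__all__ = ["PipelineResult", "fit_pipeline"]


@dataclass
class PipelineResult:
    """Everything produced by one split→train→evaluate run."""

    network: KcatNetwork
    split: DatasetSplit
    history: dict
    featurized: dict[str, list[FeaturizedRecord]]
    records_by_partition: dict[str, list[KcatRecord]]
    test_predictions: np.ndarray
    test_metrics: MetricsReport


def fit_pipeline(
    records: Sequence[KcatRecord],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    structures: Mapping[str, ProteinStructure] | None = None,
    base_dir: str | Path | None = None,
    split: DatasetSplit | None = None,
    split_seed: int | None = None,
    ratios: tuple[float, float, float] = (0.8, 0.1, 0.1),
) -> PipelineResult:
    """Train and evaluate the predictor on a record set.

    Vocabularies are built from the training partition only, so test-set
    n-grams or atom environments unseen in training map to UNK — the same
    regime a deployed model faces.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    if split is None:
        split = split_dataset(
            records,
            ratios=ratios,
            seed=train_config.seed if split_seed is None else split_seed,
        )

    by_id = {r.record_id: r for r in records}
    partitions = {
        "train": [by_id[i] for i in split.train],
        "validation": [by_id[i] for i in split.validation],
        "test": [by_id[i] for i in split.test],
    }

    seq_vocab, env_vocab = build_vocabularies(partitions["train"], model_config)
    network = KcatNetwork(model_config, seq_vocab, env_vocab)

    featurized = {
        name: featurize_records(
            recs, seq_vocab, env_vocab, model_config,
            structures=structures, base_dir=base_dir,
        )
        for name, recs in partitions.items()
    }

    history = train(
        network, featurized["train"], featurized["validation"], train_config
    )
    test_predictions = network.predict(featurized["test"])
    test_metrics = compute_metrics(
        [f.target for f in featurized["test"]], test_predictions
    )
    return PipelineResult(
        network=network,
        split=split,
        history=history,
        featurized=featurized,
        records_by_partition=partitions,
        test_predictions=test_predictions,
        test_metrics=test_metrics,
    )
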