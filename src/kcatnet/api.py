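"""Model/Results front end.

`KcatModel` is built from data (records plus structures, a DataFrame, or a
dataset table on disk) and a configuration; its :meth:`KcatModel.fit`
returns a :class:`KcatResults` carrying the trained network, loss history,
held-out metrics, predictions and diagnostics, with ``summary()`` giving a
compact text report. Interpretation (per-residue weight scores) and
prediction on new records hang off the results object.
"""

from __future__ import annotations

import io
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import featurize_records
from .interpret import ResidueWeights, residue_weight_scores
from .network import ModelConfig
from .pipeline import PipelineResult, fit_pipeline
from .records import DatasetSplit, KcatRecord, read_dataset
from .structure import ProteinStructure
from .training import MetricsReport, TrainConfig, grouped_metrics

__all__ = ["KcatModel", "KcatResults"]


class KcatModel:
    """A kcat regression model bound to a dataset.

    Parameters
    ----------
    records : sequence of KcatRecord
        The enzyme–substrate–kcat data.
    structures : mapping, optional
        record_id → :class:`ProteinStructure` for records without a
        ``structure_path``.
    config : ModelConfig, optional
        Architecture settings; defaults to the small standard configuration.
    base_dir : path, optional
        Directory against which relative ``structure_path``s resolve.
    """

    def __init__(
        self,
        records: Sequence[KcatRecord],
        structures: Mapping[str, ProteinStructure] | None = None,
        config: ModelConfig | None = None,
        base_dir: str | Path | None = None,
    ):
        self.records = list(records)
        self.structures = structures
        self.config = config or ModelConfig()
        self.base_dir = Path(base_dir) if base_dir is not None else None

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        structures: Mapping[str, ProteinStructure] | None = None,
        config: ModelConfig | None = None,
        base_dir: str | Path | None = None,
    ) -> "KcatModel":
        """Build from a DataFrame in the dataset-table dialect."""
        records = []
        for i, row in frame.iterrows():
            data = row.to_dict()
            records.append(
                KcatRecord(
                    record_id=str(data.get("record_id", f"r{i:05d}")),
                    sequence=str(data["sequence"]).upper(),
                    smiles=str(data["smiles"]),
                    kcat=float(data["kcat"]),
                    structure_path=data.get("structure_path") or None,
                    enzyme_type=data.get("enzyme_type") or "unknown",
                    ec_class=data.get("ec_class") or None,
                    organism=data.get("organism") or None,
                )
            )
        return cls(records, structures=structures, config=config, base_dir=base_dir)

    @classmethod
    def from_table(
        cls,
        path: str | Path,
        config: ModelConfig | None = None,
        structures: Mapping[str, ProteinStructure] | None = None,
    ) -> "KcatModel":
        """Build from a TSV/CSV dataset file; relative structure paths
        resolve against the file's directory."""
        records, _report = read_dataset(path)
        return cls(
            records,
            structures=structures,
            config=config,
            base_dir=Path(path).parent,
        )

    def fit(
        self,
        train_config: TrainConfig | None = None,
        split: DatasetSplit | None = None,
    ) -> "KcatResults":
        """Split, train and evaluate; returns the results object."""
        result = fit_pipeline(
            self.records,
            model_config=self.config,
            train_config=train_config,
            structures=self.structures,
            base_dir=self.base_dir,
            split=split,
        )
        return KcatResults(self, result, train_config or TrainConfig())


class KcatResults:
    """Fitted-model results: estimates, diagnostics, interpretation."""

    def __init__(self, model: KcatModel, result: PipelineResult, train_config: TrainConfig):
        self.model = model
        self.network = result.network
        self.split = result.split
        self.history = result.history
        self.train_config = train_config
        self.metrics: MetricsReport = result.test_metrics
        self._result = result
        self._feat_by_id = {
            f.record_id: f
            for feats in result.featurized.values()
            for f in feats
        }

    @property
    def test_predictions(self) -> pd.DataFrame:
        feats = self._result.featurized["test"]
        preds = self._result.test_predictions
        return pd.DataFrame(
            {
                "record_id": [f.record_id for f in feats],
                "log_kcat": [f.target for f in feats],
                "log_kcat_pred": preds,
                "kcat_pred": 10.0**preds,
            }
        )

    def predict(
        self,
        records: Sequence[KcatRecord] | None = None,
        structures: Mapping[str, ProteinStructure] | None = None,
        base_dir: str | Path | None = None,
    ) -> pd.DataFrame:
        """Predict kcat for new records (defaults to the test partition)."""
        if records is None:
            return self.test_predictions[["record_id", "log_kcat_pred", "kcat_pred"]]
        feats = featurize_records(
            records,
            self.network.seq_vocab,
            self.network.env_vocab,
            self.network.config,
            structures=structures if structures is not None else self.model.structures,
            base_dir=base_dir if base_dir is not None else self.model.base_dir,
        )
        preds = self.network.predict(feats)
        return pd.DataFrame(
            {
                "record_id": [f.record_id for f in feats],
                "log_kcat_pred": preds,
                "kcat_pred": 10.0**preds,
            }
        )

    def grouped(self, group_by: str) -> list[MetricsReport]:
        """Test metrics per group: enzyme_type, ec_class or similarity_bin."""
        return grouped_metrics(
            self._result.records_by_partition["test"],
            self._result.test_predictions,
            group_by,
            train_records=self._result.records_by_partition["train"],
        )

    def residue_weights(self, record_id: str) -> ResidueWeights:
        """Structure-stream weight scores for one featurized record."""
        feat = self._feat_by_id.get(record_id)
        if feat is None:
            raise KeyError(f"record {record_id!r} was not part of the fitted dataset")
        return residue_weight_scores(self.network, feat)

    def summary(self) -> str:
        """Compact text report of the fit."""
        cfg = self.network.config
        n = {name: len(v) for name, v in self._result.featurized.items()}
        epochs_run = len(self.history["train_loss"])
        lines = [
            "kcat regression results",
            "=" * 56,
            f"mode:            {cfg.mode}",
            f"d_model/heads:   {cfg.d_model}/{cfg.n_heads}",
            f"layers (tf/gcn): {cfg.n_transformer_layers}/"
            f"{cfg.n_gcn_layers_protein}+{cfg.n_gcn_layers_substrate}",
            f"n-gram / radius: {cfg.ngram_n} / {cfg.env_radius}",
            f"contact cutoff:  {cfg.contact_threshold:g} Å",
            f"records:         train={n['train']} val={n['validation']} test={n['test']}",
            f"epochs run:      {epochs_run} (of {self.train_config.epochs})",
            f"final train MSE: {self.history['train_loss'][-1]:.4f}",
            "-" * 56,
            f"test R²:         {self.metrics.r2:.4f}" if self.metrics.r2 is not None else "test R²:         undefined",
            f"test RMSE:       {self.metrics.rmse:.4f}  (log10 s⁻¹)",
            f"test PCC:        {self.metrics.pcc:.4f}" if self.metrics.pcc is not None else "test PCC:        undefined",
            "=" * 56,
        ]
        return "\n".join(lines)
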