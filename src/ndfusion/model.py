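"""Model / results interface for the full prediction protocol.

``NeuroDeteriorationModel`` holds a cohort (volumes, clinical records,
labels) plus the architecture and training configuration; ``fit()`` runs the
held-out-test + 5-fold cross-validation protocol and returns a
``NeuroDeteriorationResults`` with per-fold and aggregate metrics and a
``summary()`` table, in the spirit of statsmodels' model/results split.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np
import pandas as pd

from .network import ModelConfig
from .pipeline import TrainConfig, run_experiment
from .synthetic import ClinicalRecord, CohortConfig, generate_cohort

__all__ = ["NeuroDeteriorationModel", "NeuroDeteriorationResults"]


class NeuroDeteriorationModel:
    """Neurological-deterioration classifier over a multimodal cohort."""

    def __init__(self, records: list[ClinicalRecord],
                 volumes: np.ndarray | None,
                 labels: np.ndarray,
                 model_config: ModelConfig | None = None):
        if len(records) != len(labels):
            raise ValueError("records and labels differ in length")
        if volumes is not None and len(volumes) != len(labels):
            raise ValueError("volumes and labels differ in length")
        self.records = records
        self.volumes = volumes
        self.labels = np.asarray(labels).astype(int)
        self.model_config = model_config or ModelConfig()

    @classmethod
    def from_synthetic(cls, cohort_config: CohortConfig | None = None,
                       model_config: ModelConfig | None = None
                       ) -> "NeuroDeteriorationModel":
        """Build the model on a freshly generated synthetic cohort."""
        cc = cohort_config or CohortConfig()
        mc = model_config or ModelConfig()
        need_vols = mc.modality != "tabular"
        records, volumes, labels = generate_cohort(cc, include_volumes=need_vols)
        return cls(records, volumes, labels, mc)

    def fit(self, train_config: TrainConfig | None = None
            ) -> "NeuroDeteriorationResults":
        """Run the full split/train/select/evaluate protocol."""
        result = run_experiment(
            model_config=self.model_config,
            train_config=train_config or TrainConfig(),
            data=(self.records, self.volumes, self.labels),
        )
        return NeuroDeteriorationResults(self, result)


class NeuroDeteriorationResults:
    """Aggregated cross-validated evaluation of a fitted model."""

    def __init__(self, model: NeuroDeteriorationModel, result: dict):
        self.model = model
        self.result = result
        self.aggregate = result["aggregate"]
        self.per_fold = result["per_fold"]

    @property
    def metrics_frame(self) -> pd.DataFrame:
        rows = {k: (v["mean"], v["sd"]) for k, v in self.aggregate.items()}
        return pd.DataFrame(rows, index=["mean", "sd"]).T

    def summary(self) -> str:
        df = self.metrics_frame
        lines = [
            "Neurological deterioration prediction - cross-validated test metrics",
            "=" * 68,
            f"cohort size: {len(self.model.labels)}   "
            f"positives: {int(self.model.labels.sum())}   "
            f"parameters: {self.result['n_parameters']}",
            f"splits (test/val/train): {self.result['split_sizes']['test']}/"
            f"{self.result['split_sizes']['val']}/{self.result['split_sizes']['train']}",
            "-" * 68,
            f"{'metric':<12}{'mean':>10}{'sd':>10}",
        ]
        for name, row in df.iterrows():
            lines.append(f"{name:<12}{row['mean']:>10.4f}{row['sd']:>10.4f}")
        lines.append("=" * 68)
        return "\n".join(lines)

    def to_json(self, path) -> None:
        def _default(o):
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            if isinstance(o, np.ndarray):
                return o.tolist()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(f"not JSON-serializable: {type(o)}")
        with open(path, "w") as fh:
            json.dump(self.result, fh, indent=2, default=_default)
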