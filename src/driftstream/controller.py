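"""Update-strategy orchestration across the stream of update windows.

All reference artifacts (normalization parameters, binning model, reference
histogram, ELM preprocessor, recurrent classifier) are fitted once on the old
dataset and frozen.  For each window, in order: normalize with the training
parameters, score the drift D against the reference distribution, and if
D >= t run the ELM preprocessor before classifying, otherwise classify
directly.  The classifier and binning model are never refit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from . import drift as drift_mod
from .classifier import ClassifierConfig, TrainedClassifier, predict, train_classifier
from .dataset import (
    LabeledSeriesSet,
    NormalizationParams,
    fit_normalization,
    normalize,
)
from .elm import ELMModel, PreprocessorConfig, preprocess_window, train_preprocessor
from .errors import ConfigurationError, StateError
from .metrics import MICRO_OVR, MetricReport, compute_report
from .windowing import WindowSpec

__all__ = [
    "PipelineConfig",
    "TrainedPipeline",
    "WindowRecord",
    "StreamResult",
    "decide_update",
    "fit_pipeline",
    "run_pipeline",
    "run_stream",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a run needs besides the data."""

    threshold: float
    window: WindowSpec | None = None
    n_bins: int = drift_mod.DEFAULT_N_BINS
    epsilon: float = drift_mod.DEFAULT_EPSILON
    preprocessor: PreprocessorConfig = field(default_factory=PreprocessorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    elm_hidden_nums: int = 32
    averaging: str = MICRO_OVR
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.threshold > 0:
            raise ConfigurationError(f"threshold must be > 0, got {self.threshold}")


@dataclass
class TrainedPipeline:
    """Frozen artifacts produced by :func:`fit_pipeline`."""

    config: PipelineConfig
    norm_params: NormalizationParams | None = None
    binning: drift_mod.BinningModel | None = None
    old_dist: drift_mod.FeatureDistribution | None = None
    elm: ELMModel | None = None
    classifier: TrainedClassifier | None = None
    classifier_train_calls: int = 0

    def require(self) -> None:
        for name in ("norm_params", "binning", "old_dist", "elm", "classifier"):
            if getattr(self, name) is None:
                raise StateError(f"pipeline artifact {name!r} is missing; run fit first")


@dataclass(frozen=True)
class WindowRecord:
    window_index: int
    drift: drift_mod.DriftReport
    preprocessor_fired: bool
    pred_labels: np.ndarray
    probs: np.ndarray
    metrics: MetricReport

    def to_record(self) -> dict:
        rec = self.drift.to_record()
        rec["preprocessor_fired"] = bool(self.preprocessor_fired)
        rec["metrics"] = self.metrics.to_record()
        return rec


@dataclass
class StreamResult:
    """Per-window records plus stream-level totals."""

    records: list[WindowRecord]

    @property
    def n_updates(self) -> int:
        return sum(r.preprocessor_fired for r in self.records)

    def mean_metrics(self) -> dict:
        if not self.records:
            return {}
        keys = ("acc", "sen", "spe", "f1", "auc")
        return {
            k: float(np.mean([getattr(r.metrics, k) for r in self.records]))
            for k in keys
        }

    def to_dict(self) -> dict:
        return {
            "windows": [r.to_record() for r in self.records],
            "totals": {"n_updates": self.n_updates, "mean_metrics": self.mean_metrics()},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def metrics_frame(self):
        """Per-window metric table (window, acc, sen, spe, f1, auc, averaging)."""
        import pandas as pd

        return pd.DataFrame(
            [{"window": r.window_index, **r.metrics.to_record()} for r in self.records]
        )


def decide_update(D: float, t: float) -> bool:
    """True iff D >= t (boundary inclusive)."""
    return D >= t


def fit_pipeline(old_data: LabeledSeriesSet, cfg: PipelineConfig) -> TrainedPipeline:
    """Fit all reference artifacts once on the old dataset.

    Normalization parameters are fitted per feature on the old data; binning,
    the reference histogram, the ELM autoregressor, and the classifier all see
    the normalized old data.
    """
    pipeline = TrainedPipeline(config=cfg)
    pipeline.norm_params = fit_normalization(old_data)
    norm_old = normalize(old_data, pipeline.norm_params)
    pipeline.binning = drift_mod.fit_binning(norm_old, cfg.n_bins, cfg.epsilon)
    pipeline.old_dist = drift_mod.histogram(norm_old, pipeline.binning)
    pipeline.elm = train_preprocessor(
        norm_old, cfg.preprocessor, seed=cfg.seed, hidden_nums=cfg.elm_hidden_nums
    )
    pipeline.classifier = train_classifier(norm_old, cfg.classifier)
    pipeline.classifier_train_calls += 1
    return pipeline


def run_pipeline(
    pipeline: TrainedPipeline, windows: list[LabeledSeriesSet]
) -> StreamResult:
    """Score, conditionally preprocess, and classify each window in order."""
    pipeline.require()
    cfg = pipeline.config
    records: list[WindowRecord] = []
    for k, window in enumerate(windows, start=1):
        norm_win = normalize(window, pipeline.norm_params)
        new_dist = drift_mod.histogram(norm_win, pipeline.binning)
        report = drift_mod.compute_D(
            pipeline.old_dist, new_dist, threshold=cfg.threshold, window_index=k
        )
        fired = report.update
        to_classify = (
            preprocess_window(pipeline.elm, norm_win, cfg.preprocessor)
            if fired
            else norm_win
        )
        pred_labels, probs = predict(pipeline.classifier, to_classify)
        metrics = compute_report(
            window.labels, pred_labels, probs, window.n_classes, cfg.averaging
        )
        logger.info(
            "window %d: D=%.4f t=%.4f update=%s acc=%.4f",
            k, report.D, cfg.threshold, fired, metrics.acc,
        )
        records.append(
            WindowRecord(
                window_index=k,
                drift=report,
                preprocessor_fired=fired,
                pred_labels=pred_labels,
                probs=probs,
                metrics=metrics,
            )
        )
    return StreamResult(records=records)


def run_stream(
    old_data: LabeledSeriesSet, windows: list[LabeledSeriesSet], cfg: PipelineConfig
) -> tuple[TrainedPipeline, StreamResult]:
    """Convenience: fit on the old data, then run the window stream."""
    pipeline = fit_pipeline(old_data, cfg)
    return pipeline, run_pipeline(pipeline, windows)
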