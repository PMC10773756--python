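"""Saving and loading fitted pipeline artifacts, and config-file parsing.

A fitted pipeline is stored in a directory as:

* ``artifacts.npz`` — normalization parameters, binning model, reference
  histogram, ELM weights, and classifier parameters (flattened keys);
* ``pipeline.json`` — config, class names, seed and training history sidecar.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict

import numpy as np

from . import drift as drift_mod
from .classifier import ClassifierConfig, TrainedClassifier
from .controller import PipelineConfig, TrainedPipeline
from .dataset import NormalizationParams, NormalizationScope
from .elm import ELMModel, PreprocessorConfig
from .errors import ConfigurationError
from .windowing import WindowSpec

__all__ = ["save_pipeline", "load_pipeline", "config_from_dict", "config_to_dict"]


def config_from_dict(doc: dict) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a parsed YAML/JSON document."""
    if "threshold" not in doc:
        raise ConfigurationError("config must set 'threshold'")
    window = None
    if doc.get("window"):
        window = WindowSpec(**doc["window"])
    binning = doc.get("binning", {})
    return PipelineConfig(
        threshold=float(doc["threshold"]),
        window=window,
        n_bins=int(binning.get("n_bins", drift_mod.DEFAULT_N_BINS)),
        epsilon=float(binning.get("epsilon", drift_mod.DEFAULT_EPSILON)),
        preprocessor=PreprocessorConfig(**doc.get("preprocessor", {})),
        classifier=ClassifierConfig(**doc.get("classifier", {})),
        elm_hidden_nums=int(doc.get("elm_hidden_nums", 32)),
        averaging=doc.get("averaging", "micro_ovr"),
        seed=int(doc.get("seed", 0)),
    )


def config_to_dict(cfg: PipelineConfig) -> dict:
    doc = {
        "threshold": cfg.threshold,
        "window": asdict(cfg.window) if cfg.window else None,
        "binning": {"n_bins": cfg.n_bins, "epsilon": cfg.epsilon},
        "preprocessor": asdict(cfg.preprocessor),
        "classifier": asdict(cfg.classifier),
        "elm_hidden_nums": cfg.elm_hidden_nums,
        "averaging": cfg.averaging,
        "seed": cfg.seed,
    }
    if doc["window"] is not None:
        doc["window"]["mode"] = doc["window"]["mode"].value
    doc["preprocessor"]["policy"] = doc["preprocessor"]["policy"].value
    return doc


def save_pipeline(pipeline: TrainedPipeline, outdir: str) -> None:
    pipeline.require()
    os.makedirs(outdir, exist_ok=True)
    arrays: dict[str, np.ndarray] = {
        "norm.x_min": pipeline.norm_params.x_min,
        "norm.x_max": pipeline.norm_params.x_max,
        "bin.mins": pipeline.binning.mins,
        "bin.maxs": pipeline.binning.maxs,
        "bin.degenerate": pipeline.binning.degenerate,
        "old_dist.probs": pipeline.old_dist.probs,
        "elm.W": pipeline.elm.W,
        "elm.b": pipeline.elm.b,
        "elm.beta": pipeline.elm.beta,
    }
    for layer in ("lstm1", "lstm2"):
        for name in ("Wx", "Wh", "b"):
            arrays[f"clf.{layer}.{name}"] = pipeline.classifier.params[layer][name]
    arrays["clf.W_out"] = pipeline.classifier.params["W_out"]
    arrays["clf.b_out"] = pipeline.classifier.params["b_out"]
    np.savez(os.path.join(outdir, "artifacts.npz"), **arrays)
    sidecar = {
        "config": config_to_dict(pipeline.config),
        "norm_scope": pipeline.norm_params.scope.value,
        "bin_n_bins": pipeline.binning.n_bins,
        "bin_epsilon": pipeline.binning.epsilon,
        "old_dist_sample_count": pipeline.old_dist.sample_count,
        "elm_dims": [
            pipeline.elm.input_nums,
            pipeline.elm.hidden_nums,
            pipeline.elm.output_nums,
        ],
        "elm_seed": pipeline.elm.seed,
        "elm_train_resid_median": pipeline.elm.train_resid_median,
        "elm_train_value_range": [
            pipeline.elm.train_value_min,
            pipeline.elm.train_value_max,
        ],
        "class_names": list(pipeline.classifier.class_names),
        "series_length": pipeline.classifier.series_length,
        "history": pipeline.classifier.history,
        "classifier_train_calls": pipeline.classifier_train_calls,
    }
    with open(os.path.join(outdir, "pipeline.json"), "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)


def load_pipeline(outdir: str) -> TrainedPipeline:
    with open(os.path.join(outdir, "pipeline.json")) as fh:
        sidecar = json.load(fh)
    cfg = config_from_dict(sidecar["config"])
    with np.load(os.path.join(outdir, "artifacts.npz")) as arrs:
        norm_params = NormalizationParams(
            scope=NormalizationScope(sidecar["norm_scope"]),
            x_min=arrs["norm.x_min"],
            x_max=arrs["norm.x_max"],
        )
        binning = drift_mod.BinningModel(
            mins=arrs["bin.mins"],
            maxs=arrs["bin.maxs"],
            n_bins=sidecar["bin_n_bins"],
            epsilon=sidecar["bin_epsilon"],
            degenerate=arrs["bin.degenerate"],
        )
        old_dist = drift_mod.FeatureDistribution(
            probs=arrs["old_dist.probs"],
            sample_count=sidecar["old_dist_sample_count"],
        )
        dims = sidecar["elm_dims"]
        elm = ELMModel(
            W=arrs["elm.W"],
            b=arrs["elm.b"],
            beta=arrs["elm.beta"],
            input_nums=dims[0],
            hidden_nums=dims[1],
            output_nums=dims[2],
            seed=sidecar["elm_seed"],
            train_resid_median=sidecar["elm_train_resid_median"],
            train_value_min=sidecar["elm_train_value_range"][0],
            train_value_max=sidecar["elm_train_value_range"][1],
        )
        params = {
            layer: {name: arrs[f"clf.{layer}.{name}"] for name in ("Wx", "Wh", "b")}
            for layer in ("lstm1", "lstm2")
        }
        params["W_out"] = arrs["clf.W_out"]
        params["b_out"] = arrs["clf.b_out"]
    classifier = TrainedClassifier(
        params=params,
        class_names=tuple(sidecar["class_names"]),
        config=cfg.classifier,
        series_length=sidecar["series_length"],
        history=sidecar["history"],
    )
    return TrainedPipeline(
        config=cfg,
        norm_params=norm_params,
        binning=binning,
        old_dist=old_dist,
        elm=elm,
        classifier=classifier,
        classifier_train_calls=sidecar["classifier_train_calls"],
    )
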