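"""Synthetic class-structured periodic streams with controllable drift.

Class archetypes are sinusoids (class k has k+1 cycles per series by default)
with per-sample amplitude and phase jitter plus Gaussian base noise.  Update
windows are drawn from the same process and then corrupted by per-window
drift operations: additive offset, amplitude scaling, extra Gaussian noise,
anomalous spikes, and missing points (dropped then linearly interpolated so
downstream modules always see complete series).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dataset import LabeledSeriesSet
from .errors import ConfigurationError

__all__ = [
    "WindowDrift",
    "DriftScenario",
    "generate_scenario",
    "sweep_drift",
    "default_acceptance_scenario",
]


@dataclass(frozen=True)
class WindowDrift:
    """Corruptions applied to one update window; all default to no-ops."""

    offset: float = 0.0
    scale: float = 1.0
    extra_noise_sd: float = 0.0
    spike_rate: float = 0.0
    spike_amplitude: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("spike_rate", "missing_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.extra_noise_sd < 0:
            raise ConfigurationError("extra_noise_sd must be >= 0")

    @property
    def is_drifted(self) -> bool:
        return (
            self.offset != 0.0
            or self.scale != 1.0
            or self.extra_noise_sd > 0
            or self.spike_rate > 0
            or self.missing_rate > 0
        )


@dataclass(frozen=True)
class DriftScenario:
    """Full generator configuration.

    ``archetype_frequencies`` defaults to (1, 2, ..., K) cycles per series;
    frequencies must be pairwise distinct by at least ``min_frequency_gap``.
    """

    n_classes: int = 3
    series_length: int = 64
    train_size: int = 300
    window_size: int = 150
    windows: tuple[WindowDrift, ...] = ()
    amplitude: float = 1.0
    base_noise_sd: float = 0.1
    amplitude_jitter: float = 0.1
    phase_jitter: float = 0.3
    archetype_frequencies: tuple[float, ...] | None = None
    min_frequency_gap: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError("need at least 2 classes")
        if self.window_size < self.n_classes:
            raise ConfigurationError(
                "window_size must be >= n_classes so every class can appear"
            )
        freqs = self.archetype_frequencies
        if freqs is None:
            freqs = tuple(float(k + 1) for k in range(self.n_classes))
        if len(freqs) != self.n_classes:
            raise ConfigurationError("one archetype frequency per class required")
        diffs = np.abs(np.subtract.outer(freqs, freqs))
        if np.any(diffs[np.triu_indices(self.n_classes, 1)] < self.min_frequency_gap):
            raise ConfigurationError(
                f"archetype frequencies closer than min gap {self.min_frequency_gap}"
            )
        object.__setattr__(self, "archetype_frequencies", tuple(freqs))
        object.__setattr__(
            self, "windows", tuple(self.windows) if self.windows else ()
        )


def _draw_clean(
    scenario: DriftScenario, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    labels = rng.integers(0, scenario.n_classes, size=n)
    t = np.arange(scenario.series_length) / scenario.series_length
    freqs = np.array(scenario.archetype_frequencies)[labels]
    amp = scenario.amplitude * (
        1.0 + scenario.amplitude_jitter * rng.standard_normal(n)
    )
    phase = scenario.phase_jitter * rng.standard_normal(n)
    values = amp[:, None] * np.sin(2 * np.pi * (freqs[:, None] * t + phase[:, None]))
    values += scenario.base_noise_sd * rng.standard_normal(values.shape)
    return values, labels


def _apply_drift(
    values: np.ndarray, drift: WindowDrift, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Return corrupted values and the missing-point mask."""
    out = drift.scale * values + drift.offset
    if drift.extra_noise_sd > 0:
        out = out + drift.extra_noise_sd * rng.standard_normal(out.shape)
    if drift.spike_rate > 0:
        spikes = rng.random(out.shape) < drift.spike_rate
        signs = rng.choice([-1.0, 1.0], size=out.shape)
        out = out + spikes * signs * drift.spike_amplitude
    missing = np.zeros(out.shape, dtype=bool)
    if drift.missing_rate > 0:
        missing[:, 1:-1] = rng.random((out.shape[0], out.shape[1] - 2)) < drift.missing_rate
        idx = np.arange(out.shape[1])
        for i in np.nonzero(missing.any(axis=1))[0]:
            keep = ~missing[i]
            out[i, missing[i]] = np.interp(idx[missing[i]], idx[keep], out[i, keep])
    return out, missing


def generate_scenario(
    scenario: DriftScenario,
) -> tuple[LabeledSeriesSet, list[LabeledSeriesSet], list[dict]]:
    """Draw the training set, the update windows, and per-window truth records.

    Truth record k holds ``{"window": k+1, "drifted": bool, "ops": WindowDrift,
    "missing_mask": bool array}``.  Deterministic given ``scenario.seed``.
    """
    rng = np.random.default_rng(scenario.seed)
    class_names = tuple(f"class_{k}" for k in range(scenario.n_classes))
    train_values, train_labels = _draw_clean(scenario, scenario.train_size, rng)
    train = LabeledSeriesSet(
        values=train_values,
        labels=train_labels,
        class_names=class_names,
        dataset_id=f"synthetic-{scenario.seed}/train",
    )
    windows: list[LabeledSeriesSet] = []
    truth: list[dict] = []
    for k, drift in enumerate(scenario.windows):
        values, labels = _draw_clean(scenario, scenario.window_size, rng)
        values, missing = _apply_drift(values, drift, rng)
        windows.append(
            LabeledSeriesSet(
                values=values,
                labels=labels,
                class_names=class_names,
                dataset_id=f"synthetic-{scenario.seed}/window{k + 1}",
            )
        )
        truth.append(
            {
                "window": k + 1,
                "drifted": drift.is_drifted,
                "ops": drift,
                "missing_mask": missing,
            }
        )
    return train, windows, truth


def default_acceptance_scenario(seed: int = 0) -> DriftScenario:
    """3 classes, L=64, 300 training samples, 5 windows of 150 samples;
    noise + spike drift injected on windows 2 and 4 only.

    Class frequencies sit half a cycle apart and the signal-to-noise budget is
    chosen so the corruption measurably hurts a classifier trained on the
    clean data while remaining recoverable by the regression filter.  The
    spike amplitude is five times the marginal standard deviation of the
    clean signal (~0.35 here).
    """
    drift = WindowDrift(extra_noise_sd=0.3, spike_rate=0.08, spike_amplitude=1.75)
    clean = WindowDrift()
    return DriftScenario(
        n_classes=3,
        series_length=64,
        train_size=300,
        window_size=150,
        windows=(clean, drift, clean, drift, clean),
        amplitude=0.5,
        base_noise_sd=0.05,
        archetype_frequencies=(2.0, 2.5, 3.0),
        seed=seed,
    )


def sweep_drift(
    template: DriftScenario,
    offsets: list[float],
    n_seeds: int = 10,
    evaluate=None,
) -> pd.DataFrame:
    """Median drift score (and optional pipeline metrics) over an offset grid.

    For each offset magnitude the template's windows are replaced by a single
    window with that additive offset; ``evaluate(train, window, seed)`` may
    return a dict of extra columns (e.g. pipeline vs baseline accuracy) merged
    into the row.  One output row per grid point.
    """
    if not offsets:
        raise ConfigurationError("offset grid must be non-empty")
    from . import drift as drift_mod
    from .dataset import fit_normalization, normalize

    rows = []
    for delta in offsets:
        d_values, extras = [], []
        for s in range(n_seeds):
            scen = replace(
                template,
                windows=(WindowDrift(offset=delta),),
                seed=template.seed + s,
            )
            train, windows, _ = generate_scenario(scen)
            params = fit_normalization(train)
            norm_train = normalize(train, params)
            model = drift_mod.fit_binning(norm_train)
            old_dist = drift_mod.histogram(norm_train, model)
            new_dist = drift_mod.histogram(normalize(windows[0], params), model)
            d_values.append(drift_mod.compute_D(old_dist, new_dist).D)
            if evaluate is not None:
                extras.append(evaluate(train, windows[0], scen.seed))
        row = {"offset": delta, "median_D": float(np.median(d_values))}
        if extras:
            for key in extras[0]:
                row[key] = float(np.median([e[key] for e in extras]))
        rows.append(row)
    return pd.DataFrame(rows)
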