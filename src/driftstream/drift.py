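"""Distribution-shift score between a reference dataset and update windows.

Each of the L time points is treated as one feature.  Equal-interval bins are
fitted per feature on the reference (old) dataset and frozen; old and new
windows are histogrammed on those bins, smoothed additively, and compared with
the Kullback-Leibler divergence KL(old || new) in nats.  The drift score D is
the mean per-feature KL; an update fires when D >= threshold t.

Values outside the fitted range clip into the edge bins, keeping the binning
model frozen to the reference data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import rel_entr

from .dataset import LabeledSeriesSet
from .errors import ConfigurationError, FormatError

__all__ = [
    "BinningModel",
    "FeatureDistribution",
    "DriftReport",
    "fit_binning",
    "histogram",
    "kl_divergence",
    "compute_D",
    "calibrate_threshold",
]

DEFAULT_N_BINS = 10
DEFAULT_EPSILON = 1e-6


@dataclass(frozen=True)
class BinningModel:
    """Frozen per-feature equal-width bins fitted on the reference dataset.

    ``degenerate`` flags features whose observed range collapsed to a point;
    those get a unit-width pseudo-range centered on the value.
    """

    mins: np.ndarray  # (L,)
    maxs: np.ndarray  # (L,)
    n_bins: int
    epsilon: float
    degenerate: np.ndarray  # (L,) bool

    @property
    def n_features(self) -> int:
        return self.mins.shape[0]

    @property
    def widths(self) -> np.ndarray:
        return (self.maxs - self.mins) / self.n_bins

    def edges(self, feature: int) -> np.ndarray:
        """The ``n_bins + 1`` bin edges of one feature."""
        return np.linspace(self.mins[feature], self.maxs[feature], self.n_bins + 1)


@dataclass(frozen=True)
class FeatureDistribution:
    """Per-feature binned probability vectors, shape (L, n_bins)."""

    probs: np.ndarray
    sample_count: int

    @property
    def n_features(self) -> int:
        return self.probs.shape[0]


@dataclass(frozen=True)
class DriftReport:
    """Per-feature KL values, their mean D, and the update decision."""

    per_feature_kl: np.ndarray
    D: float
    threshold: float
    update: bool
    window_index: int = 0

    def to_record(self) -> dict:
        """JSON-serializable summary (per-feature values collapsed to min/mean/max)."""
        kl = self.per_feature_kl
        return {
            "window": self.window_index,
            "D": float(self.D),
            "per_feature_kl_summary": {
                "min": float(kl.min()),
                "mean": float(kl.mean()),
                "max": float(kl.max()),
            },
            "threshold": float(self.threshold),
            "update": bool(self.update),
        }


def fit_binning(
    old_data: LabeledSeriesSet,
    n_bins: int = DEFAULT_N_BINS,
    epsilon: float = DEFAULT_EPSILON,
) -> BinningModel:
    """Fit per-feature Min/Max and equal-width bin edges on the old dataset."""
    if n_bins < 2:
        raise ConfigurationError(f"n_bins must be >= 2, got {n_bins}")
    if epsilon < 0:
        raise ConfigurationError(f"epsilon must be >= 0, got {epsilon}")
    mins = old_data.values.min(axis=0)
    maxs = old_data.values.max(axis=0)
    degenerate = maxs == mins
    # unit-width pseudo-range centered on the constant value
    mins = np.where(degenerate, mins - 0.5, mins)
    maxs = np.where(degenerate, maxs + 0.5, maxs)
    return BinningModel(
        mins=mins, maxs=maxs, n_bins=int(n_bins), epsilon=float(epsilon),
        degenerate=degenerate,
    )


def histogram(data: LabeledSeriesSet, model: BinningModel) -> FeatureDistribution:
    """Bin every feature of ``data`` on the frozen ``model`` and smooth.

    Bins are half-open [e_i, e_{i+1}) with the last bin closed; out-of-range
    values clip into the edge bins.  ``model.epsilon`` is added to every count
    before renormalization so all probabilities are strictly positive.
    """
    if data.series_length != model.n_features:
        raise FormatError(
            f"data width {data.series_length} does not match binning model "
            f"width {model.n_features}"
        )
    x = data.values
    idx = np.floor((x - model.mins) / model.widths).astype(int)
    np.clip(idx, 0, model.n_bins - 1, out=idx)
    flat = idx + np.arange(model.n_features) * model.n_bins
    counts = np.bincount(
        flat.ravel(), minlength=model.n_features * model.n_bins
    ).reshape(model.n_features, model.n_bins).astype(float)
    counts += model.epsilon
    probs = counts / counts.sum(axis=1, keepdims=True)
    return FeatureDistribution(probs=probs, sample_count=data.n_samples)


def kl_divergence(p: np.ndarray, q: np.ndarray) -> float:
    """KL(p || q) = sum p_i ln(p_i / q_i) in nats, with 0 ln(0/q) = 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {q.shape}")
    if np.any(p < 0) or np.any(q < 0):
        raise ValueError("probability vectors must be non-negative")
    if not np.isclose(p.sum(), 1.0, atol=1e-6) or not np.isclose(q.sum(), 1.0, atol=1e-6):
        raise ValueError("probability vectors must sum to 1")
    if np.any((q == 0) & (p > 0)):
        raise ValueError("q has zero mass where p is positive; smooth first")
    return float(rel_entr(p, q).sum())


def compute_D(
    old_dist: FeatureDistribution,
    new_dist: FeatureDistribution,
    threshold: float = np.inf,
    window_index: int = 0,
) -> DriftReport:
    """Mean per-feature KL(old || new) and the D >= t decision."""
    if old_dist.n_features != new_dist.n_features:
        raise FormatError(
            f"feature counts differ: {old_dist.n_features} vs {new_dist.n_features}"
        )
    p, q = old_dist.probs, new_dist.probs
    per_feature = rel_entr(p, q).sum(axis=1)
    D = float(per_feature.mean())
    return DriftReport(
        per_feature_kl=per_feature,
        D=D,
        threshold=float(threshold),
        update=bool(D >= threshold),
        window_index=window_index,
    )


def calibrate_threshold(
    old_data: LabeledSeriesSet,
    model: BinningModel,
    window_size: int,
    quantile: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> float:
    """Bootstrap a null distribution of D on the old data and return a quantile.

    Each iteration draws two independent window-sized resamples (with
    replacement) of the old rows and scores one against the other.  Using a
    resampled reference -- rather than the full old histogram -- keeps the
    sampling noise of both sides in the null, which would otherwise
    underestimate the D values that drift-free fresh windows produce.
    """
    if not (0.0 < quantile < 1.0):
        raise ConfigurationError(f"quantile must be in (0, 1), got {quantile}")
    if n_boot < 10:
        raise ConfigurationError(f"n_boot must be >= 10, got {n_boot}")
    if window_size < 1:
        raise ConfigurationError(f"window_size must be >= 1, got {window_size}")
    rng = np.random.default_rng(seed)
    S = old_data.n_samples
    null_D = np.empty(n_boot)
    for b in range(n_boot):
        ref_idx = rng.integers(0, S, size=window_size)
        new_idx = rng.integers(0, S, size=window_size)
        ref = histogram(old_data.take(ref_idx), model)
        new = histogram(old_data.take(new_idx), model)
        null_D[b] = compute_D(ref, new).D
    return float(np.quantile(null_D, quantile))
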