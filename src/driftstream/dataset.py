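"""Core dataset container, min-max normalization, shuffling and file I/O.

A :class:`LabeledSeriesSet` is an S x L matrix of fixed-length series plus a
length-S vector of integer class labels.  Two on-disk representations are
supported:

* delimited text (CSV, wide): header ``id,label,t0,...,t{L-1}``, one sample
  per row, period decimal separator;
* binary array bundle (NumPy ``.npz``) holding ``values``, ``labels``,
  ``class_names`` and ``dataset_id``.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, FormatError

__all__ = [
    "LabeledSeriesSet",
    "NormalizationScope",
    "NormalizationParams",
    "fit_normalization",
    "normalize",
    "denormalize",
    "shuffle",
    "read_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class LabeledSeriesSet:
    """Matrix of fixed-length real-valued series with integer class labels.

    Parameters
    ----------
    values : ndarray of shape (S, L)
        One series per row; must be finite (no NaN/inf) after ingestion.
    labels : ndarray of shape (S,)
        Integer class ids, each a valid index into ``class_names``.
    class_names : tuple of str
        Human-readable names, one per class id.
    dataset_id : str
        Free-form identifier carried through transformations.
    """

    values: np.ndarray
    labels: np.ndarray
    class_names: tuple[str, ...] = ()
    dataset_id: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        labels = np.asarray(self.labels)
        if values.ndim != 2:
            raise FormatError(f"values must be 2-D (S, L), got ndim={values.ndim}")
        if values.shape[0] < 1 or values.shape[1] < 1:
            raise FormatError(f"need S >= 1 and L >= 1, got shape {values.shape}")
        if labels.shape != (values.shape[0],):
            raise FormatError(
                f"labels shape {labels.shape} does not match sample count "
                f"{values.shape[0]}"
            )
        if not np.issubdtype(labels.dtype, np.integer):
            if not np.all(labels == labels.astype(int)):
                raise FormatError("labels must be integers")
            labels = labels.astype(int)
        if not np.all(np.isfinite(values)):
            bad = int(np.argwhere(~np.isfinite(values).all(axis=1))[0, 0])
            raise FormatError(f"non-finite value in sample row {bad}")
        names = tuple(self.class_names)
        if not names:
            names = tuple(f"class_{k}" for k in range(int(labels.max()) + 1))
        if labels.min() < 0 or labels.max() >= len(names):
            raise FormatError(
                f"labels must lie in [0, {len(names)}), "
                f"found range [{labels.min()}, {labels.max()}]"
            )
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "class_names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def series_length(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return len(self.class_names)

    def with_values(self, values: np.ndarray) -> "LabeledSeriesSet":
        """Return a copy with ``values`` replaced, labels/names untouched."""
        return replace(self, values=values)

    def take(self, indices: np.ndarray, dataset_id: str | None = None) -> "LabeledSeriesSet":
        """Row subset / reorder by integer ``indices``."""
        return LabeledSeriesSet(
            values=self.values[indices],
            labels=self.labels[indices],
            class_names=self.class_names,
            dataset_id=self.dataset_id if dataset_id is None else dataset_id,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledSeriesSet):
            return NotImplemented
        return (
            np.array_equal(self.values, other.values)
            and np.array_equal(self.labels, other.labels)
            and self.class_names == other.class_names
            and self.dataset_id == other.dataset_id
        )


class NormalizationScope(str, enum.Enum):
    """Where min/max statistics come from.

    ``per_feature_trainset`` fits one (min, max) per column on a reference
    (training) set and reuses them on later windows, so distribution shift in
    new windows stays visible.  ``per_sample`` rescales each row by its own
    range and carries no state.
    """

    PER_FEATURE_TRAINSET = "per_feature_trainset"
    PER_SAMPLE = "per_sample"


@dataclass(frozen=True)
class NormalizationParams:
    """Fitted min-max statistics; ``x_min``/``x_max`` are None for per-sample scope."""

    scope: NormalizationScope
    x_min: np.ndarray | None = None
    x_max: np.ndarray | None = None

    def __post_init__(self) -> None:
        scope = NormalizationScope(self.scope)
        object.__setattr__(self, "scope", scope)
        if scope is NormalizationScope.PER_FEATURE_TRAINSET:
            if self.x_min is None or self.x_max is None:
                raise ConfigurationError("per-feature scope requires x_min and x_max")
            x_min = np.asarray(self.x_min, dtype=float)
            x_max = np.asarray(self.x_max, dtype=float)
            if x_min.shape != x_max.shape:
                raise FormatError("x_min and x_max shapes differ")
            if np.any(x_max < x_min):
                raise FormatError("x_max must be >= x_min elementwise")
            object.__setattr__(self, "x_min", x_min)
            object.__setattr__(self, "x_max", x_max)


def fit_normalization(
    data: LabeledSeriesSet,
    scope: NormalizationScope | str = NormalizationScope.PER_FEATURE_TRAINSET,
) -> NormalizationParams:
    """Compute min-max statistics for ``data`` under the given scope."""
    scope = NormalizationScope(scope)
    if scope is NormalizationScope.PER_SAMPLE:
        return NormalizationParams(scope=scope)
    return NormalizationParams(
        scope=scope,
        x_min=data.values.min(axis=0),
        x_max=data.values.max(axis=0),
    )


def _minmax_transform(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    span = hi - lo
    out = np.zeros_like(x, dtype=float)
    np.divide(x - lo, span, out=out, where=span > 0)
    return out


def normalize(data: LabeledSeriesSet, params: NormalizationParams) -> LabeledSeriesSet:
    """Apply X_new = (X - X_min) / (X_max - X_min) under ``params``.

    Degenerate ranges (x_max == x_min) map to 0.0.  Values outside the fitted
    range produce outputs outside [0, 1]; they pass through unclamped so that
    drift in new windows remains measurable.
    """
    if params.scope is NormalizationScope.PER_SAMPLE:
        lo = data.values.min(axis=1, keepdims=True)
        hi = data.values.max(axis=1, keepdims=True)
        return data.with_values(_minmax_transform(data.values, lo, hi))
    if params.x_min.shape != (data.series_length,):
        raise FormatError(
            f"params fitted for length {params.x_min.shape}, "
            f"data has length {data.series_length}"
        )
    return data.with_values(_minmax_transform(data.values, params.x_min, params.x_max))


def denormalize(data: LabeledSeriesSet, params: NormalizationParams) -> LabeledSeriesSet:
    """Inverse of :func:`normalize` for the per-feature scope (lossy where degenerate)."""
    if params.scope is not NormalizationScope.PER_FEATURE_TRAINSET:
        raise ConfigurationError("denormalize requires per-feature params")
    span = params.x_max - params.x_min
    return data.with_values(data.values * span + params.x_min)


def shuffle(data: LabeledSeriesSet, seed: int) -> LabeledSeriesSet:
    """Deterministic row permutation of (series, label) pairs."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(data.n_samples)
    return data.take(perm)


# ---------------------------------------------------------------------------
# File I/O


def _read_csv(path: str, interpolate_missing: bool) -> LabeledSeriesSet:
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FormatError(f"{path}: empty file") from None
        if len(header) < 3 or header[0] != "id" or header[1] != "label":
            raise FormatError(
                f"{path}: header must start with 'id,label,t0,...', got {header[:3]}"
            )
        width = len(header) - 2
        rows: list[np.ndarray] = []
        labels: list[int] = []
        for i, rec in enumerate(reader):
            if len(rec) != len(header):
                raise FormatError(
                    f"{path}: row {i} has {len(rec)} fields, expected {len(header)}"
                )
            try:
                lab = int(rec[1])
            except ValueError:
                raise FormatError(
                    f"{path}: row {i} has non-integer label {rec[1]!r}"
                ) from None
            vals = np.array(
                [float(v) if v.strip() != "" else np.nan for v in rec[2:]], dtype=float
            )
            if np.isnan(vals).any():
                if not interpolate_missing:
                    raise FormatError(
                        f"{path}: row {i} contains missing values "
                        "(pass interpolate_missing=True to fill interior gaps)"
                    )
                vals = _interpolate_interior(vals, path=path, row=i)
            rows.append(vals)
            labels.append(lab)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return LabeledSeriesSet(
        values=np.vstack(rows),
        labels=np.array(labels, dtype=int),
        dataset_id=str(path),
    )


def _interpolate_interior(vals: np.ndarray, *, path: str, row: int) -> np.ndarray:
    mask = np.isnan(vals)
    if mask[0] or mask[-1]:
        raise FormatError(
            f"{path}: row {row} has missing values at the series boundary; "
            "only interior gaps can be interpolated"
        )
    idx = np.arange(vals.size)
    out = vals.copy()
    out[mask] = np.interp(idx[mask], idx[~mask], vals[~mask])
    return out


def read_dataset(
    path: str, format: str = "csv", *, interpolate_missing: bool = False
) -> LabeledSeriesSet:
    """Read a dataset from ``path``.

    ``format`` is ``"csv"`` (wide delimited text) or ``"npz"`` (binary array
    bundle).  Missing values in text input are rejected unless
    ``interpolate_missing`` is set, in which case interior gaps are filled
    linearly and boundary gaps remain errors.
    """
    if format == "csv":
        return _read_csv(path, interpolate_missing)
    if format == "npz":
        with np.load(path, allow_pickle=False) as bundle:
            return LabeledSeriesSet(
                values=bundle["values"],
                labels=bundle["labels"],
                class_names=tuple(str(n) for n in bundle["class_names"]),
                dataset_id=str(bundle["dataset_id"][()]),
            )
    raise FormatError(f"unknown format {format!r}; expected 'csv' or 'npz'")


def write_dataset(data: LabeledSeriesSet, path: str, format: str = "csv") -> None:
    """Write ``data`` to ``path`` in the given format (see :func:`read_dataset`)."""
    if format == "csv":
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["id", "label"] + [f"t{j}" for j in range(data.series_length)]
            )
            for i in range(data.n_samples):
                writer.writerow(
                    [i, int(data.labels[i])]
                    + [repr(float(v)) for v in data.values[i]]
                )
        return
    if format == "npz":
        np.savez(
            path,
            values=data.values,
            labels=data.labels,
            class_names=np.array(data.class_names, dtype=str),
            dataset_id=np.array(data.dataset_id, dtype=str),
        )
        return
    raise FormatError(f"unknown format {format!r}; expected 'csv' or 'npz'")
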