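"""Training-block / update-window generation.

Two update modes:

* ``feature_update`` — long periodic samples; the training block is the first
  ``size`` time points of every sample and window k is the column span
  ``[k*step, k*step + size)``.  With a cycle wavelength ``w`` and multiplier
  ``n``, ``size = w*n`` and the window count N must satisfy ``w*n*N <= L``.
* ``sample_update`` — many short samples; the training block is the first
  ``train_split`` rows and window k is the next contiguous block of ``size``
  rows advancing by ``step``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .dataset import LabeledSeriesSet
from .errors import ConfigurationError

__all__ = ["WindowMode", "WindowSpec", "make_feature_windows", "make_sample_windows", "make_windows"]


class WindowMode(str, enum.Enum):
    FEATURE_UPDATE = "feature_update"
    SAMPLE_UPDATE = "sample_update"


@dataclass(frozen=True)
class WindowSpec:
    """Configuration of the update-window stream.

    ``size`` counts time points in feature mode and samples in sample mode.
    ``cycle_wavelength`` (w) and ``multiplier`` (n) are optional; when both are
    given in feature mode they must satisfy ``size == w*n``.
    ``train_split`` (sample mode) defaults to ``S - count*size`` at generation
    time when left as None.
    """

    mode: WindowMode
    size: int
    step: int
    count: int
    cycle_wavelength: int | None = None
    multiplier: int | None = None
    train_split: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mode", WindowMode(self.mode))
        for name in ("size", "step", "count"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 1:
                raise ConfigurationError(f"{name} must be a positive integer, got {v!r}")
        if (self.cycle_wavelength is None) != (self.multiplier is None):
            raise ConfigurationError("cycle_wavelength and multiplier must be given together")
        if self.cycle_wavelength is not None:
            if self.cycle_wavelength < 1 or self.multiplier < 1:
                raise ConfigurationError("cycle_wavelength and multiplier must be >= 1")
            if self.size != self.cycle_wavelength * self.multiplier:
                raise ConfigurationError(
                    f"feature-mode size must equal w*n = "
                    f"{self.cycle_wavelength * self.multiplier}, got {self.size}"
                )
        if self.train_split is not None and self.train_split < 0:
            raise ConfigurationError("train_split must be >= 0")


def make_feature_windows(
    data: LabeledSeriesSet, spec: WindowSpec
) -> tuple[LabeledSeriesSet, list[LabeledSeriesSet]]:
    """Split columns into a training block and ``count`` update windows."""
    if spec.mode is not WindowMode.FEATURE_UPDATE:
        raise ConfigurationError(f"spec mode is {spec.mode.value}, expected feature_update")
    L = data.series_length
    if spec.cycle_wavelength is not None:
        wn = spec.cycle_wavelength * spec.multiplier
        if wn * spec.count > L:
            raise ConfigurationError(
                f"w*n*N = {wn * spec.count} exceeds series length L = {L}"
            )
    last_end = spec.count * spec.step + spec.size
    if last_end > L:
        raise ConfigurationError(
            f"window {spec.count} spans columns [{spec.count * spec.step}, {last_end}) "
            f"but series length is {L}"
        )
    train = LabeledSeriesSet(
        values=data.values[:, : spec.size],
        labels=data.labels,
        class_names=data.class_names,
        dataset_id=f"{data.dataset_id}/train[0:{spec.size})",
    )
    windows = []
    for k in range(1, spec.count + 1):
        start = k * spec.step
        windows.append(
            LabeledSeriesSet(
                values=data.values[:, start : start + spec.size],
                labels=data.labels,
                class_names=data.class_names,
                dataset_id=f"{data.dataset_id}/window{k}[{start}:{start + spec.size})",
            )
        )
    return train, windows


def make_sample_windows(
    data: LabeledSeriesSet, spec: WindowSpec
) -> tuple[LabeledSeriesSet | None, list[LabeledSeriesSet]]:
    """Split rows into a training block and ``count`` update windows.

    Returns ``(None, windows)`` when ``train_split`` is explicitly 0.
    """
    if spec.mode is not WindowMode.SAMPLE_UPDATE:
        raise ConfigurationError(f"spec mode is {spec.mode.value}, expected sample_update")
    S = data.n_samples
    train_split = spec.train_split
    if train_split is None:
        train_split = S - spec.count * spec.size
        if train_split < 1:
            raise ConfigurationError(
                f"default train_split = S - count*size = {train_split} < 1; "
                f"need at least {spec.count * spec.size + 1} samples, have {S}"
            )
    required = train_split + (spec.count - 1) * spec.step + spec.size
    if required > S:
        raise ConfigurationError(
            f"insufficient samples: windows require {required}, dataset has {S}"
        )
    # train_split = 0 means "no training block" (window-only streaming)
    train = (
        data.take(slice(0, train_split), dataset_id=f"{data.dataset_id}/train[0:{train_split})")
        if train_split > 0
        else None
    )
    windows = []
    for k in range(spec.count):
        start = train_split + k * spec.step
        windows.append(
            data.take(
                slice(start, start + spec.size),
                dataset_id=f"{data.dataset_id}/window{k + 1}[{start}:{start + spec.size})",
            )
        )
    return train, windows


def make_windows(
    data: LabeledSeriesSet, spec: WindowSpec
) -> tuple[LabeledSeriesSet, list[LabeledSeriesSet]]:
    """Dispatch on ``spec.mode``."""
    if spec.mode is WindowMode.FEATURE_UPDATE:
        return make_feature_windows(data, spec)
    return make_sample_windows(data, spec)
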