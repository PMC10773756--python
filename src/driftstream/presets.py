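"""Documented per-dataset configuration presets.

Window settings and update thresholds used in the published experiments on
five public datasets.  These are reference values for reproducing those runs
on the original data; they are NOT defaults anywhere in the package.
"""

from __future__ import annotations

from .windowing import WindowMode, WindowSpec

__all__ = ["PRESETS"]

PRESETS: dict[str, dict] = {
    # 127 samples x 588 points (2 classes): three 196-point cycle waves;
    # feature update, window = two cycles, step = one cycle, one window.
    "lirb127": {
        "threshold": 0.60,
        "window": WindowSpec(
            mode=WindowMode.FEATURE_UPDATE,
            size=392, step=196, count=1,
            cycle_wavelength=196, multiplier=2,
        ),
    },
    # 78 samples x 1764 points (3 classes): three 588-point cycle waves.
    "lirb78": {
        "threshold": 0.62,
        "window": WindowSpec(
            mode=WindowMode.FEATURE_UPDATE,
            size=1176, step=588, count=1,
            cycle_wavelength=588, multiplier=2,
        ),
    },
    # 5000 samples x 140 points (5 classes): sample update, five windows of
    # 500 trailing samples; 2500 samples remain for training.
    "ecg": {
        "threshold": 0.73,
        "window": WindowSpec(
            mode=WindowMode.SAMPLE_UPDATE, size=500, step=500, count=5
        ),
    },
    # 1305 samples x 28 features (6 classes): sample update, five windows of 20.
    "casia": {
        "threshold": 0.68,
        "window": WindowSpec(
            mode=WindowMode.SAMPLE_UPDATE, size=20, step=20, count=5
        ),
    },
    # 31200 samples x 48 points (24 classes): sample update, five windows of 1200.
    "crop": {
        "threshold": 0.76,
        "window": WindowSpec(
            mode=WindowMode.SAMPLE_UPDATE, size=1200, step=1200, count=5
        ),
    },
}
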