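"""Feature extraction, feature matrices and quantization.

A feature is the integral of the signal times a wavelet over the wavelet's
support, approximated as a Riemann sum scaled by the sample interval 1/fs
(units: signal-units * seconds).  The scale is immaterial to classification
but fixed for reproducibility.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .wavelets import Wavelet, waveform

__all__ = [
    "WindowedDataset",
    "FeatureSpec",
    "FeatureMatrix",
    "QuantizationConfig",
    "extract_feature",
    "extract_matrix",
    "quantize",
    "standardize",
]


@dataclass
class WindowedDataset:
    """Windowed multichannel time series with class labels.

    ``windows`` has shape (n_windows, n_channels, window_len) in signal
    units; ``split`` tags each window "train" or "test".
    """

    windows: np.ndarray
    labels: np.ndarray
    fs: float
    channel_names: list[str]
    class_names: list[str]
    split: np.ndarray  # array of "train"/"test" tags, one per window

    def __post_init__(self) -> None:
        self.windows = np.asarray(self.windows, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        self.split = np.asarray(self.split)
        if self.windows.ndim != 3:
            raise ValueError("windows must be (n_windows, n_channels, window_len)")
        n, c, _ = self.windows.shape
        if self.labels.shape != (n,) or self.split.shape != (n,):
            raise ValueError("labels/split length must match n_windows")
        if len(self.channel_names) != c:
            raise ValueError("channel_names length must match n_channels")
        if self.labels.min(initial=0) < 0 or (
            len(self.labels) and self.labels.max() >= len(self.class_names)
        ):
            raise ValueError("labels out of range of class_names")

    @property
    def n_windows(self) -> int:
        return self.windows.shape[0]

    @property
    def n_channels(self) -> int:
        return self.windows.shape[1]

    @property
    def window_len(self) -> int:
        return self.windows.shape[2]

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "train"

    @property
    def test_mask(self) -> np.ndarray:
        return self.split == "test"

    def save(self, path: str | Path) -> None:
        """npz payload + JSON sidecar with names and rates."""
        path = Path(path)
        np.savez(path.with_suffix(".npz"), windows=self.windows,
                 labels=self.labels, split=self.split)
        sidecar = {
            "fs": self.fs,
            "channel_names": self.channel_names,
            "class_names": self.class_names,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "WindowedDataset":
        path = Path(path)
        payload = np.load(path.with_suffix(".npz"))
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            windows=payload["windows"],
            labels=payload["labels"],
            split=payload["split"],
            fs=sidecar["fs"],
            channel_names=sidecar["channel_names"],
            class_names=sidecar["class_names"],
        )


@dataclass(frozen=True)
class FeatureSpec:
    """One candidate feature: a wavelet applied to one channel."""

    channel: int
    wavelet: Wavelet

    def describe(self) -> str:
        w = self.wavelet
        return f"ch{self.channel}:{w.family}:P{w.period}:ts{w.t_s}:dt{w.delta_t}"


@dataclass
class FeatureMatrix:
    values: np.ndarray            # (n_windows, n_features)
    specs: list[FeatureSpec]
    quantized: bool = False
    bits: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.specs):
            raise ValueError("values must be (n_windows, len(specs))")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature values must be finite")

    @property
    def n_features(self) -> int:
        return len(self.specs)

    def select(self, idx: Sequence[int]) -> "FeatureMatrix":
        idx = list(idx)
        return FeatureMatrix(self.values[:, idx], [self.specs[i] for i in idx],
                             quantized=self.quantized, bits=self.bits)

    def to_csv(self) -> str:
        df = pd.DataFrame(self.values, columns=[s.describe() for s in self.specs])
        buf = io.StringIO()
        df.to_csv(buf, index=False)
        return buf.getvalue()


@dataclass
class QuantizationConfig:
    """Uniform quantizer: 2^bits levels spanning each feature's training
    range (endpoints included); test values are clipped into range."""

    bits: int
    mins: np.ndarray | None = None
    maxs: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.bits < 1:
            raise ValueError(f"bits must be >= 1, got {self.bits}")


def extract_feature(window: np.ndarray, w: Wavelet, fs: float) -> float:
    """Riemann-sum inner product of one channel's window with a wavelet."""
    window = np.asarray(window, dtype=float)
    if window.shape != (w.window_len,):
        raise ValueError(
            f"window has {window.shape[0]} samples but wavelet expects "
            f"{w.window_len}"
        )
    return float(window @ waveform(w)) / fs


def extract_matrix(ds: WindowedDataset, specs: Sequence[FeatureSpec]) -> FeatureMatrix:
    """Vectorized extraction: one column per spec, one row per window."""
    specs = list(specs)
    for s in specs:
        if not (0 <= s.channel < ds.n_channels):
            raise ValueError(f"unknown channel {s.channel}")
        if s.wavelet.window_len != ds.window_len:
            raise ValueError(
                f"wavelet window {s.wavelet.window_len} != dataset window "
                f"{ds.window_len}"
            )
    values = np.empty((ds.n_windows, len(specs)))
    # group by channel so each channel's windows hit one matmul
    by_channel: dict[int, list[int]] = {}
    for j, s in enumerate(specs):
        by_channel.setdefault(s.channel, []).append(j)
    for ch, cols in by_channel.items():
        basis = np.stack([waveform(specs[j].wavelet) for j in cols])  # (k, L)
        values[:, cols] = ds.windows[:, ch, :] @ basis.T / ds.fs
    return FeatureMatrix(values, specs)


def quantize(fm: FeatureMatrix, cfg: QuantizationConfig,
             train_mask: np.ndarray) -> FeatureMatrix:
    """Quantize each feature to the nearest of 2^bits uniform levels learned
    on the training rows; out-of-range values are clipped."""
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.sum() < 1:
        raise ValueError("train_mask must select at least one row")
    train = fm.values[train_mask]
    mins = train.min(axis=0)
    maxs = train.max(axis=0)
    n_levels = 2 ** cfg.bits
    span = maxs - mins
    out = np.empty_like(fm.values)
    for j in range(fm.n_features):
        if span[j] == 0:
            out[:, j] = mins[j]
            continue
        step = span[j] / (n_levels - 1) if n_levels > 1 else span[j]
        clipped = np.clip(fm.values[:, j], mins[j], maxs[j])
        out[:, j] = mins[j] + np.round((clipped - mins[j]) / step) * step
    qcfg = replace(cfg, mins=mins, maxs=maxs)
    result = FeatureMatrix(out, fm.specs, quantized=True, bits=cfg.bits)
    result._quant_config = qcfg  # type: ignore[attr-defined]
    return result


def standardize(fm: FeatureMatrix, train_mask: np.ndarray
                ) -> tuple[FeatureMatrix, np.ndarray, np.ndarray]:
    """Z-score each feature with training-split statistics.

    Returns the standardized matrix and the (mean, sd) used.  Zero-variance
    features map to 0.
    """
    train_mask = np.asarray(train_mask, dtype=bool)
    mu = fm.values[train_mask].mean(axis=0)
    sd = fm.values[train_mask].std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    z = (fm.values - mu) / sd_safe
    return (FeatureMatrix(z, fm.specs, quantized=fm.quantized, bits=fm.bits),
            mu, sd)
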