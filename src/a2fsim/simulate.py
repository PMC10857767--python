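"""Synthetic windowed datasets with the statistical structure the converter
targets, so the whole chain is testable without downloading the real
recordings.

ECG-like windows are heartbeat-aligned (R-peak at sample 100 of a 256-sample
window at 360 Hz) with an ~85/15 normal/abnormal prior; abnormal beats have a
widened, lower QRS complex, a missing P wave and a shifted secondary peak —
a stereotyped stand-in for ventricular ectopy, not physiology.

Inertial-like windows are 6-channel, 128 samples at 50 Hz, six balanced
classes: three static (distinct per-channel mean vectors, near-zero
oscillation — only a direct-integration/constant feature can tell them
apart) and three dynamic (distinct oscillation frequency and amplitude
patterns chosen on the Haar frequency grid fs/2^k, with small phase jitter).

A fixed-width-text reader for the UCI smartphone activity dataset is
included as an optional extra; no test needs it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .features import WindowedDataset

__all__ = [
    "EcgSimConfig",
    "InertialSimConfig",
    "gen_ecg",
    "gen_inertial",
    "load_ucihar",
]


def _gauss(t: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((t - center) / width) ** 2)


def _stratified_split(labels: np.ndarray, train_frac: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-class 70/30-style split; returns a "train"/"test" tag array."""
    split = np.empty(labels.size, dtype=object)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        idx = rng.permutation(idx)
        n_train = int(round(train_frac * idx.size))
        split[idx[:n_train]] = "train"
        split[idx[n_train:]] = "test"
    return split.astype(str)


# ---------------------------------------------------------------------------
# ECG


@dataclass
class EcgSimConfig:
    n_windows: int = 400
    abnormal_fraction: float = 0.15
    window_len: int = 256
    fs: float = 360.0
    r_peak_index: int = 100
    qrs_amp_normal: float = 1.0
    qrs_width_normal: float = 4.0
    qrs_amp_abnormal: float = 0.65
    qrs_width_abnormal: float = 12.0
    secondary_peak_shift: int = 85   # abnormal extra peak, samples after R
    amp_jitter_sd: float = 0.05
    noise_sd: float = 0.05
    train_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must be in [0, 1]")
        if not 0 <= self.r_peak_index < self.window_len:
            raise ValueError("r_peak_index must lie inside the window")


def _ecg_window(cfg: EcgSimConfig, abnormal: bool,
                rng: np.random.Generator) -> np.ndarray:
    t = np.arange(cfg.window_len, dtype=float)
    r = cfg.r_peak_index
    scale = 1.0 + cfg.amp_jitter_sd * rng.standard_normal()
    x = np.zeros(cfg.window_len)
    if not abnormal:
        x += 0.15 * _gauss(t, r - 45, 8.0)                    # P wave
        x += cfg.qrs_amp_normal * _gauss(t, r, cfg.qrs_width_normal)
        x -= 0.15 * _gauss(t, r - 7, 3.0)                     # Q
        x -= 0.20 * _gauss(t, r + 8, 3.0)                     # S
        x += 0.30 * _gauss(t, r + 60, 14.0)                   # T wave
    else:
        x += cfg.qrs_amp_abnormal * _gauss(t, r, cfg.qrs_width_abnormal)
        x -= 0.25 * _gauss(t, r + 20, 8.0)
        x += 0.35 * _gauss(t, r + cfg.secondary_peak_shift, 18.0)
    x *= scale
    x += cfg.noise_sd * rng.standard_normal(cfg.window_len)
    return x


def gen_ecg(cfg: EcgSimConfig) -> WindowedDataset:
    """Heartbeat-aligned one-channel windows, stratified 70/30 split."""
    if cfg.n_windows < 10:
        raise ValueError(
            f"n_windows must be >= 10 for a meaningful split, got {cfg.n_windows}"
        )
    rng = np.random.default_rng(cfg.seed)
    n_abn = int(round(cfg.abnormal_fraction * cfg.n_windows))
    labels = np.zeros(cfg.n_windows, dtype=int)
    labels[rng.choice(cfg.n_windows, size=n_abn, replace=False)] = 1
    windows = np.empty((cfg.n_windows, 1, cfg.window_len))
    for i in range(cfg.n_windows):
        windows[i, 0] = _ecg_window(cfg, bool(labels[i]), rng)
    split = _stratified_split(labels, cfg.train_frac, rng)
    return WindowedDataset(windows, labels, cfg.fs, ["ecg"],
                           ["normal", "abnormal"], split)


# ---------------------------------------------------------------------------
# inertial


@dataclass
class DynamicClassSpec:
    fundamental_hz: float
    channel_amps: list[float]     # oscillation amplitude per channel
    harmonic_amp: float = 0.2     # relative 2nd-harmonic admixture


def _default_static_means() -> list[list[float]]:
    # sitting, standing, laying: distinct gravity projections, gyro at rest
    return [
        [0.3, 0.9, 0.2, 0.0, 0.0, 0.0],
        [0.0, 1.0, 0.4, 0.0, 0.0, 0.0],
        [0.9, 0.1, -0.3, 0.0, 0.0, 0.0],
    ]


def _default_dynamics() -> list[DynamicClassSpec]:
    # walking, upstairs, downstairs: fundamentals on the Haar grid 50/2^k
    return [
        DynamicClassSpec(1.5625, [1.0, 0.6, 0.0, 0.0, 0.0, 0.5]),
        DynamicClassSpec(3.125, [0.8, 1.0, 0.2, 0.0, 0.0, 0.3]),
        DynamicClassSpec(6.25, [1.2, 0.3, 0.5, 0.0, 0.0, 0.8]),
    ]


@dataclass
class InertialSimConfig:
    n_windows: int = 360
    window_len: int = 128
    fs: float = 50.0
    static_means: list[list[float]] = field(default_factory=_default_static_means)
    dynamics: list[DynamicClassSpec] = field(default_factory=_default_dynamics)
    phase_jitter_sd: float = 0.2  # radians
    noise_sd: float = 0.05
    train_frac: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        means = [tuple(m) for m in self.static_means]
        if len(set(means)) != len(means):
            raise ValueError("static class mean vectors must be pairwise distinct")
        for d in self.dynamics:
            if not 0.0 < d.fundamental_hz < self.fs / 2:
                raise ValueError(
                    f"dynamic fundamental {d.fundamental_hz} Hz outside (0, fs/2)"
                )


_INERTIAL_CHANNELS = ["accx", "accy", "accz", "gyrx", "gyry", "gyrz"]
_INERTIAL_CLASSES = ["walking", "upstairs", "downstairs",
                     "sitting", "standing", "laying"]


def gen_inertial(cfg: InertialSimConfig) -> WindowedDataset:
    """Six balanced classes: dynamics first (labels 0-2), statics 3-5."""
    rng = np.random.default_rng(cfg.seed)
    n_classes = len(cfg.dynamics) + len(cfg.static_means)
    labels = np.arange(cfg.n_windows) % n_classes
    labels = rng.permutation(labels)
    t = np.arange(cfg.window_len) / cfg.fs
    windows = np.empty((cfg.n_windows, 6, cfg.window_len))
    for i, lab in enumerate(labels):
        x = cfg.noise_sd * rng.standard_normal((6, cfg.window_len))
        if lab < len(cfg.dynamics):
            d = cfg.dynamics[lab]
            phase = cfg.phase_jitter_sd * rng.standard_normal()
            carrier = np.sin(2 * np.pi * d.fundamental_hz * t + phase)
            harmonic = np.sin(4 * np.pi * d.fundamental_hz * t + 2 * phase)
            osc = carrier + d.harmonic_amp * harmonic
            x += np.outer(d.channel_amps, osc)
        else:
            means = cfg.static_means[lab - len(cfg.dynamics)]
            x += np.asarray(means)[:, None]
        windows[i] = x
    split = _stratified_split(labels, cfg.train_frac, rng)
    return WindowedDataset(windows, labels, cfg.fs, list(_INERTIAL_CHANNELS),
                           list(_INERTIAL_CLASSES), split)


# ---------------------------------------------------------------------------
# optional real-data reader (pre-windowed fixed-width text)


_UCIHAR_SIGNALS = [
    "body_acc_x", "body_acc_y", "body_acc_z",
    "body_gyro_x", "body_gyro_y", "body_gyro_z",
]


def load_ucihar(root: str | Path) -> WindowedDataset:
    """Read the pre-windowed smartphone activity dataset (fixed-width text
    under ``<root>/{train,test}/Inertial Signals``) into one container.

    The dataset ships already split and windowed (128 samples at 50 Hz, 50%
    overlap), so windows pass through unchanged.
    """
    root = Path(root)
    all_windows, all_labels, all_split = [], [], []
    for split in ("train", "test"):
        sig_dir = root / split / "Inertial Signals"
        chans = [np.loadtxt(sig_dir / f"{sig}_{split}.txt")
                 for sig in _UCIHAR_SIGNALS]
        windows = np.stack(chans, axis=1)          # (n, 6, 128)
        labels = np.loadtxt(root / split / f"y_{split}.txt", dtype=int) - 1
        all_windows.append(windows)
        all_labels.append(labels)
        all_split.append(np.full(labels.shape, split))
    return WindowedDataset(
        np.concatenate(all_windows),
        np.concatenate(all_labels),
        50.0,
        list(_INERTIAL_CHANNELS),
        _INERTIAL_CLASSES,
        np.concatenate(all_split),
    )
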