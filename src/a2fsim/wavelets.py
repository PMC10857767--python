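"""Wavelet atoms and dictionary enumeration for non-uniform wavelet sampling.

A feature extractor mixes the input signal with a wavelet and integrates over
the wavelet's support.  Unlike the classical continuous wavelet transform,
where scale ties the oscillation frequency to the support size, the atoms here
have three independent degrees of freedom: oscillation frequency ``f_o``
(stored exactly as an integer period ``P`` in samples), support size ``t_s``
(samples) and time shift ``delta_t`` (samples) inside a fixed analysis window.

The Haar dictionary is enumerated by (1) doubling the oscillation frequency
from one period per window up to half the sampling rate, (2) for each
frequency, doubling the support from one period up to the full window, and
(3) allowing only shifts that are multiples of the support, so atoms sharing
(frequency, support) never overlap in time.  An optional "constant" atom with
unit value across the whole window implements direct integration of the
signal (its mean); it is the only atom able to discriminate signals that
differ solely by their DC level.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "Wavelet",
    "WaveletDictionary",
    "build_haar_dictionary",
    "build_gabor_dictionary",
    "waveform",
    "haar_count",
]

_FAMILIES = ("haar", "gabor", "constant")


@dataclass(frozen=True)
class Wavelet:
    """One dictionary atom.

    ``period`` is the oscillation period in samples (0 for the constant
    family); the frequency in Hz is derived as ``fs / period`` so enumeration
    never touches floating point.
    """

    family: str
    period: int          # samples per oscillation (0 for constant)
    t_s: int             # support, samples
    delta_t: int         # shift from window start, samples
    window_len: int      # analysis window, samples
    fs: float            # sampling rate, Hz
    gabor_sigma: float = 0.0
    gabor_phase: float = 0.0
    polarity: int = 1    # +1: first half-period is +1 (default convention)

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown wavelet family {self.family!r}")
        if self.delta_t < 0 or self.delta_t + self.t_s > self.window_len:
            raise ValueError(
                f"support [{self.delta_t}, {self.delta_t + self.t_s}) exceeds "
                f"window of {self.window_len} samples"
            )
        if self.family == "haar":
            p = self.period
            if p < 2 or p % 2 != 0:
                raise ValueError(f"haar period must be an even integer >= 2, got {p}")
            ratio = self.t_s / p
            if self.t_s % p != 0 or not _is_power_of_two(int(ratio)):
                raise ValueError(
                    f"haar support {self.t_s} must be a power-of-two multiple "
                    f"of the period {p}"
                )
        elif self.family == "constant":
            if self.t_s != self.window_len or self.delta_t != 0 or self.period != 0:
                raise ValueError("constant wavelet must span the whole window")

    @property
    def f_o(self) -> float:
        """Oscillation frequency in Hz (0 for the constant atom)."""
        return 0.0 if self.period == 0 else self.fs / self.period

    @property
    def support_seconds(self) -> float:
        return self.t_s / self.fs

    def key(self) -> tuple:
        return (self.family, self.period, self.t_s, self.delta_t, self.gabor_phase)

    def to_record(self) -> dict:
        rec = {
            "family": self.family,
            "period_samples": self.period,
            "support_samples": self.t_s,
            "shift_samples": self.delta_t,
        }
        if self.family == "gabor":
            rec["sigma_samples"] = self.gabor_sigma
            rec["phase_rad"] = self.gabor_phase
        return rec


def _is_power_of_two(n: int) -> bool:
    return n >= 1 and (n & (n - 1)) == 0


@dataclass
class WaveletDictionary:
    """Ordered collection of atoms sharing one analysis window."""

    wavelets: list[Wavelet]
    window_len: int
    fs: float
    construction_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [w.key() for w in self.wavelets]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate atoms in dictionary")
        for w in self.wavelets:
            if w.window_len != self.window_len:
                raise ValueError("atom window length differs from dictionary's")

    def __len__(self) -> int:
        return len(self.wavelets)

    def __iter__(self) -> Iterator[Wavelet]:
        return iter(self.wavelets)

    def __getitem__(self, i: int) -> Wavelet:
        return self.wavelets[i]

    # -- serialization: line-oriented JSON, one record per atom ---------------

    def to_json(self) -> str:
        header = {
            "window_len": self.window_len,
            "fs": self.fs,
            "construction_params": self.construction_params,
        }
        lines = [json.dumps(header, sort_keys=True)]
        lines += [json.dumps(w.to_record(), sort_keys=True) for w in self.wavelets]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "WaveletDictionary":
        lines = [ln for ln in text.splitlines() if ln.strip()]
        header = json.loads(lines[0])
        wavelets = []
        for ln in lines[1:]:
            rec = json.loads(ln)
            wavelets.append(
                Wavelet(
                    family=rec["family"],
                    period=rec["period_samples"],
                    t_s=rec["support_samples"],
                    delta_t=rec["shift_samples"],
                    window_len=header["window_len"],
                    fs=header["fs"],
                    gabor_sigma=rec.get("sigma_samples", 0.0),
                    gabor_phase=rec.get("phase_rad", 0.0),
                )
            )
        return cls(
            wavelets=wavelets,
            window_len=header["window_len"],
            fs=header["fs"],
            construction_params=header["construction_params"],
        )


def _check_window(window_len: int) -> None:
    if window_len < 2:
        raise ValueError(f"window_len must be >= 2, got {window_len}")
    if not _is_power_of_two(window_len):
        raise ValueError(f"window_len must be a power of two, got {window_len}")


def _haar_lattice(window_len: int) -> Iterator[tuple[int, int, int]]:
    """Yield (period, support, shift) triples in canonical order.

    Order: descending period (ascending frequency), then ascending support,
    then ascending shift.
    """
    period = window_len
    while period >= 2:
        t_s = period
        while t_s <= window_len:
            for delta_t in range(0, window_len - t_s + 1, t_s):
                yield period, t_s, delta_t
            t_s *= 2
        period //= 2


def haar_count(window_len: int) -> int:
    """Closed-form dictionary size (constant excluded): sum over periods P of
    2*N/P - 1."""
    _check_window(window_len)
    return sum(2 * window_len // p - 1
               for p in (2 ** k for k in range(1, int(math.log2(window_len)) + 1)))


def build_haar_dictionary(
    window_len: int, fs: float, include_constant: bool = False
) -> WaveletDictionary:
    """Enumerate the initial Haar dictionary for one analysis window.

    For a 256-sample window this yields 502 atoms; for 128 samples, 247
    (248 with the constant atom appended).
    """
    _check_window(window_len)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    atoms = [
        Wavelet("haar", period=p, t_s=t_s, delta_t=dt,
                window_len=window_len, fs=fs)
        for p, t_s, dt in _haar_lattice(window_len)
    ]
    if include_constant:
        atoms.append(
            Wavelet("constant", period=0, t_s=window_len, delta_t=0,
                    window_len=window_len, fs=fs)
        )
    return WaveletDictionary(
        wavelets=atoms,
        window_len=window_len,
        fs=fs,
        construction_params={
            "family": "haar",
            "include_constant": include_constant,
            "rule": "freq-doubling/support-doubling/shift-multiples",
        },
    )


def build_gabor_dictionary(
    window_len: int,
    fs: float,
    phases: Sequence[float] = (0.0, math.pi / 2),
    sigma_divisor: float = 6.0,
) -> WaveletDictionary:
    """Enumerate Gabor atoms on the same (period, support, shift) lattice as
    Haar, expanded by a phase grid; sigma = t_s / sigma_divisor."""
    _check_window(window_len)
    if fs <= 0:
        raise ValueError(f"fs must be positive, got {fs}")
    atoms = []
    for p, t_s, dt in _haar_lattice(window_len):
        for phase in phases:
            atoms.append(
                Wavelet("gabor", period=p, t_s=t_s, delta_t=dt,
                        window_len=window_len, fs=fs,
                        gabor_sigma=t_s / sigma_divisor, gabor_phase=phase)
            )
    return WaveletDictionary(
        wavelets=atoms,
        window_len=window_len,
        fs=fs,
        construction_params={
            "family": "gabor",
            "phases": list(phases),
            "sigma_divisor": sigma_divisor,
        },
    )


def waveform(w: Wavelet) -> np.ndarray:
    """Sampled amplitude sequence of length ``window_len`` (unitless).

    Haar: +-1 square oscillation inside the support, 0 elsewhere.
    Constant: all ones.  Gabor: real Gaussian-windowed sinusoid on the
    support, de-meaned over the support so it integrates a constant to zero.
    """
    out = np.zeros(w.window_len)
    if w.family == "constant":
        out[:] = 1.0
        return out
    sl = slice(w.delta_t, w.delta_t + w.t_s)
    n = np.arange(w.t_s)
    if w.family == "haar":
        half = w.period // 2
        out[sl] = np.where((n % w.period) < half, 1.0, -1.0) * w.polarity
    else:  # gabor
        center = (w.t_s - 1) / 2.0
        envelope = np.exp(-0.5 * ((n - center) / w.gabor_sigma) ** 2)
        carrier = np.cos(2.0 * math.pi * n / w.period + w.gabor_phase)
        g = envelope * carrier
        out[sl] = g - g.mean()
    return out
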