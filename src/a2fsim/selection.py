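"""Hardware-aware feature selection.

Three stages:

1. An information-gain filter ranks every candidate feature by the entropy
   reduction of the class label after discretizing the feature into 12
   equal-width bins, and keeps the top 100 — this keeps the quadratic-cost
   wrapper search tractable.
2. Sequential forward search (SFS) greedily grows the selected set, training
   a fresh classifier for every candidate subset.  The *adapted* variant only
   admits candidates whose wavelet supports can still be packed onto at most
   ``n_ext_max`` parallel hardware extractors; the *optimized* variant
   additionally penalizes the per-window extraction energy of the subset.
3. Interval scheduling assigns the chosen wavelets to extractors: one
   extractor serves any set of features whose supports do not overlap in
   time, so the minimum extractor count is the maximum overlap depth
   (greedy-by-start-time is optimal for interval graphs).

Classifier training inside SFS is seeded per (step, candidate): random weight
initialization otherwise changes which subsets win, and with it the whole
selection trajectory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from . import classify
from .classify import ClassifierSpec
from .energy import PowerBudget, feature_energy, selection_energy
from .features import FeatureMatrix, FeatureSpec
from .wavelets import Wavelet

__all__ = [
    "SelectionConfig",
    "SelectionResult",
    "ExtractorSchedule",
    "information_gain",
    "preselect_top_k",
    "schedule_extractors",
    "sfs_basic",
    "sfs_adapted",
    "sfs_optimized",
]


# ---------------------------------------------------------------------------
# information gain


def _entropy_bits(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(-(p * np.log2(p)).sum())


def information_gain(values: np.ndarray, labels: np.ndarray, n_bins: int = 12) -> float:
    """IG = H(D) - sum_i |D_i|/|D| * H(D_i), in bits, over ``n_bins``
    equal-width intervals of the feature's observed range.

    A constant feature carries no information (single occupied bin, IG = 0);
    empty bins contribute nothing.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError(
            f"values ({values.shape}) and labels ({labels.shape}) differ in length"
        )
    if values.size == 0:
        raise ValueError("need at least one sample")
    lo, hi = values.min(), values.max()
    if hi == lo:
        return 0.0
    width = (hi - lo) / n_bins
    bins = np.minimum((values - lo) // width, n_bins - 1).astype(int)
    h_total = _entropy_bits(labels)
    h_cond = 0.0
    for b in np.unique(bins):
        sub = labels[bins == b]
        h_cond += (sub.size / labels.size) * _entropy_bits(sub)
    return h_total - h_cond


def preselect_top_k(fm: FeatureMatrix, labels: np.ndarray, k: int = 100,
                    n_bins: int = 12) -> list[int]:
    """Rank all feature columns by IG (descending, ties broken by dictionary
    order) and return the first min(k, n_features) column indices."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ig = np.array([information_gain(fm.values[:, j], labels, n_bins)
                   for j in range(fm.n_features)])
    order = np.argsort(-ig, kind="stable")
    return order[: min(k, fm.n_features)].tolist()


# ---------------------------------------------------------------------------
# extractor scheduling


@dataclass
class ExtractorSchedule:
    """Assignment of features to parallel extractors.

    ``assignment[i]`` is the extractor index of feature i; each extractor's
    interval list is ordered and pairwise disjoint.  Extractors whose features
    are all constant-family (full-window direct integration) need no wavelet
    generator.
    """

    assignment: list[int]
    intervals: list[list[tuple[int, int]]]        # per extractor, [start, end)
    direct_integration: list[bool]                # per extractor

    @property
    def n_extractors(self) -> int:
        return len(self.intervals)

    @property
    def n_direct(self) -> int:
        return sum(self.direct_integration)

    @property
    def n_with_generator(self) -> int:
        return self.n_extractors - self.n_direct


def schedule_extractors(specs: Sequence[FeatureSpec]) -> ExtractorSchedule:
    """Greedy interval partitioning of wavelet supports onto extractors.

    Features are sorted by support start; each goes to the first extractor
    whose latest interval ends at or before the feature's start.  The
    resulting extractor count equals the maximum temporal overlap depth, the
    minimum possible.  Extractors are channel-agnostic (an input multiplexer
    selects the signal per feature).
    """
    specs = list(specs)
    if specs:
        wl = specs[0].wavelet.window_len
        for s in specs:
            if s.wavelet.window_len != wl:
                raise ValueError("all features must share one analysis window")
    order = sorted(range(len(specs)),
                   key=lambda i: (specs[i].wavelet.delta_t, specs[i].wavelet.t_s))
    assignment = [-1] * len(specs)
    ends: list[int] = []                          # last interval end per extractor
    intervals: list[list[tuple[int, int]]] = []
    families: list[list[str]] = []
    for i in order:
        w = specs[i].wavelet
        start, end = w.delta_t, w.delta_t + w.t_s
        for e in range(len(ends)):
            if ends[e] <= start:
                assignment[i] = e
                ends[e] = end
                intervals[e].append((start, end))
                families[e].append(w.family)
                break
        else:
            assignment[i] = len(ends)
            ends.append(end)
            intervals.append([(start, end)])
            families.append([w.family])
    direct = [all(f == "constant" for f in fam) for fam in families]
    return ExtractorSchedule(assignment, intervals, direct)


# ---------------------------------------------------------------------------
# sequential forward search


@dataclass
class SelectionConfig:
    n_preselect: int = 100
    NF_max: int = 10
    n_ext_max: int | None = None          # adapted/optimized only
    energy_weight: float = 0.0            # lambda, optimized only
    monotone_stop: bool = False
    seed: int = 0
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    budget: PowerBudget | None = None
    energy_ref: float | None = None       # J; default: full-window Haar feature

    def __post_init__(self) -> None:
        if self.n_preselect < 1:
            raise ValueError("n_preselect must be >= 1")
        if self.NF_max < 0:
            raise ValueError("NF_max must be >= 0")
        if self.n_ext_max is not None and self.n_ext_max < 1:
            raise ValueError("n_ext_max must be >= 1")
        if self.energy_weight < 0:
            raise ValueError("energy_weight must be >= 0")


@dataclass
class SelectionResult:
    selected: list[int]                   # candidate column indices, in order
    specs: list[FeatureSpec]
    metric_trajectory: list[float]        # eval metric after each step
    energy_trajectory: list[float]        # J per window after each step
    extractor_trajectory: list[tuple[int, int, int]]  # (total, with_gen, direct)
    ext_max_reached_step: int | None      # first step hitting n_ext_max (1-based)

    def __post_init__(self) -> None:
        n = len(self.selected)
        for name in ("specs", "metric_trajectory", "energy_trajectory",
                     "extractor_trajectory"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must equal step count {n}")

    @property
    def n_selected(self) -> int:
        return len(self.selected)

    def to_json(self) -> str:
        return json.dumps({
            "selected": self.selected,
            "specs": [s.describe() for s in self.specs],
            "metric_trajectory": self.metric_trajectory,
            "energy_trajectory": self.energy_trajectory,
            "extractor_trajectory": [list(t) for t in self.extractor_trajectory],
            "ext_max_reached_step": self.ext_max_reached_step,
        }, indent=1)


def _candidate_seed(base: int, step: int, rank: int) -> int:
    return (base * 1_000_003 + step * 10_007 + rank) % (2 ** 31)


def _run_sfs(
    candidates: Sequence[int],
    fm: FeatureMatrix,
    labels: np.ndarray,
    train_mask: np.ndarray,
    eval_mask: np.ndarray,
    cfg: SelectionConfig,
    n_ext_max: int | None,
    energy_weight: float,
) -> SelectionResult:
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    labels = np.asarray(labels, dtype=int)
    train_mask = np.asarray(train_mask, dtype=bool)
    eval_mask = np.asarray(eval_mask, dtype=bool)
    y_train = labels[train_mask]
    y_eval = labels[eval_mask]

    budget = cfg.budget
    if energy_weight > 0 and budget is None:
        raise ValueError("optimized SFS with lambda > 0 requires a power budget")
    e_ref = cfg.energy_ref
    if budget is not None and e_ref is None:
        # normalizer: a full-window Haar feature in this budget
        wl = fm.specs[candidates[0]].wavelet.window_len
        fs = fm.specs[candidates[0]].wavelet.fs
        ref = Wavelet("haar", period=wl, t_s=wl, delta_t=0,
                      window_len=wl, fs=fs)
        e_ref = feature_energy(ref, budget)

    selected: list[int] = []
    metric_traj: list[float] = []
    energy_traj: list[float] = []
    ext_traj: list[tuple[int, int, int]] = []
    ext_reached: int | None = None
    current_metric = -np.inf

    for step in range(1, cfg.NF_max + 1):
        best_rank = None
        best_score = -np.inf
        best_metric = None
        for rank, col in enumerate(candidates):
            if col in selected:
                continue
            trial = selected + [col]
            if n_ext_max is not None:
                if schedule_extractors([fm.specs[c] for c in trial]).n_extractors \
                        > n_ext_max:
                    continue
            spec = replace(cfg.classifier,
                           n_classes=len(np.unique(labels)),
                           seed=_candidate_seed(cfg.seed, step, rank))
            X = fm.values[:, trial]
            model = classify.train(spec, X[train_mask], y_train)
            acc = classify.evaluate(model, X[eval_mask], y_eval).accuracy
            score = acc
            if budget is not None and energy_weight > 0:
                e = selection_energy([fm.specs[c] for c in trial], budget)
                score = acc - energy_weight * (e / e_ref)
            if score > best_score:  # strict: ties keep the lowest rank
                best_score, best_rank, best_metric = score, rank, acc
        if best_rank is None:
            break  # no admissible candidate left
        if cfg.monotone_stop and best_metric <= current_metric:
            break
        col = candidates[best_rank]
        selected.append(col)
        current_metric = best_metric
        chosen_specs = [fm.specs[c] for c in selected]
        sched = schedule_extractors(chosen_specs)
        metric_traj.append(best_metric)
        energy_traj.append(
            selection_energy(chosen_specs, budget) if budget is not None else 0.0
        )
        ext_traj.append(
            (sched.n_extractors, sched.n_with_generator, sched.n_direct)
        )
        if (n_ext_max is not None and ext_reached is None
                and sched.n_extractors == n_ext_max):
            ext_reached = step

    return SelectionResult(selected, [fm.specs[c] for c in selected],
                           metric_traj, energy_traj, ext_traj, ext_reached)


def sfs_basic(candidates: Sequence[int], fm: FeatureMatrix, labels: np.ndarray,
              train_mask: np.ndarray, eval_mask: np.ndarray,
              cfg: SelectionConfig) -> SelectionResult:
    """Greedy forward search maximizing eval accuracy; no hardware limits."""
    return _run_sfs(candidates, fm, labels, train_mask, eval_mask, cfg,
                    n_ext_max=None, energy_weight=0.0)


def sfs_adapted(candidates: Sequence[int], fm: FeatureMatrix, labels: np.ndarray,
                train_mask: np.ndarray, eval_mask: np.ndarray,
                cfg: SelectionConfig) -> SelectionResult:
    """Forward search admitting only candidates whose subset still fits on
    ``cfg.n_ext_max`` parallel extractors."""
    if cfg.n_ext_max is None:
        raise ValueError("adapted SFS requires n_ext_max")
    return _run_sfs(candidates, fm, labels, train_mask, eval_mask, cfg,
                    n_ext_max=cfg.n_ext_max, energy_weight=0.0)


def sfs_optimized(candidates: Sequence[int], fm: FeatureMatrix, labels: np.ndarray,
                  train_mask: np.ndarray, eval_mask: np.ndarray,
                  cfg: SelectionConfig) -> SelectionResult:
    """Adapted search scoring accuracy - lambda * E(subset)/E_ref; with
    lambda = 0 it reduces exactly to the adapted search."""
    if cfg.n_ext_max is None:
        raise ValueError("optimized SFS requires n_ext_max")
    return _run_sfs(candidates, fm, labels, train_mask, eval_mask, cfg,
                    n_ext_max=cfg.n_ext_max, energy_weight=cfg.energy_weight)
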