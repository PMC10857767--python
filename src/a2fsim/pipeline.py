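"""End-to-end experiment orchestration.

One declarative config drives: data (synthetic or on-disk) -> per-channel
wavelet dictionary -> feature extraction -> optional quantization ->
standardization -> information-gain pre-selection -> SFS (basic / adapted /
optimized) -> final refit and test evaluation -> extractor accounting,
compression ratio and (when a power budget is given) energy breakdowns.

Candidate subsets inside SFS are scored on a held-out validation split carved
from the training windows by default; ``split_policy="test"`` scores them on
the test split instead (matching the original experimental protocol, at the
cost of selection-level test leakage).  The final reported metrics always
come from a classifier refit on the full training split and evaluated on the
untouched test split.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import classify
from .classify import ClassifierSpec, MetricsReport
from .energy import PowerBudget, chain_a2f, compression_ratio, selection_energy
from .features import (FeatureMatrix, FeatureSpec, QuantizationConfig,
                       WindowedDataset, extract_matrix, quantize, standardize)
from .selection import (SelectionConfig, SelectionResult, preselect_top_k,
                        schedule_extractors, sfs_adapted, sfs_basic,
                        sfs_optimized)
from .simulate import EcgSimConfig, InertialSimConfig, gen_ecg, gen_inertial
from .wavelets import build_haar_dictionary

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment",
           "report_table2", "build_feature_specs"]

_APPLICATIONS = ("arrhythmia", "har_multiclass", "har_one_vs_all")
_SFS_MODES = {"basic": sfs_basic, "adapted": sfs_adapted,
              "optimized": sfs_optimized}


@dataclass
class ExperimentConfig:
    application: str = "arrhythmia"
    sim: EcgSimConfig | InertialSimConfig | None = None
    dataset_path: str | None = None
    include_constant: bool = True
    sfs_mode: str = "adapted"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    final_classifier: ClassifierSpec | None = None  # defaults to selection's
    quantization_bits: int | None = None
    budget: PowerBudget | None = None
    split_policy: str = "validation"   # or "test"
    validation_frac: float = 0.25      # of the training windows
    chain_duration_s: float = 10.0
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.application not in _APPLICATIONS:
            raise ValueError(f"unknown application {self.application!r}")
        if self.sfs_mode not in _SFS_MODES:
            raise ValueError(f"unknown SFS mode {self.sfs_mode!r}")
        if self.split_policy not in ("validation", "test"):
            raise ValueError(f"unknown split policy {self.split_policy!r}")


@dataclass
class ExperimentReport:
    application: str
    selection: SelectionResult | dict
    metrics: MetricsReport | dict
    compression_pct: float
    extractors: dict
    energy: dict | None
    stages: list[dict]
    seed: int

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, SelectionResult):
                return json.loads(o.to_json())
            if isinstance(o, MetricsReport):
                return o.to_dict()
            if isinstance(o, np.generic):
                return o.item()
            raise TypeError(type(o).__name__)
        return json.dumps(self.__dict__, default=enc, indent=1)


def build_feature_specs(ds: WindowedDataset,
                        include_constant: bool) -> list[FeatureSpec]:
    """One Haar dictionary per channel (plus the constant atom on request),
    flattened channel-major into candidate features."""
    dictionary = build_haar_dictionary(ds.window_len, ds.fs,
                                       include_constant=include_constant)
    return [FeatureSpec(ch, w) for ch in range(ds.n_channels)
            for w in dictionary]


def _load_dataset(cfg: ExperimentConfig) -> WindowedDataset:
    if cfg.sim is not None:
        if isinstance(cfg.sim, EcgSimConfig):
            return gen_ecg(cfg.sim)
        return gen_inertial(cfg.sim)
    if cfg.dataset_path is not None:
        return WindowedDataset.load(cfg.dataset_path)
    raise ValueError("config needs either a synthetic sim config or a dataset path")


def _carve_validation(labels: np.ndarray, train_mask: np.ndarray,
                      frac: float, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Stratified fit/eval sub-split of the training windows."""
    rng = np.random.default_rng(seed)
    fit = train_mask.copy()
    eval_mask = np.zeros_like(train_mask)
    for c in np.unique(labels[train_mask]):
        idx = np.flatnonzero(train_mask & (labels == c))
        idx = rng.permutation(idx)
        n_val = max(1, int(round(frac * idx.size)))
        eval_mask[idx[:n_val]] = True
        fit[idx[:n_val]] = False
    return fit, eval_mask


def _run_selection(cfg: ExperimentConfig, fm: FeatureMatrix,
                   labels: np.ndarray, train_mask: np.ndarray,
                   test_mask: np.ndarray) -> SelectionResult:
    sel_cfg = cfg.selection
    if cfg.budget is not None and sel_cfg.budget is None:
        sel_cfg = replace(sel_cfg, budget=cfg.budget)
    train_fm = FeatureMatrix(fm.values[train_mask], fm.specs,
                             quantized=fm.quantized, bits=fm.bits)
    ranked = preselect_top_k(train_fm, labels[train_mask],
                             k=sel_cfg.n_preselect)
    if cfg.split_policy == "validation":
        fit_mask, eval_mask = _carve_validation(
            labels, train_mask, cfg.validation_frac, cfg.seed)
    else:
        fit_mask, eval_mask = train_mask, test_mask
    return _SFS_MODES[cfg.sfs_mode](ranked, fm, labels, fit_mask, eval_mask,
                                    sel_cfg)


def _final_metrics(cfg: ExperimentConfig, fm: FeatureMatrix,
                   labels: np.ndarray, selected: list[int],
                   train_mask: np.ndarray, test_mask: np.ndarray
                   ) -> MetricsReport:
    spec = cfg.final_classifier or cfg.selection.classifier
    spec = replace(spec, n_classes=len(np.unique(labels)),
                   seed=cfg.seed % (2 ** 31))
    X = fm.values[:, selected]
    model = classify.train(spec, X[train_mask], labels[train_mask])
    return classify.evaluate(model, X[test_mask], labels[test_mask])


def _compression(ds: WindowedDataset, selection: SelectionResult) -> float:
    """Features kept vs Nyquist samples of the channels that actually feed
    the selection (one window)."""
    channels = {s.channel for s in selection.specs}
    n_samples = ds.window_len * max(1, len(channels))
    return compression_ratio(selection.n_selected, n_samples)


def run_experiment(cfg: ExperimentConfig) -> ExperimentReport:
    stages: list[dict] = []
    current_stage = "data"

    def stage(name: str):
        nonlocal current_stage
        current_stage = name
        t0 = time.perf_counter()

        def done(**info):
            stages.append({"stage": name, "seconds": time.perf_counter() - t0,
                           **info})
        return done

    try:
        done = stage("data")
        ds = _load_dataset(cfg)
        done(n_windows=ds.n_windows, n_channels=ds.n_channels)

        done = stage("features")
        specs = build_feature_specs(ds, cfg.include_constant)
        fm = extract_matrix(ds, specs)
        done(n_features=fm.n_features)

        if cfg.quantization_bits is not None:
            done = stage("quantize")
            fm = quantize(fm, QuantizationConfig(bits=cfg.quantization_bits),
                          ds.train_mask)
            done(bits=cfg.quantization_bits)

        done = stage("standardize")
        fm, _, _ = standardize(fm, ds.train_mask)
        done()

        done = stage("selection")
        if cfg.application == "har_one_vs_all":
            per_class: dict[str, SelectionResult] = {}
            per_class_metrics: dict[str, MetricsReport] = {}
            for c, name in enumerate(ds.class_names):
                labels_c = (ds.labels == c).astype(int)
                sel = _run_selection(cfg, fm, labels_c, ds.train_mask,
                                     ds.test_mask)
                per_class[name] = sel
                per_class_metrics[name] = _final_metrics(
                    cfg, fm, labels_c, sel.selected, ds.train_mask,
                    ds.test_mask)
            done(classes=len(per_class))
            selection: SelectionResult | dict = per_class
            metrics: MetricsReport | dict = per_class_metrics
            any_sel = next(iter(per_class.values()))
            sched = schedule_extractors(any_sel.specs)
            compression = _compression(ds, any_sel)
            first_specs = any_sel.specs
        else:
            sel = _run_selection(cfg, fm, ds.labels, ds.train_mask,
                                 ds.test_mask)
            done(n_selected=sel.n_selected)
            done = stage("final_fit")
            metrics = _final_metrics(cfg, fm, ds.labels, sel.selected,
                                     ds.train_mask, ds.test_mask)
            done()
            selection = sel
            sched = schedule_extractors(sel.specs)
            compression = _compression(ds, sel)
            first_specs = sel.specs

        extractors = {
            "total": sched.n_extractors,
            "with_generator": sched.n_with_generator,
            "direct_integration": sched.n_direct,
        }

        energy = None
        if cfg.budget is not None and first_specs:
            window_period = ds.window_len / ds.fs
            energy = {
                "per_window_J": selection_energy(first_specs, cfg.budget),
                "chain_a2f": chain_a2f(cfg.chain_duration_s, first_specs,
                                       window_period, cfg.budget).to_dict(),
                "p_wavelet_W": cfg.budget.P_wavelet,
            }
    except Exception as err:
        raise RuntimeError(
            f"experiment aborted in stage {current_stage!r}: {err}") from err

    report = ExperimentReport(
        application=cfg.application,
        selection=selection,
        metrics=metrics,
        compression_pct=compression,
        extractors=extractors,
        energy=energy,
        stages=stages,
        seed=cfg.seed,
    )
    if cfg.output_dir is not None:
        out = Path(cfg.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        tmp = out / "report.json.tmp"
        tmp.write_text(report.to_json())
        tmp.replace(out / "report.json")
    return report


def report_table2(results: dict[str, tuple[SelectionResult, float]]):
    """Tabulate one-vs-all selections: features, metric, extractor totals
    and the generator / direct-integration split per class.

    ``results`` maps class name to (selection, metric value).
    """
    import pandas as pd

    if not results:
        raise ValueError("no per-class results")
    rows = []
    for name, (sel, metric) in results.items():
        if sel.n_selected == 0:
            raise ValueError(f"empty selection for class {name!r}")
        sched = schedule_extractors(sel.specs)
        rows.append({
            "class": name,
            "n_features": sel.n_selected,
            "metric": metric,
            "extractors": sched.n_extractors,
            "with_generator": sched.n_with_generator,
            "direct_integration": sched.n_direct,
        })
    return pd.DataFrame(rows).set_index("class")
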