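"""Information gain, extractor scheduling and the SFS variants."""

import itertools

import numpy as np
import pytest

from a2fsim.classify import ClassifierSpec
from a2fsim.energy import reference_budget, selection_energy
from a2fsim.features import FeatureMatrix, FeatureSpec
from a2fsim.selection import (SelectionConfig, information_gain,
                              preselect_top_k, schedule_extractors,
                              sfs_adapted, sfs_basic, sfs_optimized)
from a2fsim.wavelets import Wavelet

# ---------------------------------------------------------------------------
# information gain


def test_ig_constant_feature_is_zero():
    assert information_gain(np.ones(20), np.arange(20) % 3) == 0.0


def test_ig_hand_computed_toy():
    # H(D) = 1 bit; every occupied bin is class-pure, so IG = 1 exactly
    values = np.array([0.0, 1.0, 10.0, 11.0])
    labels = np.array([0, 0, 1, 1])
    assert information_gain(values, labels, n_bins=12) == pytest.approx(1.0)


def test_ig_entropy_bounds_on_random_inputs():
    rng = np.random.default_rng(42)
    for _ in range(300):
        n = rng.integers(2, 40)
        values = rng.standard_normal(n)
        labels = rng.integers(0, rng.integers(2, 5), n)
        _, counts = np.unique(labels, return_counts=True)
        p = counts / n
        h = -(p * np.log2(p)).sum()
        ig = information_gain(values, labels)
        assert -1e-12 <= ig <= h + 1e-12


def test_ig_affine_invariance():
    rng = np.random.default_rng(1)
    values = rng.standard_normal(60)
    labels = rng.integers(0, 2, 60)
    base = information_gain(values, labels)
    assert information_gain(3.5 * values + 2.0, labels) == pytest.approx(base)


def test_ig_length_mismatch_rejected():
    with pytest.raises(ValueError):
        information_gain(np.zeros(3), np.zeros(4, dtype=int))


# ---------------------------------------------------------------------------
# pre-selection


def _fm_from_columns(cols):
    cols = np.asarray(cols, dtype=float)
    w = Wavelet("haar", period=4, t_s=4, delta_t=0, window_len=8, fs=10.0)
    return FeatureMatrix(cols, [FeatureSpec(0, w)] * cols.shape[1])


def test_preselect_large_k_returns_permutation():
    rng = np.random.default_rng(0)
    fm = _fm_from_columns(rng.standard_normal((30, 7)))
    labels = rng.integers(0, 2, 30)
    assert sorted(preselect_top_k(fm, labels, k=100)) == list(range(7))


def test_preselect_label_indicator_ranks_first():
    rng = np.random.default_rng(11)
    labels = rng.integers(0, 2, 80)
    noise = rng.standard_normal((80, 19))
    cols = np.column_stack([noise[:, :10], labels.astype(float), noise[:, 10:]])
    fm = _fm_from_columns(cols)
    assert preselect_top_k(fm, labels, k=5)[0] == 10


def test_preselect_ties_keep_dictionary_order():
    rng = np.random.default_rng(2)
    labels = rng.integers(0, 2, 40)
    col = labels.astype(float) + 0.01 * rng.standard_normal(40)
    fm = _fm_from_columns(np.column_stack([col, col]))
    assert preselect_top_k(fm, labels, k=2) == [0, 1]


# ---------------------------------------------------------------------------
# extractor scheduling


def _spec(delta_t, t_s, family="haar", n=128, fs=50.0):
    if family == "constant":
        w = Wavelet("constant", period=0, t_s=n, delta_t=0, window_len=n, fs=fs)
    else:
        w = Wavelet("haar", period=t_s, t_s=t_s, delta_t=delta_t,
                    window_len=n, fs=fs)
    return FeatureSpec(0, w)


def brute_force_min_extractors(intervals):
    """Independent oracle: smallest k such that some assignment of intervals
    to k machines keeps each machine conflict-free (backtracking search)."""
    n = len(intervals)

    def feasible(k):
        ends = [0] * k  # machines interchangeable: track last end per machine
        order = sorted(range(n), key=lambda i: intervals[i][0])

        def place(pos):
            if pos == len(order):
                return True
            s, e = intervals[order[pos]]
            tried = set()
            for m in range(k):
                if ends[m] in tried:
                    continue
                tried.add(ends[m])
                if ends[m] <= s:
                    saved = ends[m]
                    ends[m] = e
                    if place(pos + 1):
                        return True
                    ends[m] = saved
            return False

        return place(0)

    for k in range(1, n + 1):
        if feasible(k):
            return k
    return n


def test_two_non_overlapping_wavelets_share_one_extractor():
    sched = schedule_extractors([_spec(0, 32), _spec(64, 32)])
    assert sched.n_extractors == 1


def test_identical_supports_need_two_extractors():
    sched = schedule_extractors([_spec(0, 32), _spec(0, 32)])
    assert sched.n_extractors == 2


def test_toy_depth_three():
    specs = [_spec(0, 64), _spec(32, 32), _spec(32, 64, n=128),
             _spec(96, 32), _spec(0, 32)]
    intervals = [(s.wavelet.delta_t, s.wavelet.delta_t + s.wavelet.t_s)
                 for s in specs]
    sched = schedule_extractors(specs)
    assert sched.n_extractors == brute_force_min_extractors(intervals) == 3


def test_greedy_matches_exhaustive_minimum_on_random_instances():
    rng = np.random.default_rng(9)
    for _ in range(150):
        n_feat = rng.integers(1, 8)
        specs = []
        for _ in range(n_feat):
            t_s = int(2 ** rng.integers(2, 8))          # 4..128
            dt = int(rng.integers(0, (128 - t_s) // t_s + 1)) * t_s
            specs.append(_spec(dt, t_s))
        intervals = [(s.wavelet.delta_t, s.wavelet.delta_t + s.wavelet.t_s)
                     for s in specs]
        assert schedule_extractors(specs).n_extractors == \
            brute_force_min_extractors(intervals)


def test_constant_features_tagged_direct_integration():
    sched = schedule_extractors([_spec(0, 32), _spec(0, 0, family="constant")])
    assert sched.n_extractors == 2
    assert sched.n_direct == 1 and sched.n_with_generator == 1
    # the constant feature sits alone on its extractor
    const_ext = sched.assignment[1]
    assert sched.assignment.count(const_ext) == 1


def test_schedule_intervals_disjoint_within_extractor():
    rng = np.random.default_rng(4)
    specs = []
    for _ in range(12):
        t_s = int(2 ** rng.integers(2, 7))
        dt = int(rng.integers(0, (128 - t_s) // t_s + 1)) * t_s
        specs.append(_spec(dt, t_s))
    sched = schedule_extractors(specs)
    for iv in sched.intervals:
        for (_, e1), (s2, _) in zip(iv, iv[1:]):
            assert e1 <= s2


# ---------------------------------------------------------------------------
# SFS


def _sfs_problem(seed=0, n=90):
    """Small linearly-structured problem: col 0 perfectly separates, col 1 is
    its duplicate with a different (overlapping) wavelet, cols 2+ are noise.
    Wavelet supports overlap for cols 0-1 and are disjoint for noise cols."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n)
    signal = 2.0 * labels - 1.0
    cols = [signal, signal + 0.001 * rng.standard_normal(n)]
    cols += [rng.standard_normal(n) for _ in range(4)]
    specs = [
        _spec(0, 64), _spec(0, 64),              # overlapping pair
        _spec(64, 16), _spec(80, 16), _spec(96, 16), _spec(112, 16),
    ]
    fm = FeatureMatrix(np.column_stack(cols), specs)
    masks = np.arange(n) < int(0.6 * n)
    return fm, labels, masks, ~masks


def _cfg(**kw):
    kw.setdefault("classifier", ClassifierSpec(hidden_sizes=[4], epochs=40))
    kw.setdefault("NF_max", 3)
    kw.setdefault("seed", 5)
    return SelectionConfig(**kw)


def test_sfs_nf_max_zero_gives_empty_result():
    fm, labels, tr, ev = _sfs_problem()
    res = sfs_basic(range(6), fm, labels, tr, ev, _cfg(NF_max=0))
    assert res.n_selected == 0


def test_sfs_empty_candidates_rejected():
    fm, labels, tr, ev = _sfs_problem()
    with pytest.raises(ValueError):
        sfs_basic([], fm, labels, tr, ev, _cfg())


def test_sfs_picks_separating_feature_first():
    fm, labels, tr, ev = _sfs_problem()
    res = sfs_basic(range(6), fm, labels, tr, ev, _cfg(NF_max=1))
    assert res.selected[0] == 0
    assert res.metric_trajectory[0] == pytest.approx(1.0)


def test_sfs_monotone_stop_gives_increasing_trajectory():
    fm, labels, tr, ev = _sfs_problem()
    res = sfs_basic(range(6), fm, labels, tr, ev,
                    _cfg(NF_max=5, monotone_stop=True))
    traj = res.metric_trajectory
    assert all(b > a for a, b in zip(traj, traj[1:]))


def test_adapted_single_extractor_selection_is_non_overlapping():
    fm, labels, tr, ev = _sfs_problem()
    res = sfs_adapted(range(6), fm, labels, tr, ev,
                      _cfg(NF_max=4, n_ext_max=1))
    assert schedule_extractors(res.specs).n_extractors == 1
    assert all(t[0] <= 1 for t in res.extractor_trajectory)


def test_adapted_excludes_overlapping_duplicate():
    # cols 0 and 1 overlap in time; with one extractor only one may enter
    fm, labels, tr, ev = _sfs_problem()
    res = sfs_adapted(range(6), fm, labels, tr, ev,
                      _cfg(NF_max=2, n_ext_max=1))
    assert res.selected[0] == 0
    assert 1 not in res.selected
    assert res.n_selected == 2          # best non-overlapping noise col next


def test_adapted_with_loose_bound_equals_basic():
    fm, labels, tr, ev = _sfs_problem()
    cfg = _cfg(NF_max=3, n_ext_max=10)
    a = sfs_adapted(range(6), fm, labels, tr, ev, cfg)
    b = sfs_basic(range(6), fm, labels, tr, ev, cfg)
    assert a.selected == b.selected
    assert a.metric_trajectory == b.metric_trajectory


def test_optimized_lambda_zero_reduces_to_adapted():
    fm, labels, tr, ev = _sfs_problem()
    budget = reference_budget(0.1e-6)
    cfg = _cfg(NF_max=3, n_ext_max=2, energy_weight=0.0, budget=budget)
    a = sfs_adapted(range(6), fm, labels, tr, ev, cfg)
    o = sfs_optimized(range(6), fm, labels, tr, ev, cfg)
    assert o.selected == a.selected
    assert o.metric_trajectory == a.metric_trajectory
    assert o.energy_trajectory == a.energy_trajectory


def test_optimized_prefers_shorter_support_at_equal_accuracy():
    # three duplicated perfect columns with supports 128, 64, 32
    rng = np.random.default_rng(3)
    labels = rng.integers(0, 2, 80)
    col = 2.0 * labels - 1.0
    fm = FeatureMatrix(
        np.column_stack([col, col, col]),
        [_spec(0, 128), _spec(0, 64), _spec(0, 32)],
    )
    tr = np.arange(80) < 50
    budget = reference_budget(0.1e-6)
    cfg = _cfg(NF_max=1, n_ext_max=3, energy_weight=0.5, budget=budget)
    res = sfs_optimized(range(3), fm, labels, tr, ~tr, cfg)
    assert res.selected == [2]
    # exhaustive score check: equal accuracy, so ranking is by energy alone
    energies = [selection_energy([fm.specs[j]], budget) for j in range(3)]
    assert int(np.argmin(energies)) == 2


def test_sfs_is_reproducible_run_to_run():
    fm, labels, tr, ev = _sfs_problem()
    cfg = _cfg(NF_max=3)
    r1 = sfs_basic(range(6), fm, labels, tr, ev, cfg)
    r2 = sfs_basic(range(6), fm, labels, tr, ev, cfg)
    assert r1.to_json() == r2.to_json()
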