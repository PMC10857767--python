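"""Per-feature and whole-chain energy arithmetic."""

import numpy as np
import pytest

from a2fsim.energy import (EnergyBreakdown, PowerBudget, chain_a2f, chain_a2i,
                           chain_nyquist, compression_ratio, feature_energy,
                           reference_budget, selection_energy)
from a2fsim.features import FeatureSpec
from a2fsim.wavelets import Wavelet


def _haar(t_s=256, delta_t=0, n=256, fs=360.0):
    return Wavelet("haar", period=t_s, t_s=t_s, delta_t=delta_t,
                   window_len=n, fs=fs)


def _const(n=256, fs=360.0):
    return Wavelet("constant", period=0, t_s=n, delta_t=0, window_len=n, fs=fs)


@pytest.fixture
def budget():
    return reference_budget(0.1e-6)


def test_feature_energy_direct_arithmetic(budget):
    # full 256-sample window at 360 Hz is the 0.711 s support
    w = _haar()
    expected = (5.04e-6 + 0.625e-6 + 0.1e-6) * (256 / 360.0) + 0.3e-6 / 40e3
    assert feature_energy(w, budget) == pytest.approx(expected)
    assert expected == pytest.approx(4.099e-6, rel=2e-3)  # ~4.099 uJ + 7.5 pJ


def test_feature_energy_short_support_approaches_adc_term(budget):
    short = Wavelet("haar", period=2, t_s=2, delta_t=0, window_len=256, fs=360.0)
    adc_term = budget.P_adc / budget.F_s_adc
    assert feature_energy(short, budget) == \
        pytest.approx(adc_term + (5.04e-6 + 0.625e-6 + 0.1e-6) * 2 / 360.0)
    assert feature_energy(short, budget) < feature_energy(_haar(), budget)


def test_constant_wavelet_skips_generator_power(budget):
    assert feature_energy(_const(), budget) < feature_energy(_haar(), budget)
    diff = feature_energy(_haar(), budget) - feature_energy(_const(), budget)
    assert diff == pytest.approx(budget.P_wavelet * 256 / 360.0)


def test_feature_energy_monotone_in_support_and_powers(budget):
    energies = [feature_energy(_haar(t_s=t), budget) for t in (32, 64, 128, 256)]
    assert all(a < b for a, b in zip(energies, energies[1:]))
    richer = reference_budget(0.2e-6)
    assert feature_energy(_haar(), richer) > feature_energy(_haar(), budget)


def test_nyquist_chain_printed_constants(budget):
    bd = chain_nyquist(10.0, budget)
    # amplifier + anti-aliasing LPF + ADC sum to 6.04 uW per channel
    assert bd.acquisition == pytest.approx(6.04e-6 * 10.0)
    # 37 nJ per transmitted 10-bit sample
    per_sample = bd.transmission / (budget.F_s_nyq * 10.0)
    assert per_sample == pytest.approx(37e-9)
    assert bd.transmission == pytest.approx(740e-6)


def test_a2i_chain(budget):
    bd = chain_a2i(10.0, budget)
    assert bd.acquisition == pytest.approx(9e-6)
    assert bd.transmission == pytest.approx(chain_nyquist(10.0, budget).transmission / 4)
    b1 = reference_budget(0.1e-6, a2i_compression=1.0)
    assert chain_a2i(10.0, b1).transmission == \
        pytest.approx(chain_nyquist(10.0, b1).transmission)


def test_a2f_chain_transmission_reductions(budget):
    period = 256 / 360.0
    specs8 = [FeatureSpec(0, _haar(t_s=32, delta_t=32 * i)) for i in range(8)]
    off = chain_a2f(10.0, specs8, period, budget, in_sensor=False)
    on = chain_a2f(10.0, specs8, period, budget, in_sensor=True, result_bits=1)
    assert off.transmission / on.transmission == pytest.approx(80.0)
    assert on.classification > 0 and off.classification == 0

    for n_feat, expected in ((16, 160 / 3), (17, 170 / 3)):
        specs = [FeatureSpec(0, _haar(t_s=2, delta_t=2 * i, n=128, fs=50.0))
                 for i in range(n_feat)]
        off = chain_a2f(10.0, specs, 1.28, budget, in_sensor=False)
        on = chain_a2f(10.0, specs, 1.28, budget, in_sensor=True, result_bits=3)
        assert off.transmission / on.transmission == pytest.approx(expected)


def test_a2f_chain_acquisition_is_window_count_times_feature_sum(budget):
    specs = [FeatureSpec(0, _haar(t_s=64, delta_t=64 * i)) for i in range(3)]
    period = 256 / 360.0
    bd = chain_a2f(10.0, specs, period, budget)
    n_windows = int(10.0 // period)
    assert bd.acquisition == pytest.approx(
        n_windows * selection_energy(specs, budget))
    assert bd.total == pytest.approx(
        bd.acquisition + bd.transmission + bd.classification)


def test_a2f_empty_selection_rejected(budget):
    with pytest.raises(ValueError):
        chain_a2f(10.0, [], 0.711, budget)


def test_a2f_below_nyquist_for_plausible_generator_power():
    # worst case: 8 full-window features, generator power swept over [0, 1 uW]
    period = 256 / 360.0
    for p_wavelet in (0.0, 0.1e-6, 0.5e-6, 1e-6):
        b = reference_budget(p_wavelet)
        specs = [FeatureSpec(0, _haar())] + \
            [FeatureSpec(ch, _haar()) for ch in range(1, 8)]
        a2f = chain_a2f(10.0, specs, period, b)
        assert a2f.total < chain_nyquist(10.0, b).total


@pytest.mark.parametrize("n_feat,n_samp,expected",
                         [(7, 256, 97.3), (16, 384, 95.8), (17, 384, 95.6),
                          (0, 100, 100.0), (100, 100, 0.0)])
def test_compression_ratio_printed_values(n_feat, n_samp, expected):
    assert compression_ratio(n_feat, n_samp) == expected


def test_compression_ratio_rejects_bad_input():
    with pytest.raises(ValueError):
        compression_ratio(5, 0)
    with pytest.raises(ValueError):
        compression_ratio(10, 5)


def test_budget_validation_and_round_trip(tmp_path, budget):
    with pytest.raises(ValueError):
        reference_budget(-1e-6)
    with pytest.raises(ValueError):
        reference_budget(0.0, adc_bits=0)
    p = tmp_path / "budget.json"
    p.write_text(budget.to_json())
    again = PowerBudget.load(p)
    assert again == budget


def test_breakdown_invariants():
    bd = EnergyBreakdown(1e-6, 2e-6, 3e-6)
    assert bd.total == pytest.approx(6e-6)
    with pytest.raises(ValueError):
        EnergyBreakdown(-1e-9, 0.0)
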