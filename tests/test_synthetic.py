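"""Simulator statistics, determinism, leakage logic, and scenarios."""

import dataclasses

import numpy as np
import pytest

from luvburst import (
    AnalysisConfig,
    LeakModel,
    SimConfig,
    count_events,
    dose_config,
    make_scenario,
    permeabilized_fraction_from_dose,
    resolve_leak,
    simulate_trace,
)

SHORT = SimConfig(duration_s=5.0)


def events(trace, window_s):
    return count_events(trace, AnalysisConfig(window_s=window_s)).n_events


def test_fixed_seed_is_bit_identical():
    cfg = dataclasses.replace(SHORT, permeabilized_fraction=0.5, seed=42)
    t1, truth1 = simulate_trace(cfg)
    t2, truth2 = simulate_trace(cfg)
    np.testing.assert_array_equal(t1.counts, t2.counts)
    assert truth1 == truth2


def test_no_arrivals_no_background_gives_silence():
    cfg = dataclasses.replace(SHORT, arrival_rate=0.0, background_rate=0.0, seed=0)
    trace, truth = simulate_trace(cfg)
    assert truth == []
    assert trace.total_photons == 0


def test_background_only_total_counts_poisson_mean():
    r, T = 2000.0, 5.0
    cfg = dataclasses.replace(SHORT, arrival_rate=0.0, background_rate=r, seed=1)
    trace, _ = simulate_trace(cfg)
    mean = r * T
    assert abs(trace.total_photons - mean) < 4 * np.sqrt(mean)


def test_transit_count_matches_poisson_process_rate():
    cfg = SimConfig(duration_s=300.0, arrival_rate=16.7, seed=2)
    _, truth = simulate_trace(cfg)
    mean = 16.7 * 300.0
    assert abs(len(truth) - mean) < 4 * np.sqrt(mean)
    # arrivals sorted and inside the record
    times = [t.arrival_time_s for t in truth]
    assert times == sorted(times)
    assert all(0 <= t <= 300.0 for t in times)


def test_dye_occupancy_law_of_large_numbers():
    cfg = SimConfig(duration_s=600.0, arrival_rate=20.0, seed=3)  # ~12000 vesicles
    _, truth = simulate_trace(cfg)
    assert len(truth) > 1e4
    mean_dyes = np.mean([t.n_dyes for t in truth])
    assert mean_dyes == pytest.approx(cfg.mean_dyes, rel=0.05)


def test_truth_peak_rate_consistency():
    cfg = dataclasses.replace(SHORT, permeabilized_fraction=0.5, seed=4)
    _, truth = simulate_trace(cfg)
    for t in truth:
        if not t.dye_retained:
            assert t.peak_rate == 0.0
        else:
            b = cfg.brightness_bright if t.permeabilized else cfg.brightness_dark
            assert t.peak_rate == pytest.approx(t.n_dyes * b)


def test_bin_width_must_be_smaller_than_duration():
    with pytest.raises(ValueError):
        SimConfig(duration_s=1e-4, bin_width_s=1e-4)


def test_hill_fraction_midpoint_and_limits():
    assert permeabilized_fraction_from_dose(0.0, 0.01, 1.0) == 0.0
    assert permeabilized_fraction_from_dose(0.01, 0.01, 1.0) == pytest.approx(0.5)
    assert permeabilized_fraction_from_dose(0.010, 0.010, 2.7) == pytest.approx(0.5)
    assert permeabilized_fraction_from_dose(1e6, 0.01, 1.0) == pytest.approx(1.0, abs=1e-6)


def test_leak_size_exclusion(rng):
    # a 46 A dextran-conjugated dye cannot pass an 11 A pore
    dextran = LeakModel(dye_diameter_A=46.0, pore_diameter_A=11.0, leak_probability_if_fits=1.0)
    assert all(resolve_leak(dextran, rng) for _ in range(100))
    # a 10 A free dye always escapes an 11 A pore at leak probability 1
    free = LeakModel(dye_diameter_A=10.0, pore_diameter_A=11.0, leak_probability_if_fits=1.0)
    assert not any(resolve_leak(free, rng) for _ in range(100))
    # zero leak probability retains regardless of sizes
    safe = LeakModel(dye_diameter_A=10.0, pore_diameter_A=60.0, leak_probability_if_fits=0.0)
    assert all(resolve_leak(safe, rng) for _ in range(100))


def test_leaky_pores_suppress_detected_events():
    base = SimConfig(duration_s=10.0, permeabilized_fraction=1.0)
    free_dye = dataclasses.replace(
        base,
        leak=LeakModel(dye_diameter_A=10.0, pore_diameter_A=30.0, leak_probability_if_fits=1.0),
        seed=5,
    )
    dextran = dataclasses.replace(
        free_dye,
        leak=LeakModel(dye_diameter_A=46.0, pore_diameter_A=30.0, leak_probability_if_fits=1.0),
    )
    ev_free = events(simulate_trace(free_dye)[0], 10.0)
    ev_dex = events(simulate_trace(dextran)[0], 10.0)
    assert ev_free == 0
    assert ev_dex > 50


def test_scenario_ordering_over_seeds():
    base = SimConfig(duration_s=10.0)
    means = {}
    for name in ("blank", "calcium_only", "permeabilized"):
        cfg = make_scenario(name, base)
        counts = [
            events(simulate_trace(dataclasses.replace(cfg, seed=s))[0], 10.0)
            for s in range(10)
        ]
        means[name] = np.mean(counts)
    assert means["blank"] <= means["calcium_only"] <= means["permeabilized"]
    assert means["permeabilized"] > 10 * max(means["calcium_only"], 1.0)


def test_triton_scenario_is_eventless():
    cfg = make_scenario("triton", SimConfig(duration_s=10.0))
    assert cfg.arrival_rate == 0.0
    assert cfg.background_rate > SimConfig().background_rate  # released dye glow
    for s in range(5):
        trace, truth = simulate_trace(dataclasses.replace(cfg, seed=s))
        assert truth == []
        assert events(trace, 10.0) == 0


def test_unknown_scenario_rejected():
    with pytest.raises(ValueError):
        make_scenario("lysed", SimConfig())


def test_detected_events_monotone_in_permeabilized_fraction():
    base = SimConfig(duration_s=10.0)
    mean_ev = []
    for frac in (0.0, 0.3, 1.0):
        cfg = dataclasses.replace(base, permeabilized_fraction=frac)
        mean_ev.append(
            np.mean(
                [
                    events(simulate_trace(dataclasses.replace(cfg, seed=s))[0], 10.0)
                    for s in range(10)
                ]
            )
        )
    assert mean_ev[0] <= mean_ev[1] <= mean_ev[2]


def test_equal_brightness_states_hide_permeabilization():
    # when Ca2+ binding confers no brightness change the permeabilized and
    # blank scenarios are statistically indistinguishable
    base = SimConfig(duration_s=10.0, brightness_dark=5e3, brightness_bright=5.001e3)
    ev = {
        frac: [
            events(
                simulate_trace(
                    dataclasses.replace(base, permeabilized_fraction=frac, seed=s)
                )[0],
                10.0,
            )
            for s in range(10)
        ]
        for frac in (0.0, 1.0)
    }
    # both regimes sit far below threshold; identical zero event counts
    assert np.mean(ev[0.0]) == pytest.approx(np.mean(ev[1.0]), abs=1.0)


def test_dose_config_composes_baseline_and_hill():
    base = SimConfig()
    c0 = dose_config(base, 0.0, 0.010, 1.0)
    assert c0.permeabilized_fraction == pytest.approx(0.02)
    cmid = dose_config(base, 0.010, 0.010, 1.0)
    assert cmid.permeabilized_fraction == pytest.approx(0.02 + 0.98 * 0.5)
    chigh = dose_config(base, 1e4, 0.010, 1.0)
    assert chigh.permeabilized_fraction == pytest.approx(1.0, abs=1e-4)
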