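"""Burst counting, normalization, and rebinning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from luvburst import AnalysisConfig, count_events, normalized_response, rebin

from conftest import make_trace


def brute_force_events(counts, threshold, mode):
    """Independent oracle: explicit scan over bins."""
    n = 0
    prev_above = False
    for c in counts:
        above = c > threshold
        if mode == "per_bin":
            n += above
        else:
            if above and not prev_above:
                n += 1
        prev_above = above
    return n


def cfg(threshold=50.0, n_bins=None, bin_width=1e-4, mode="per_excursion"):
    return AnalysisConfig(
        threshold=threshold,
        window_s=n_bins * bin_width,
        burst_definition=mode,
    )


def test_all_zero_trace_has_no_events():
    tr = make_trace([0] * 100)
    assert count_events(tr, cfg(n_bins=100)).n_events == 0


def test_hand_enumerated_excursions_and_bins():
    tr = make_trace([0, 60, 70, 0, 0, 55, 0])
    assert count_events(tr, cfg(n_bins=7)).n_events == 2
    assert count_events(tr, cfg(n_bins=7, mode="per_bin")).n_events == 3


def test_single_run_counts_once_per_excursion():
    tr = make_trace([51] * 20)
    assert count_events(tr, cfg(threshold=50, n_bins=20)).n_events == 1
    assert count_events(tr, cfg(threshold=50, n_bins=20, mode="per_bin")).n_events == 20


def test_threshold_is_strict():
    tr = make_trace([50, 51])
    assert count_events(tr, cfg(threshold=50, n_bins=2)).n_events == 1


def test_window_longer_than_trace_rejected():
    tr = make_trace([0] * 10)
    with pytest.raises(ValueError):
        count_events(tr, AnalysisConfig(window_s=1.0))


def test_empty_trace_rejected():
    with pytest.raises(ValueError):
        make_trace([])  # zero-length trace cannot satisfy duration invariant


def test_counting_analyzes_first_window_only():
    counts = [0] * 10 + [99] * 5
    tr = make_trace(counts)
    assert count_events(tr, cfg(n_bins=10)).n_events == 0
    assert count_events(tr, cfg(n_bins=15)).n_events == 1


def test_matches_brute_force_oracle_on_random_traces(rng):
    for _ in range(1000):
        n = int(rng.integers(1, 60))
        counts = rng.integers(0, 8, size=n)
        thr = int(rng.integers(1, 7))
        tr = make_trace(counts)
        for mode in ("per_excursion", "per_bin"):
            got = count_events(tr, cfg(threshold=thr, n_bins=n, mode=mode)).n_events
            assert got == brute_force_events(counts, thr, mode)


@settings(deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=120), min_size=1, max_size=200),
    st.integers(min_value=1, max_value=100),
)
def test_excursions_never_exceed_suprathreshold_bins(counts, thr):
    tr = make_trace(counts)
    per_exc = count_events(tr, cfg(threshold=thr, n_bins=len(counts))).n_events
    per_bin = count_events(
        tr, cfg(threshold=thr, n_bins=len(counts), mode="per_bin")
    ).n_events
    assert per_exc <= per_bin <= len(counts)


@settings(deadline=None)
@given(
    st.lists(st.integers(min_value=0, max_value=120), min_size=1, max_size=200),
    st.integers(min_value=1, max_value=99),
)
def test_per_bin_count_non_increasing_in_threshold(counts, thr):
    # strict monotonicity in threshold holds per bin; per excursion a higher
    # threshold can split one burst into two, so only the per-bin bound is a law
    tr = make_trace(counts)
    lo = count_events(tr, cfg(threshold=thr, n_bins=len(counts), mode="per_bin")).n_events
    hi = count_events(tr, cfg(threshold=thr + 1, n_bins=len(counts), mode="per_bin")).n_events
    assert hi <= lo


def test_normalization_anchors():
    assert normalized_response(570, 570, 3200).value == 0.0
    assert normalized_response(3200, 570, 3200).value == 1.0
    assert normalized_response(1885, 570, 3200).value == pytest.approx(0.5)


def test_normalization_sub_blank_is_negative():
    # samples that suppress events below the blank map to negative values
    f_min, f_max = 570, 3200
    f_sample = f_min - 0.2 * (f_max - f_min)
    assert normalized_response(f_sample, f_min, f_max).value == pytest.approx(-0.2)


def test_normalization_refuses_equal_anchors():
    with pytest.raises(ValueError):
        normalized_response(100, 50, 50)


@given(
    st.integers(min_value=0, max_value=5000),
    st.integers(min_value=0, max_value=5000),
    st.integers(min_value=0, max_value=5000),
    st.integers(min_value=1, max_value=1000),
)
def test_normalization_shift_invariance(f, fmin, fmax, shift):
    # adding the same constant to all three counts leaves the value unchanged
    if fmax == fmin:
        return
    a = normalized_response(f, fmin, fmax).value
    b = normalized_response(f + shift, fmin + shift, fmax + shift).value
    assert a == pytest.approx(b, abs=1e-12)


def test_rebin_identity_and_pairwise_sum():
    tr = make_trace([1, 2, 3, 4])
    same = rebin(tr, 1)
    np.testing.assert_array_equal(same.counts, tr.counts)
    half = rebin(tr, 2)
    np.testing.assert_array_equal(half.counts, [3, 7])
    assert half.bin_width_s == pytest.approx(2 * tr.bin_width_s)


@given(st.lists(st.integers(min_value=0, max_value=1000), min_size=1, max_size=60))
def test_rebin_conserves_photons(counts):
    tr = make_trace(counts)
    for factor in range(1, len(counts) + 1):
        if len(counts) % factor == 0:
            assert rebin(tr, factor).total_photons == tr.total_photons


def test_rebin_rejects_non_divisor():
    with pytest.raises(ValueError):
        rebin(make_trace([1, 2, 3]), 2)
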