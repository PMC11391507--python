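"""Burst / episode detection against brute-force oracles and hand cases."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from burstkit.detection import (
    DetectionError,
    DetectionParams,
    analyze_recording,
    detect_bursts,
    detect_episodes,
    estimate_threshold,
    exclude_channels,
    filter_network_bursts,
    pool_spikes,
)
from burstkit.synthetic import SyntheticConfig, generate_culture

from conftest import make_burst, make_recording
from oracles import episode_closure_oracle, window_union_oracle


# ---------------------------------------------------------------------------
# pooling
# ---------------------------------------------------------------------------


def test_pool_spikes_merges_channels():
    rec = make_recording({"a": [0.1, 0.3], "b": [0.2]})
    assert pool_spikes(rec).tolist() == [0.1, 0.2, 0.3]
    single = make_recording({"a": [0.5, 0.7, 0.9]})
    assert pool_spikes(single).tolist() == [0.5, 0.7, 0.9]


def test_pool_spikes_equals_full_sort(rng):
    spikes = {f"c{i}": np.sort(rng.uniform(0, 100, 100)) for i in range(3)}
    rec = make_recording(spikes, duration=100.0)
    pooled = pool_spikes(rec)
    assert pooled.size == 300
    expected = np.sort(np.concatenate(list(spikes.values())))
    np.testing.assert_array_equal(pooled, expected)


def test_pool_spikes_empty_subset_errors():
    rec = make_recording({"a": [0.1]})
    with pytest.raises(DetectionError, match="no channels selected"):
        pool_spikes(rec, channel_subset=[])


# ---------------------------------------------------------------------------
# threshold estimation
# ---------------------------------------------------------------------------


def _bimodal_train(n_bursts=50, spikes_per_burst=12, within_isi=0.002, gap=2.0):
    t = []
    start = 0.0
    for _ in range(n_bursts):
        t.extend(start + np.arange(spikes_per_burst) * within_isi)
        start += gap
    return np.array(t)


def test_threshold_falls_in_the_empty_valley():
    """Well-separated within-/between-burst spans: T lands between them."""
    pooled = _bimodal_train()
    params = DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=1)
    isi = estimate_threshold(pooled, params)
    assert 0.05 < isi.threshold < 1.0
    spans = pooled[9:] - pooled[:-9]
    within = spans[spans < 0.05]
    between = spans[spans > 1.0]
    assert within.max() < isi.threshold < between.min()


def test_threshold_constant_isi_errors():
    pooled = np.arange(100) * 0.01
    params = DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=1)
    with pytest.raises(DetectionError, match="no local minimum"):
        estimate_threshold(pooled, params)


def test_threshold_override_bypasses_estimation():
    pooled = np.arange(100) * 0.01  # degenerate data: estimation would fail
    params = DetectionParams(
        n_spikes=10, min_total_spikes=10, min_channels=1, threshold_override=0.2
    )
    isi = estimate_threshold(pooled, params)
    assert isi.threshold == 0.2
    assert isi.minima == []


def test_threshold_insufficient_spikes_errors():
    params = DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=1)
    with pytest.raises(DetectionError, match="insufficient spikes"):
        estimate_threshold(np.arange(15) * 0.1, params)


def test_threshold_probabilities_sum_to_one():
    isi = estimate_threshold(
        _bimodal_train(), DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=1)
    )
    assert abs(isi.probabilities.sum() - 1.0) < 1e-9
    assert isi.threshold in isi.minima


def test_threshold_separates_generator_timescales():
    """On generated data with well-separated timescales the threshold sits
    strictly between the within-burst and between-burst N-spans."""
    cfg = SyntheticConfig.culture(
        burst_interval_mean=30.0,
        burst_duration_mean=0.5,
        background_rate=0.02,
        total_duration=3600.0,
        drug_onset=3600.0,
        seed=7,
    )
    rec, truth = generate_culture(cfg)
    pooled = pool_spikes(rec)
    params = DetectionParams.culture()
    isi = estimate_threshold(pooled, params)
    n = params.n_spikes
    spans = pooled[n - 1 :] - pooled[: -(n - 1)]
    starts = pooled[: -(n - 1)]
    ends = pooled[n - 1 :]
    within = np.zeros(spans.size, dtype=bool)
    touches = np.zeros(spans.size, dtype=bool)
    for s, e, _ in truth.burst_intervals:
        within |= (starts >= s) & (ends <= e)
        touches |= (ends >= s) & (starts <= e)
    between = ~touches  # windows entirely in interburst time
    assert within.any() and between.any()
    assert spans[within].max() < isi.threshold < spans[between].min()


# ---------------------------------------------------------------------------
# burst detection
# ---------------------------------------------------------------------------


def test_detect_bursts_two_separated_bursts():
    burst = np.arange(10) * 0.010
    pooled = np.concatenate((burst, 5.0 + burst))
    out = detect_bursts(pooled, threshold=0.2, n_spikes=10)
    assert out.shape == (2, 2)
    np.testing.assert_allclose(out[:, 1] - out[:, 0], [0.09, 0.09])


def test_detect_bursts_lengthens_while_next_window_qualifies():
    # spikes 1-10 span 200 ms and spikes 2-11 span 180 ms: one 11-spike burst
    t = np.concatenate(([0.0], 0.025 + np.arange(9) * 0.0194, [0.205]))
    assert t[9] - t[0] <= 0.2 and t[10] - t[1] <= 0.2
    out = detect_bursts(t, threshold=0.2, n_spikes=10)
    assert out.shape == (1, 2)
    assert out[0, 0] == t[0] and out[0, 1] == t[10]


def test_detect_bursts_empty_and_short_input():
    assert detect_bursts(np.array([]), 0.1, 5).size == 0
    assert detect_bursts(np.arange(3) * 0.01, 0.1, 5).size == 0


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    raw=st.lists(st.integers(0, 2000), min_size=0, max_size=80),
    n=st.integers(2, 6),
    t_scale=st.integers(1, 400),
)
def test_detect_bursts_equals_window_enumeration_oracle(raw, n, t_scale):
    """The vectorized detector is identical to brute-force enumeration of
    all N-spike windows followed by interval union, ties included."""
    pooled = np.sort(np.array(raw, dtype=float)) / 100.0
    threshold = t_scale / 100.0
    fast = detect_bursts(pooled, threshold, n)
    slow = window_union_oracle(pooled, threshold, n)
    np.testing.assert_array_equal(fast, slow)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(raw=st.lists(st.integers(0, 2000), min_size=12, max_size=80), n=st.integers(2, 6))
def test_spikes_in_bursts_monotone_in_threshold(raw, n):
    pooled = np.sort(np.array(raw, dtype=float)) / 100.0

    def assigned(threshold):
        total = 0
        for s, e in detect_bursts(pooled, threshold, n):
            total += np.searchsorted(pooled, e, "right") - np.searchsorted(pooled, s, "left")
        return total

    counts = [assigned(t) for t in (0.05, 0.2, 1.0, 5.0)]
    assert counts == sorted(counts)


def test_detected_bursts_disjoint_and_sorted(rng):
    pooled = np.sort(rng.uniform(0, 50, 400))
    out = detect_bursts(pooled, 0.3, 5)
    assert np.all(out[1:, 0] > out[:-1, 1])
    assert np.all(out[:, 1] >= out[:, 0])


# ---------------------------------------------------------------------------
# network filtering
# ---------------------------------------------------------------------------


def _multi_channel_burst_recording():
    # one candidate with 12 spikes on 1 channel, one with 12 spikes on 6 channels
    single = {"a": np.arange(12) * 0.01}
    spread = {c: 10.0 + np.arange(2) * 0.01 + i * 0.001 for i, c in enumerate("abcdef")}
    spikes = {c: np.sort(np.concatenate((single.get(c, []), spread.get(c, [])))) for c in "abcdef"}
    return make_recording(spikes, duration=20.0)


def test_network_filter_rejects_single_channel_candidate():
    rec = _multi_channel_burst_recording()
    params = DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=5)
    candidates = np.array([[0.0, 0.11], [10.0, 10.016]])
    bursts = filter_network_bursts(candidates, rec, params)
    assert len(bursts) == 1
    assert bursts[0].start == 10.0
    assert bursts[0].n_channels == 6
    assert bursts[0].n_spikes == 12


def test_network_filter_counts_match_recount(rng):
    spikes = {f"c{i}": np.sort(rng.uniform(0, 30, 200)) for i in range(4)}
    rec = make_recording(spikes, duration=30.0)
    candidates = np.array([[2.0, 3.0], [10.0, 12.5], [20.0, 20.0]])
    bursts = filter_network_bursts(
        candidates, rec, DetectionParams(n_spikes=2, min_total_spikes=1, min_channels=1)
    )
    for b in bursts:
        for c, t in spikes.items():
            assert b.spikes_per_channel[c] == int(np.sum((t >= b.start) & (t <= b.end)))


def test_network_filter_monotone_in_min_channels(rng):
    spikes = {f"c{i}": np.sort(rng.uniform(0, 30, 150)) for i in range(6)}
    rec = make_recording(spikes, duration=30.0)
    candidates = np.column_stack((np.arange(0, 28, 3.0), np.arange(0, 28, 3.0) + 1.0))
    counts = []
    for mc in (1, 3, 5, 7):
        params = DetectionParams(n_spikes=2, min_total_spikes=1, min_channels=mc)
        counts.append(len(filter_network_bursts(candidates, rec, params)))
    assert counts == sorted(counts, reverse=True)


# ---------------------------------------------------------------------------
# channel exclusion
# ---------------------------------------------------------------------------


def test_exclusion_drops_silent_and_noise_channels():
    rng = np.random.default_rng(0)
    duration = 200.0
    burst_starts = np.arange(0, duration - 1, 10.0)
    good = {}
    for i, c in enumerate("abcdef"):
        # every good channel fires 5 spikes inside every burst
        good[c] = np.sort(
            np.concatenate([s + rng.uniform(0, 0.1, 5) for s in burst_starts])
        )
    good["noise"] = np.sort(rng.uniform(0, duration, 1000))  # constantly active
    good["silent"] = np.array([])
    rec = make_recording(good, duration=duration)
    bursts = filter_network_bursts(
        np.column_stack((burst_starts, burst_starts + 0.1)),
        rec,
        DetectionParams(n_spikes=10, min_total_spikes=10, min_channels=5),
    )
    kept = exclude_channels(rec, bursts, DetectionParams.culture())
    assert set(kept.channels) == set("abcdef")


def test_exclusion_requires_some_survivor():
    rec = make_recording({"silent": [], "quiet": [50.0]}, duration=100.0)
    bursts = [make_burst(0.0, 1.0, {"silent": 0, "quiet": 0})]
    with pytest.raises(DetectionError, match="no channels survive"):
        exclude_channels(rec, bursts, DetectionParams.culture())


def test_participating_channel_retained_on_generator_output():
    cfg = SyntheticConfig.culture(total_duration=1800.0, drug_onset=1800.0, seed=11)
    rec, truth = generate_culture(cfg)
    result = analyze_recording(rec, DetectionParams.culture())
    # every generated channel joins bursts regularly: none may be excluded
    assert set(result.recording.channels) == set(rec.channels)


# ---------------------------------------------------------------------------
# episodes
# ---------------------------------------------------------------------------


def test_episode_groups_bursts_within_gap():
    bursts = [make_burst(s, s + 6.0) for s in np.arange(0, 40, 8.0)]  # spans 0..38
    eps = detect_episodes(bursts, gap_threshold=10.0, duration_range=(20.0, 100.0))
    assert len(eps) == 1
    assert eps[0].duration == pytest.approx(38.0)
    assert len(eps[0].bursts) == 5


def test_single_short_burst_is_no_episode():
    eps = detect_episodes([make_burst(0.0, 0.1)], 10.0, (20.0, 100.0))
    assert eps == []


@settings(derandomize=True, max_examples=80, deadline=None)
@given(
    gaps=st.lists(st.integers(1, 300), min_size=1, max_size=15),
    durs=st.lists(st.integers(1, 80), min_size=1, max_size=15),
    gap_threshold=st.integers(5, 150),
)
def test_episode_grouping_equals_transitive_closure(gaps, durs, gap_threshold):
    n = min(len(gaps), len(durs))
    start = 0.0
    intervals = []
    for g, d in zip(gaps[:n], durs[:n]):
        start += g / 10.0
        intervals.append((start, start + d / 10.0))
        start += d / 10.0
    bursts = [make_burst(s, e) for s, e in intervals]
    groups = episode_closure_oracle(intervals, gap_threshold / 10.0)
    expected = [
        (intervals[g[0]][0], intervals[g[-1]][1])
        for g in groups
        if 0.0 <= intervals[g[-1]][1] - intervals[g[0]][0] <= 1e9
    ]
    eps = detect_episodes(bursts, gap_threshold / 10.0, (0.0, 1e9))
    assert [(e.start, e.end) for e in eps] == expected


def test_detection_params_warns_on_weak_window():
    with pytest.warns(UserWarning, match="weaker"):
        DetectionParams(n_spikes=4, min_total_spikes=10, min_channels=5)
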