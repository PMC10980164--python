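"""Bouts, microarousals, consolidated NREM spans and behavioural metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from murisleep import (
    Hypnogram,
    bout_duration_distribution,
    consolidate_nrem,
    detect_bouts,
    detect_microarousals,
    episode_stats,
    sor_metrics,
    state_percentages,
)


def hyp(spec: str) -> Hypnogram:
    """'N*24 W*4 N*28' -> hypnogram; bare letters count as one epoch."""
    states = []
    for token in spec.split():
        if "*" in token:
            s, k = token.split("*")
            states.extend([s] * int(k))
        else:
            states.append(token)
    return Hypnogram(states=np.array(states))


state_lists = st.lists(st.sampled_from(["W", "N", "R"]), min_size=1, max_size=120)


class TestDetectBouts:
    def test_small_example(self):
        bouts = detect_bouts(hyp("N N W R"))
        assert [(b.state, b.duration_s) for b in bouts] == [("N", 5.0), ("W", 2.5), ("R", 2.5)]

    def test_all_one_state(self):
        assert len(detect_bouts(hyp("N*40"))) == 1

    @settings(max_examples=200, deadline=None)
    @given(states=state_lists)
    def test_matches_run_length_encoding(self, states):
        bouts = detect_bouts(Hypnogram(states=np.array(states)))
        # brute-force RLE
        rle = []
        for s in states:
            if rle and rle[-1][0] == s:
                rle[-1][1] += 1
            else:
                rle.append([s, 1])
        assert [(b.state, b.n_epochs) for b in bouts] == [(s, n) for s, n in rle]
        # partition: concatenation reconstructs the hypnogram
        rebuilt = [b.state for b in bouts for _ in range(b.n_epochs)]
        assert rebuilt == states


class TestDetectMicroarousals:
    def test_twenty_second_wake_is_ma(self):
        mas = detect_microarousals(hyp("N N W*8 N"))
        assert len(mas) == 1
        assert mas[0].duration_s == 20.0

    def test_wake_over_bound_is_not_ma(self):
        assert detect_microarousals(hyp("N W*9 N")) == []  # 22.5 s

    def test_edge_flanked_wake_is_not_ma(self):
        assert detect_microarousals(hyp("W*4 N*10")) == []
        assert detect_microarousals(hyp("N*10 W*4")) == []

    def test_rem_flanked_wake_is_not_ma(self):
        assert detect_microarousals(hyp("R W*4 N*10")) == []

    @settings(max_examples=100, deadline=None)
    @given(states=state_lists, ma_max=st.sampled_from([10.0, 20.0, 30.0]))
    def test_matches_brute_force_and_monotonicity(self, states, ma_max):
        h = Hypnogram(states=np.array(states))
        mas = detect_microarousals(h, max_dur_s=ma_max)
        # brute force: scan every wake run
        expected = []
        i = 0
        while i < len(states):
            if states[i] == "W":
                j = i
                while j < len(states) and states[j] == "W":
                    j += 1
                dur = (j - i) * 2.5
                if dur <= ma_max and i > 0 and j < len(states) \
                        and states[i - 1] == "N" and states[j] == "N":
                    expected.append((i * 2.5, dur))
                i = j
            else:
                i += 1
        assert [(m.start_s, m.duration_s) for m in mas] == expected
        # widening the bound never removes MAs
        assert len(detect_microarousals(h, max_dur_s=ma_max + 10)) >= len(mas)


class TestConsolidateNrem:
    def test_bridged_span_includes_ma_time(self):
        bouts = consolidate_nrem(hyp("N*24 W*4 N*28"))  # 60 s + 10 s MA + 70 s
        assert len(bouts) == 1
        assert bouts[0].span_s == 140.0
        assert len(bouts[0].ma_events) == 1

    def test_long_wake_breaks_span(self):
        assert consolidate_nrem(hyp("N*24 W*12 N*28")) == []  # 30 s wake, fragments short

    def test_plain_long_nrem(self):
        bouts = consolidate_nrem(hyp("N*52"))  # 130 s
        assert len(bouts) == 1
        assert bouts[0].ma_events == ()

    @settings(max_examples=100, deadline=None)
    @given(states=state_lists)
    def test_spans_disjoint_ordered_and_pure(self, states):
        h = Hypnogram(states=np.array(states))
        spans = consolidate_nrem(h, min_span_s=0.0)
        prev_end = -1.0
        for sp in spans:
            assert sp.start_s >= prev_end
            prev_end = sp.end_s
            # removing MA time leaves only NREM epochs
            for e in range(int(sp.start_s / 2.5), int(sp.end_s / 2.5)):
                t = e * 2.5
                in_ma = any(m.start_s <= t < m.end_s for m in sp.ma_events)
                assert states[e] == ("W" if in_ma else "N")


class TestStatePercentages:
    def test_small_example(self):
        pct = state_percentages(hyp("N N W R"))
        assert pct == {"W": 25.0, "N": 50.0, "R": 25.0}

    def test_all_wake(self):
        assert state_percentages(hyp("W*8"))["W"] == 100.0

    def test_empty_interval_rejected(self):
        with pytest.raises(ValueError, match="no epochs"):
            state_percentages(hyp("N N"), interval=(100.0, 200.0))

    @settings(max_examples=100, deadline=None)
    @given(states=state_lists)
    def test_matches_counting_oracle(self, states):
        pct = state_percentages(Hypnogram(states=np.array(states)))
        for s in "WNR":
            assert pct[s] == pytest.approx(100.0 * states.count(s) / len(states))
        assert sum(pct.values()) == pytest.approx(100.0)


class TestEpisodeStats:
    def test_mean_and_frequency(self):
        bouts = detect_bouts(hyp("N*24 W*12 N*48"))  # N bouts of 60 s and 120 s
        stats = episode_stats(bouts, "N", total_hours=1.0)
        assert stats["mean_duration_s"] == pytest.approx(90.0)
        assert stats["frequency_per_h"] == pytest.approx(2.0)

    def test_absent_state(self):
        stats = episode_stats(detect_bouts(hyp("N*10")), "R", total_hours=1.0)
        assert math.isnan(stats["mean_duration_s"])
        assert stats["frequency_per_h"] == 0.0


class TestBoutDurationDistribution:
    def test_counting(self):
        bouts = detect_bouts(hyp("N*4 W N*4 W N*80"))  # N durations 10, 10, 200 s
        props = bout_duration_distribution(bouts, "N", [0.0, 64.0, np.inf])
        np.testing.assert_allclose(props, [2 / 3, 1 / 3])

    def test_empty(self):
        np.testing.assert_allclose(
            bout_duration_distribution([], "N", [0.0, 64.0, np.inf]), [0.0, 0.0]
        )

    def test_all_in_one_bin(self):
        bouts = detect_bouts(hyp("N*4 W N*4"))
        props = bout_duration_distribution(bouts, "N", [0.0, 64.0, np.inf])
        np.testing.assert_allclose(props, [1.0, 0.0])


class TestSorMetrics:
    def test_printed_formulas(self):
        res = sor_metrics(30.0, 10.0)
        assert res.preference_pct == pytest.approx(75.0)
        assert res.discrimination_ratio == pytest.approx(0.5)
        assert not res.excluded

    def test_symmetry(self):
        res = sor_metrics(10.0, 10.0)
        assert res.preference_pct == pytest.approx(50.0)
        assert res.discrimination_ratio == pytest.approx(0.0)

    def test_low_exploration_excluded(self):
        assert sor_metrics(0.5, 1.0).excluded

    def test_zero_exploration_undefined(self):
        res = sor_metrics(0.0, 0.0)
        assert res.excluded and math.isnan(res.preference_pct)

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            sor_metrics(-1.0, 2.0)
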