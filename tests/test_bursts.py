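"""Max-interval burst detection, activity metrics and network qualification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from astrocrosstalk.bursts import (
    Burst,
    BurstParams,
    burst_features,
    burst_rate,
    detect_bursts,
    normalize_to_baseline,
    qualify_network,
    spike_rate,
)
from astrocrosstalk.mea import SpikeTrain
from helpers import brute_force_bursts, random_spike_train

MS = 1e-3


def as_tuples(bursts):
    return [(b.start, b.end, b.n_spikes) for b in bursts]


class TestDetectBursts:
    def test_empty_train(self):
        assert detect_bursts(np.empty(0)) == ()

    def test_regular_5ms_train_is_one_burst(self):
        t = np.array([0, 5, 10, 15, 20, 25]) * MS
        bursts = detect_bursts(t)
        assert as_tuples(bursts) == [(0.0, pytest.approx(0.025), 6)]

    def test_start_isi_opens_but_end_isi_closes(self):
        # 15 ms ISIs open candidates (<= 20 ms) but exceed the 10 ms
        # continuation limit, so every candidate dies at 2 spikes < 4.
        t = np.array([0, 15, 30, 45]) * MS
        assert detect_bursts(t) == ()

    def test_boundary_isis_inclusive(self):
        # An ISI exactly equal to max_isi_start opens a burst and one exactly
        # equal to max_isi_end continues it.  Binary-exact times and
        # parameters keep the boundary comparison free of float rounding.
        params = BurstParams(max_isi_start=1.0, max_isi_end=0.5, min_ibi=0.5,
                             min_duration=1.0, min_spikes=4)
        t = np.array([0.0, 1.0, 1.5, 2.0, 2.5])
        bursts = detect_bursts(t, params)
        assert as_tuples(bursts) == [(0.0, 2.5, 5)]
        # Nudging the opening ISI past the boundary drops the first spike:
        # the burst then opens at the second spike instead.
        nudged = detect_bursts(t + np.array([-1e-9, 0, 0, 0, 0]), params)
        assert as_tuples(nudged) == [(1.0, 2.5, 4)]

    def test_too_short_burst_discarded(self):
        # 4 spikes at 5 ms spacing: duration 15 ms < 20 ms minimum.
        t = np.array([0, 5, 10, 15]) * MS
        assert detect_bursts(t) == ()

    def test_too_few_spikes_discarded(self):
        t = np.array([0, 10, 20]) * MS  # duration fine only with >= 4 spikes
        assert detect_bursts(t) == ()

    def test_merge_is_vacuous_at_default_parameters(self, rng):
        # With max_isi_end == min_ibi any inter-candidate gap is an ISI
        # > max_isi_end >= min_ibi, so merging can never fire: detection on
        # concatenated bursts equals per-burst detection.
        for _ in range(200):
            t = random_spike_train(rng)
            got = as_tuples(detect_bursts(t))
            oracle = brute_force_bursts(t, min_ibi=1e-12)  # merging disabled
            assert got == [tuple(map(pytest.approx, o[:2])) + (o[2],) for o in oracle]

    def test_merge_active_when_min_ibi_exceeds_end_isi(self):
        # Two 5-spike runs 12 ms apart: with min_ibi=15 ms they merge into
        # one 10-spike burst; with the default 10 ms they stay separate.
        t = np.concatenate([np.arange(5) * 5, 32 + np.arange(5) * 5]) * MS
        merged = detect_bursts(t, BurstParams(min_ibi=0.015))
        assert as_tuples(merged) == [(0.0, pytest.approx(0.052), 10)]
        split = detect_bursts(t)
        assert [b.n_spikes for b in split] == [5, 5]

    def test_oracle_equivalence_on_random_trains(self, rng):
        params = BurstParams()
        for _ in range(1000):
            t = random_spike_train(rng)
            got = as_tuples(detect_bursts(t, params))
            exp = brute_force_bursts(t)
            assert len(got) == len(exp)
            for g, e in zip(got, exp):
                assert g[0] == pytest.approx(e[0])
                assert g[1] == pytest.approx(e[1])
                assert g[2] == e[2]

    def test_bursts_ordered_and_disjoint(self, rng):
        for _ in range(100):
            bursts = detect_bursts(random_spike_train(rng))
            for a, b in zip(bursts, bursts[1:]):
                assert a.end < b.start

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0005, max_value=0.05), min_size=0, max_size=60),
           st.floats(min_value=0.005, max_value=0.02))
    def test_raising_end_isi_never_drops_burst_spikes(self, isis, end_isi):
        t = np.cumsum(np.asarray(isis))
        lo = detect_bursts(t, BurstParams(max_isi_end=end_isi))
        hi = detect_bursts(t, BurstParams(max_isi_end=end_isi * 1.5))
        assert sum(b.n_spikes for b in hi) >= sum(b.n_spikes for b in lo)


class TestRates:
    def test_spike_rate_definition(self):
        t = np.linspace(0, 299.9, 600)
        assert spike_rate(t, 300.0) == pytest.approx(2.0)

    def test_spike_rate_empty(self):
        assert spike_rate(np.empty(0)) == 0.0

    def test_spikes_outside_window_ignored(self):
        t = np.concatenate([np.linspace(0, 299, 300), np.linspace(301, 600, 300)])
        assert spike_rate(t, 300.0) == pytest.approx(1.0)

    def test_burst_rate_per_minute(self):
        bursts = [Burst(i * 20.0, i * 20.0 + 0.05, 5) for i in range(15)]
        assert burst_rate(bursts, 300.0) == pytest.approx(3.0)

    def test_burst_rate_empty(self):
        assert burst_rate([], 300.0) == 0.0

    def test_burst_rate_stationary_under_window_doubling(self):
        pattern = [Burst(s, s + 0.05, 4) for s in np.arange(0, 300, 10.0)]
        doubled = pattern + [Burst(b.start + 300, b.end + 300, 4) for b in pattern]
        assert burst_rate(pattern, 300.0) == pytest.approx(burst_rate(doubled, 600.0))


class TestBurstFeatures:
    def test_single_burst_arithmetic(self):
        f = burst_features([Burst(0.0, 0.025, 6)])
        assert f.loc[0, "duration_s"] == pytest.approx(0.025)
        assert f.loc[0, "n_spikes"] == 6
        assert f.loc[0, "intra_rate_hz"] == pytest.approx(240.0)

    def test_mean_of_identical_bursts_is_single_value(self):
        f = burst_features([Burst(0.0, 0.025, 6), Burst(1.0, 1.025, 6)])
        assert f["duration_s"].mean() == pytest.approx(0.025)

    def test_empty_set_flagged_undefined(self):
        f = burst_features([])
        assert len(f) == 0
        assert np.isnan(f["duration_s"].mean())


class TestNormalizeToBaseline:
    @staticmethod
    def _metrics(baseline, later):
        return pd.DataFrame(
            {
                "electrode": ["e"] * 2,
                "timepoint": ["baseline", "4h"],
                "spike_rate_hz": [baseline, later],
                "burst_rate_per_min": [1.0, 1.0],
            }
        )

    def test_threefold_increase(self):
        out = normalize_to_baseline(self._metrics(2.0, 6.0))
        assert out.set_index("timepoint")["fold_spike_rate_hz"]["4h"] == pytest.approx(3.0)
        assert out.set_index("timepoint")["fold_spike_rate_hz"]["baseline"] == pytest.approx(1.0)

    def test_constant_metric_gives_unit_folds(self):
        out = normalize_to_baseline(self._metrics(2.0, 2.0))
        assert np.allclose(out["fold_spike_rate_hz"], 1.0)

    def test_zero_baseline_flagged_nan(self):
        df = pd.concat([self._metrics(0.0, 6.0), self._metrics(1.0, 2.0).assign(electrode="f")])
        out = normalize_to_baseline(df)
        assert out[out["electrode"] == "e"]["fold_spike_rate_hz"].isna().all()
        assert out[out["electrode"] == "f"]["fold_spike_rate_hz"].notna().all()

    def test_all_zero_baseline_errors(self):
        with pytest.raises(ValueError, match="zero"):
            normalize_to_baseline(self._metrics(0.0, 6.0))

    def test_missing_baseline_errors(self):
        df = self._metrics(2.0, 6.0)
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline(df[df["timepoint"] != "baseline"])


def _burst_train(eid, starts, duration=300.0):
    times = np.concatenate([s + np.arange(6) * 0.005 for s in starts]) if len(starts) else np.empty(0)
    return SpikeTrain(eid, times, duration)


class TestQualifyNetwork:
    def test_all_silent_not_qualified(self):
        trains = {f"e{i}": _burst_train(f"e{i}", []) for i in range(12)}
        q = qualify_network(trains)
        assert not q.qualified and q.active_electrodes == ()

    def test_twelve_synchronous_electrodes_qualify(self):
        starts = np.arange(0, 300, 10.0)
        trains = {f"e{i}": _burst_train(f"e{i}", starts) for i in range(12)}
        q = qualify_network(trains)
        assert q.qualified and len(q.active_electrodes) == 12
        assert q.synchrony_index == pytest.approx(1.0)

    def test_exactly_ten_active_among_silent(self):
        starts = np.arange(0, 300, 10.0)
        trains = {f"s{i}": _burst_train(f"s{i}", starts) for i in range(10)}
        trains.update({f"q{i}": _burst_train(f"q{i}", []) for i in range(50)})
        q = qualify_network(trains)
        assert q.qualified and len(q.active_electrodes) == 10

    def test_nine_active_do_not_qualify(self):
        starts = np.arange(0, 300, 10.0)
        trains = {f"s{i}": _burst_train(f"s{i}", starts) for i in range(9)}
        q = qualify_network(trains)
        assert not q.qualified
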