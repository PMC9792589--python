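"""MUA power, event detection, event-triggered averages, and overlap nulls."""

import numpy as np
import pytest

from orgephys.data import EventTrain, Recording
from orgephys.mua import (
    MuaPowerTrace,
    detect_events,
    event_triggered_average,
    evoked_mua_snr,
    mua_power,
    overlap_count,
    overlap_shift_test,
)
from orgephys.preprocess import filter_mua
from orgephys.synth import SpikeSpec, _spike_kernel, default_grid_channels

from conftest import make_single_channel

FS = 20000.0


def mua_noise(rng, dur_s, n_ch=1, sd=5.0):
    """Gaussian noise restricted to the MUA band."""
    raw = Recording(data=rng.standard_normal((n_ch, int(dur_s * FS))) * sd,
                    fs_hz=FS, channels=default_grid_channels()[:n_ch])
    return filter_mua(raw)


def inject_spikes(x, times_s, amp_uv):
    k = amp_uv * _spike_kernel(SpikeSpec(), FS)
    out = x.copy()
    for t in times_s:
        i0 = int(round(t * FS))
        out[i0 : i0 + k.size] += k[: max(0, min(k.size, out.size - i0))]
    return out


class TestMuaPower:
    def test_zero_in_zero_out(self):
        pt = mua_power(make_single_channel(np.zeros(10000), FS))
        np.testing.assert_allclose(pt.values, 0.0)
        assert np.all(pt.values >= 0)

    def test_tone_envelope_matches_rectified_mean(self):
        t = np.arange(int(5 * FS)) / FS
        A = 7.0
        pt = mua_power(make_single_channel(A * np.sin(2 * np.pi * 1000 * t), FS))
        mid = pt.values[0, int(FS) : -int(FS)]
        assert mid.mean() == pytest.approx(2 * A / np.pi, rel=0.02)

    def test_linearity_in_amplitude(self, rng):
        x = filter_mua(Recording(data=rng.standard_normal((1, 40000)) * 3, fs_hz=FS,
                                 channels=default_grid_channels()[:1]))
        p1 = mua_power(x).values
        x2 = x.with_data(x.data * 2)
        p2 = mua_power(x2).values
        np.testing.assert_allclose(p2, 2 * p1, rtol=1e-9)


class TestEvokedSnr:
    def _trace(self, peak_ratio):
        p = np.ones((1, int(10 * FS)))
        for onset in (3.0, 6.0):
            i = int(onset * FS)
            p[0, i : i + 2000] = peak_ratio
        return MuaPowerTrace(values=p, fs_hz=FS)

    @pytest.mark.parametrize("ratio,db", [(1.0, 0.0), (10.0, 10.0)])
    def test_known_ratios(self, ratio, db):
        snr = evoked_mua_snr(self._trace(ratio), [3.0, 6.0])
        assert snr[0] == pytest.approx(db, abs=1e-9)

    def test_zero_baseline_is_error(self):
        p = MuaPowerTrace(values=np.zeros((1, int(5 * FS))), fs_hz=FS)
        with pytest.raises(ValueError, match="baseline"):
            evoked_mua_snr(p, [2.0])


class TestDetectEvents:
    def test_recall_on_injected_large_spikes(self, rng):
        band = mua_noise(rng, 60.0)
        sd = band.data[0].std()
        true_t = np.sort(rng.uniform(0.1, 59.9, 120))
        x = inject_spikes(band.data[0], true_t, 6 * sd)
        tr = detect_events(band.with_data(x[None, :]), k=3.5)[0]
        hits = np.array([np.min(np.abs(tr.event_times_s - t)) < 5e-4 for t in true_t])
        assert hits.mean() >= 0.95

    def test_count_monotone_in_threshold(self, rng):
        band = mua_noise(rng, 30.0)
        counts = [detect_events(band, k=k)[0].n_events for k in (3.0, 3.25, 3.5, 3.75, 4.0)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_noise_crossing_rate_matches_level_crossing_theory(self, rng):
        # Rice rate for the 0.5-3 kHz band: sqrt(m2/m0) ~ 1.9 kHz
        band = mua_noise(rng, 100.0)
        n = detect_events(band, k=3.5)[0].n_events
        expected = 1893.0 * np.exp(-3.5**2 / 2) * 100.0
        assert 0.5 * expected < n < 1.5 * expected

    def test_dead_time_enforced(self, rng):
        band = mua_noise(rng, 30.0)
        times = detect_events(band, k=3.0)[0].event_times_s
        assert np.all(np.diff(times) >= 0.001 - 1e-9)

    def test_flat_channel_warns_and_returns_empty(self):
        rec = Recording(data=np.zeros((1, 10000)), fs_hz=FS,
                        channels=default_grid_channels()[:1])
        with pytest.warns(UserWarning, match="flat"):
            tr = detect_events(rec, k=3.5)[0]
        assert tr.n_events == 0

    def test_threshold_out_of_range_rejected(self, rng):
        band = mua_noise(rng, 1.0)
        with pytest.raises(ValueError):
            detect_events(band, k=2.0)


@pytest.fixture(scope="module")
def eta_setup():
    rng = np.random.default_rng(77)
    band = mua_noise(rng, 60.0, n_ch=16)
    sd = band.data[0].std()
    true_t = np.sort(rng.uniform(0.1, 59.9, 500))
    data = band.data.copy()
    data[0] = inject_spikes(data[0], true_t, 8 * sd)
    data[1] = data[0]  # duplicated channel: spread should be visible
    rec = band.with_data(data)
    trains = detect_events(rec, k=4.0)
    eta = event_triggered_average(trains, rec, target_channel=0)
    return eta, sd


class TestEventTriggeredAverage:
    def test_target_shows_lag_zero_deflection(self, eta_setup):
        eta, sd = eta_setup
        i0 = np.argmin(np.abs(eta.t_axis_s))
        assert eta.mean[0, i0] < -3 * sd

    def test_duplicate_channel_shows_spread(self, eta_setup):
        eta, sd = eta_setup
        i0 = np.argmin(np.abs(eta.t_axis_s))
        assert eta.mean[1, i0] < -3 * sd

    def test_independent_channels_average_to_zero(self, eta_setup):
        eta, sd = eta_setup
        bound = 4.5 * sd / np.sqrt(eta.n_events)
        frac_inside = np.mean(np.abs(eta.mean[2:]) < bound)
        assert frac_inside > 0.99

    def test_edge_events_skipped(self, rng):
        band = mua_noise(rng, 2.0)
        trains = [EventTrain(0, np.array([0.0002, 1.0, 1.99998]))]
        eta = event_triggered_average(trains, band, 0)
        assert eta.n_events == 1
        assert eta.n_skipped == 2


class TestOverlap:
    def test_identical_trains_count_all_bins(self):
        t = np.array([0.0105, 0.5002, 1.25, 3.0001])
        a = EventTrain(0, t)
        assert overlap_count(a, EventTrain(1, t)) == 4

    def test_disjoint_trains_zero(self):
        a = EventTrain(0, np.array([0.01, 0.5]))
        b = EventTrain(1, np.array([0.1, 0.7]))
        assert overlap_count(a, b) == 0

    def test_symmetric_and_translation_invariant(self, rng):
        ta = np.sort(rng.uniform(0, 10, 50))
        tb = np.sort(rng.uniform(0, 10, 50))
        a, b = EventTrain(0, ta), EventTrain(1, tb)
        assert overlap_count(a, b) == overlap_count(b, a)
        # whole-bin translation leaves the count unchanged
        a2 = EventTrain(0, ta + 0.004)
        b2 = EventTrain(1, tb + 0.004)
        assert overlap_count(a2, b2) == overlap_count(a, b)

    def test_independent_poisson_expectation(self, rng):
        # expected co-occupancy: n_bins * p_a * p_b for independent binary bins
        T, rate = 600.0, 2.0
        counts = []
        for _ in range(30):
            a = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            b = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
            counts.append(overlap_count(EventTrain(0, a), EventTrain(1, b)))
        n_bins = T / 0.001
        p = rate * T / n_bins  # occupancy probability per bin (sparse regime)
        expected = n_bins * p * p
        assert np.mean(counts) == pytest.approx(expected, rel=0.35)


class TestOverlapShiftTest:
    def test_self_overlap_is_maximally_significant(self, rng):
        t = np.sort(rng.uniform(0, 100, 200))
        a = EventTrain(0, t)
        res = overlap_shift_test(a, EventTrain(1, t), duration_s=100.0,
                                 n_shifts=1000, seed=0)
        assert res["observed"] == 200
        assert res["p_value"] <= 2 / 1000

    def test_injected_cooccurrence_detected(self, rng):
        T = 300.0
        a = np.sort(rng.uniform(1, T - 1, 600))
        shared = rng.choice(a, size=120, replace=False)
        b = np.sort(np.concatenate([rng.uniform(1, T - 1, 480), shared + 2e-4]))
        res = overlap_shift_test(EventTrain(0, a), EventTrain(1, b), duration_s=T,
                                 n_shifts=2000, seed=1)
        assert res["p_value"] < 0.01

    def test_empty_train_warns_p_one(self):
        a = EventTrain(0, np.array([1.0, 2.0]))
        with pytest.warns(UserWarning, match="empty"):
            res = overlap_shift_test(a, EventTrain(1, np.array([])), duration_s=10.0)
        assert res["p_value"] == 1.0

    def test_short_recording_rejected(self):
        a = EventTrain(0, np.array([0.5]))
        with pytest.raises(ValueError, match="too short"):
            overlap_shift_test(a, a, duration_s=1.5)
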