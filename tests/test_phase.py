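"""Multitaper phase estimation and spike-field phase-locking statistics."""

import numpy as np
import pytest

from orgephys.data import EventTrain, Recording, StimulusProtocol
from orgephys.phase import (
    multitaper_phase,
    plv,
    plv_bootstrap,
    plv_compare,
    plv_spatial_map,
    rayleigh_test,
    split_events_by_stimulus,
)
from orgephys.synth import default_grid_channels, expected_plv, sample_locked_spikes

from conftest import make_single_channel

FS = 1000.0


def tone_field(f0=5.0, dur=100.0, phi0=0.0, step_s=0.01):
    t = np.arange(int(dur * FS)) / FS
    rec = make_single_channel(np.cos(2 * np.pi * f0 * t + phi0), FS)
    return multitaper_phase(rec, freqs_hz=np.arange(1.0, 251.0), step_s=step_s)


@pytest.fixture(scope="module")
def field_5hz():
    return tone_field()


class TestMultitaperPhase:
    def test_tone_phase_tracks_window_center(self, field_5hz):
        pf = field_5hz
        i5 = int(np.argmin(np.abs(pf.freqs_hz - 5.0)))
        pred = np.mod(2 * np.pi * 5.0 * pf.t_axis_s + np.pi, 2 * np.pi) - np.pi
        err = np.angle(np.exp(1j * (pf.phases[0, i5] - pred)))
        assert np.max(np.abs(err)) < 0.05

    def test_delay_shifts_phase_by_minus_2pi_f_tau(self):
        tau = 0.05
        pf0 = tone_field(phi0=0.0, dur=30.0)
        pfd = tone_field(phi0=-2 * np.pi * 5.0 * tau, dur=30.0)  # x(t - tau)
        i5 = int(np.argmin(np.abs(pf0.freqs_hz - 5.0)))
        diff = np.angle(np.exp(1j * (pfd.phases[0, i5] - pf0.phases[0, i5])))
        assert np.allclose(diff, -2 * np.pi * 5.0 * tau, atol=0.05)

    def test_white_noise_phases_uniform(self, rng):
        rec = make_single_channel(rng.standard_normal(int(60 * FS)), FS)
        pf = multitaper_phase(rec, freqs_hz=np.arange(5.0, 100.0, 10.0), step_s=1.0)
        # non-overlapping windows: phases at each frequency should be uniform
        ps = [rayleigh_test(pf.phases[0, i])["p"] for i in range(pf.freqs_hz.size)]
        assert np.mean(np.asarray(ps) > 0.05) >= 0.9

    def test_taper_count_constraint(self):
        rec = make_single_channel(np.zeros(2000), FS)
        with pytest.raises(ValueError, match="2\\*TW-1"):
            multitaper_phase(rec, time_bandwidth=3.0, n_tapers=7)

    def test_phase_range_and_window_geometry(self, field_5hz):
        pf = field_5hz
        assert np.nanmax(np.abs(pf.phases)) <= np.pi
        assert pf.t_axis_s[0] == pytest.approx((pf.window_s * FS - 1) / (2 * FS))
        assert np.allclose(np.diff(pf.t_axis_s), pf.step_s)


class TestPlv:
    def test_identical_phases_give_one(self):
        assert plv([0.7] * 20) == pytest.approx(1.0)

    def test_antipodal_phases_cancel(self):
        assert plv([0.0, np.pi]) == pytest.approx(0.0, abs=1e-12)

    def test_von_mises_sample_matches_bessel_ratio(self, rng):
        ph = rng.vonmises(0.3, 2.0, size=1000)
        assert plv(ph) == pytest.approx(expected_plv(2.0), abs=0.04)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            plv([])

    def test_global_rotation_invariance(self, rng):
        ph = rng.vonmises(0.0, 1.0, size=200)
        assert plv(ph) == pytest.approx(plv(ph + 1.234), abs=1e-12)


class TestPlvBootstrap:
    def test_constant_phase_events_pin_ci_at_one(self, field_5hz):
        # events exactly at oscillation troughs: all phases equal
        times = (np.arange(40) + 0.5) / 5.0  # trough of cos at phase pi
        r = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=200, seed=0)
        i5 = int(np.argmin(np.abs(r.freqs_hz - 5.0)))
        assert r.plv[i5] == pytest.approx(1.0, abs=0.01)
        assert r.ci_lo[i5] == pytest.approx(1.0, abs=0.02)

    def test_uniform_phases_ci_sits_at_resultant_floor(self, field_5hz, rng):
        # the raw size-50 resultant has mean ~ sqrt(pi/(4*50)) under uniformity
        times = np.sort(rng.uniform(1.0, 99.0, 80))
        r = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=1000,
                          sample_size=50, seed=1)
        i5 = int(np.argmin(np.abs(r.freqs_hz - 5.0)))
        floor = np.sqrt(np.pi / (4 * 50))
        assert r.ci_lo[i5] < floor < r.ci_hi[i5]
        assert r.ci_lo[i5] > 0.0  # documented small-sample bias: CI excludes 0

    def test_debiased_ci_covers_zero_for_uniform(self, field_5hz, rng):
        times = np.sort(rng.uniform(1.0, 99.0, 300))
        r = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=1000,
                          sample_size=50, seed=2, debias=True)
        i5 = int(np.argmin(np.abs(r.freqs_hz - 5.0)))
        assert r.ci_lo[i5] == 0.0

    def test_ci_ordering_invariant(self, field_5hz, rng):
        times = np.sort(rng.uniform(1.0, 99.0, 120))
        r = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=300, seed=3)
        assert np.all(r.ci_lo <= r.plv + 1e-12)
        assert np.all(r.plv <= r.ci_hi + 1e-12)

    def test_small_trial_shrinks_sample_with_flag(self, field_5hz):
        times = np.linspace(2, 90, 20)
        with pytest.warns(UserWarning, match="shrunk"):
            r = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=100,
                              sample_size=50, seed=0)
        assert r.shrunk_sample and r.sample_size == 20

    def test_no_events_in_span_rejected(self, field_5hz):
        with pytest.raises(ValueError, match="span"):
            plv_bootstrap(EventTrain(0, np.array([1e4])), field_5hz, 0)


class TestPlvCompare:
    def test_identical_inputs_nothing_significant(self, field_5hz, rng):
        times = np.sort(rng.uniform(1.0, 99.0, 200))
        r1 = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=400, seed=5)
        r2 = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=400, seed=5)
        out = plv_compare(r1, r2)
        assert not out["significant"].any()

    def test_locked_vs_unlocked_flags_lock_frequency(self, field_5hz, rng):
        locked = sample_locked_spikes(4.0, 98.0, 5.0, 4.0, seed=6)
        unlocked = np.sort(rng.uniform(1.0, 99.0, locked.size))
        rs = plv_bootstrap(EventTrain(0, locked), field_5hz, 0, n_boot=500, seed=7)
        rn = plv_bootstrap(EventTrain(0, unlocked), field_5hz, 0, n_boot=500, seed=8)
        out = plv_compare(rs, rn)
        band = (rs.freqs_hz >= 4) & (rs.freqs_hz <= 6)
        assert out["significant"][band].any()

    def test_grid_mismatch_rejected(self, field_5hz, rng):
        times = np.sort(rng.uniform(1.0, 99.0, 100))
        r1 = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=100, seed=0)
        r2 = plv_bootstrap(EventTrain(0, times), field_5hz, 0, n_boot=100, seed=0,
                           freq_mask=field_5hz.freqs_hz < 100)
        with pytest.raises(ValueError, match="grids"):
            plv_compare(r1, r2)


class TestRayleigh:
    def test_degenerate_all_equal(self):
        res = rayleigh_test(np.full(60, 1.2))
        assert res["Z"] == pytest.approx(60.0)
        assert res["p"] < 1e-20

    def test_uniformly_spaced_phases_null(self):
        ph = np.linspace(-np.pi, np.pi, 64, endpoint=False)
        res = rayleigh_test(ph)
        assert res["R"] == pytest.approx(0.0, abs=1e-12)
        assert res["p"] == pytest.approx(1.0, abs=0.01)

    def test_p_monotone_decreasing_in_resultant(self, rng):
        n = 67
        ps = []
        for kappa in (0.2, 0.5, 1.0, 2.0):
            ph = rng.vonmises(0, kappa, n)
            ps.append((rayleigh_test(ph)["R"], rayleigh_test(ph)["p"]))
        rs, pvals = zip(*sorted(ps))
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_tiny_sample_warns(self):
        with pytest.warns(UserWarning, match="n=3"):
            res = rayleigh_test([0.0, 0.1, 0.2])
        assert res["p"] == 1.0


@pytest.fixture(scope="module")
def grid_field():
    """16 channels; only the reference-corner row carries the 5 Hz tone."""
    t = np.arange(int(80 * FS)) / FS
    rng = np.random.default_rng(9)
    data = 0.3 * rng.standard_normal((16, t.size))
    carriers = [12, 13, 14, 15]  # bottom row, nearest the reference corner
    for ci in carriers:
        data[ci] += np.cos(2 * np.pi * 5.0 * t)
    rec = Recording(data=data, fs_hz=FS, channels=default_grid_channels())
    return multitaper_phase(rec, freqs_hz=np.arange(3.0, 8.0), step_s=0.01), carriers


class TestSpatialMap:
    def test_map_maximal_on_carrier_channels(self, grid_field):
        pf, carriers = grid_field
        locked = sample_locked_spikes(4.0, 78.0, 5.0, 4.0, seed=10)
        out = plv_spatial_map(EventTrain(0, locked), pf, band_hz=(4.0, 6.0),
                              n_boot=200, seed=0)
        others = [i for i in range(16) if i not in carriers]
        assert out["plv"][carriers].min() > out["plv"][others].max()

    def test_uniform_copies_give_uniform_map(self, rng):
        t = np.arange(int(60 * FS)) / FS
        x = np.cos(2 * np.pi * 5.0 * t)
        rec = Recording(data=np.tile(x, (16, 1)), fs_hz=FS,
                        channels=default_grid_channels())
        pf = multitaper_phase(rec, freqs_hz=np.arange(4.0, 7.0), step_s=0.02)
        locked = sample_locked_spikes(4.0, 58.0, 5.0, 2.0, seed=11)
        out = plv_spatial_map(EventTrain(0, locked), pf, band_hz=(4.0, 6.0),
                              n_boot=200, seed=1)
        assert np.ptp(out["plv"]) < 1e-9


class TestStimulusSplit:
    def test_partition_boundaries(self):
        stim = StimulusProtocol(onsets_s=np.array([10.0]), pulse_width_s=0.1,
                                pulse_rate_hz=2.0, train_duration_s=1.0)
        times = np.array([9.99, 10.0, 10.15, 10.3, 10.55, 10.71, 11.0])
        ev = EventTrain(0, times)
        s, ns = split_events_by_stimulus(ev, stim)
        # pulses at 10.0 and 10.5; stim windows [10.0,10.2) and [10.5,10.7)
        np.testing.assert_allclose(s.event_times_s, [10.0, 10.15, 10.55])
        np.testing.assert_allclose(ns.event_times_s, [9.99, 10.3, 10.71, 11.0])
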