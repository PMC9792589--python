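"""Morlet time-frequency power, band power, and region ratios."""

import numpy as np
import pandas as pd
import pytest

from orgephys.spectral import (
    BandDefinition,
    DEFAULT_BANDS,
    band_power,
    morlet_spectrogram,
    region_power_ratio,
    trial_averaged_spectrogram,
)
from orgephys.evoked import TrialTensor, epoch_trials
from orgephys.synth import (
    GammaBurstSpec,
    SynthSpec,
    default_grid_channels,
    generate_anesthesia_epoch,
    generate_recording,
)

from conftest import make_single_channel

FS = 500.0


def tone(f, dur=30.0, amp=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    return amp * np.cos(2 * np.pi * f * t)


class TestMorlet:
    def test_tone_localizes_to_its_frequency(self):
        tfa = morlet_spectrogram(make_single_channel(tone(10.0), FS),
                                 freqs_hz=np.geomspace(1, 150, 80))
        mean_pw = tfa.values[0].mean(axis=1)
        assert abs(tfa.freqs_hz[np.argmax(mean_pw)] - 10.0) < 0.7

    def test_power_scales_quadratically(self):
        p1 = morlet_spectrogram(make_single_channel(tone(10.0), FS),
                                freqs_hz=[10.0]).values[0].mean()
        p2 = morlet_spectrogram(make_single_channel(tone(10.0, amp=2.0), FS),
                                freqs_hz=[10.0]).values[0].mean()
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)

    def test_tone_power_concentrates_within_bandwidth(self):
        f0, n_cycles = 40.0, 7.0
        freqs = np.arange(5.0, 150.0, 1.0)
        tfa = morlet_spectrogram(make_single_channel(tone(f0), FS), freqs_hz=freqs)
        pw = tfa.values[0].mean(axis=1)
        sigma_f = f0 / n_cycles
        inside = np.abs(freqs - f0) <= 2 * sigma_f
        assert pw[inside].sum() / pw.sum() >= 0.90

    def test_white_noise_density_flat(self, rng):
        x = rng.standard_normal(int(120 * FS))
        tfa = morlet_spectrogram(make_single_channel(x, FS),
                                 freqs_hz=np.geomspace(8, 150, 20))
        density = tfa.values[0].mean(axis=1) / (2.0 / FS)  # expect ~1 everywhere
        assert np.all(np.abs(density - 1.0) < 0.2)

    def test_nyquist_violation_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            morlet_spectrogram(make_single_channel(tone(10.0, dur=2.0), FS),
                               freqs_hz=[300.0])


class TestTrialAveragedSpectrogram:
    def test_identical_trials_equal_single_trial(self, rng):
        x = rng.standard_normal((1, 500))
        trials = np.repeat(x[None], 5, axis=0)
        tt = TrialTensor(values=trials, t_axis_s=np.arange(500) / FS,
                         baseline_window_s=(0, 0), fs_hz=FS)
        tfa = trial_averaged_spectrogram(tt, freqs_hz=[10.0, 20.0])
        single = morlet_spectrogram(x, freqs_hz=[10.0, 20.0], fs_hz=FS)
        np.testing.assert_allclose(tfa.values[0], single.values[0], rtol=1e-10)

    def test_evoked_gamma_burst_localized_in_band_and_time(self):
        spec = SynthSpec(
            fs_hz=FS, duration_s=40.0, n_trials=4, train_period_s=8.0,
            noise_sd_uv=1.0, evoked=None, oscillation=None, spikes=None,
            gamma_burst=GammaBurstSpec(amp_uv=20.0), seed=3,
        )
        rec, _ = generate_recording(spec)
        tt = epoch_trials(rec, 0, pre_s=0.25, post_s=0.25)
        freqs = np.arange(10.0, 150.0, 5.0)
        tfa = trial_averaged_spectrogram(tt, freqs_hz=freqs)
        gamma_rows = (freqs >= 60) & (freqs <= 100)
        low_rows = freqs < 40
        pre = tfa.t_axis_s < -0.05
        post = (tfa.t_axis_s >= 0) & (tfa.t_axis_s < 0.15)
        pw = tfa.values[0]
        assert pw[np.ix_(gamma_rows, post)].mean() > 5 * pw[np.ix_(gamma_rows, pre)].mean()
        assert pw[np.ix_(gamma_rows, post)].mean() > 5 * pw[np.ix_(low_rows, post)].mean()


class TestBandPower:
    def test_theta_tone_dominates_theta_band(self):
        bp = band_power(make_single_channel(tone(6.0), FS), DEFAULT_BANDS)
        assert bp.loc[0, "theta"] > 50 * bp.loc[0, "alpha"]
        assert bp.loc[0, "theta"] > 50 * bp.loc[0, "low_gamma"]

    def test_zero_signal_zero_power(self):
        bp = band_power(make_single_channel(np.zeros(int(10 * FS)), FS), DEFAULT_BANDS)
        assert (bp.to_numpy() == 0).all()

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no grid frequencies"):
            band_power(make_single_channel(tone(6.0, dur=5.0), FS),
                       [BandDefinition("sliver", 33.0, 33.1)])

    def test_additive_over_disjoint_bands(self, rng):
        x = rng.standard_normal(int(60 * FS))
        tfa = morlet_spectrogram(make_single_channel(x, FS), freqs_hz=np.arange(8.0, 60.0))
        lo = BandDefinition("lo", 8.0, 30.0)
        hi = BandDefinition("hi", 30.0, 60.0)
        full = BandDefinition("full", 8.0, 60.0)
        bp = band_power(tfa, [lo, hi, full])
        n_lo = ((tfa.freqs_hz >= 8) & (tfa.freqs_hz < 30)).sum()
        n_hi = ((tfa.freqs_hz >= 30) & (tfa.freqs_hz < 60)).sum()
        combined = (bp.loc[0, "lo"] * n_lo + bp.loc[0, "hi"] * n_hi) / (n_lo + n_hi)
        assert combined == pytest.approx(bp.loc[0, "full"], rel=1e-10)


class TestRegionPowerRatio:
    def test_copied_channels_give_unit_ratio(self, rng):
        channels = default_grid_channels()
        base = rng.standard_normal(int(20 * FS))
        data = np.tile(base, (16, 1)) + 0.01 * rng.standard_normal((16, int(20 * FS)))
        from orgephys.data import Recording

        rec = Recording(data=data, fs_hz=FS, channels=channels)
        ratio = region_power_ratio(band_power(rec), channels)
        assert np.allclose(ratio["organoid_ratio"], 1.0, atol=0.01)

    def test_scale_invariance(self, rng):
        channels = default_grid_channels()
        bp = pd.DataFrame({"theta": rng.uniform(1, 2, 16), "low_gamma": rng.uniform(1, 2, 16)})
        r1 = region_power_ratio(bp, channels)
        r2 = region_power_ratio(bp * 37.5, channels)
        np.testing.assert_allclose(r1["organoid_ratio"], r2["organoid_ratio"])
        np.testing.assert_allclose(r1["p_value"], r2["p_value"])

    def test_too_few_region_channels_rejected(self, rng):
        channels = default_grid_channels()[:4]  # organoid only
        bp = pd.DataFrame({"theta": rng.uniform(1, 2, 4)})
        with pytest.raises(ValueError, match="2 included channels per region"):
            region_power_ratio(bp, channels)

    def test_anesthesia_gamma_contrast_recovered(self):
        spec = SynthSpec(fs_hz=FS, duration_s=60.0, noise_sd_uv=2.0, seed=6)
        anesth = generate_anesthesia_epoch(spec)
        awake = generate_anesthesia_epoch(spec, awake_control=True)
        r_an = region_power_ratio(band_power(anesth), anesth.channels)
        r_aw = region_power_ratio(band_power(awake), awake.channels)
        for band in ("low_gamma", "high_gamma"):
            assert r_an.loc[band, "organoid_ratio"] == pytest.approx(0.5, abs=0.1)
            assert r_an.loc[band, "p_value"] < 0.05
            assert r_aw.loc[band, "organoid_ratio"] == pytest.approx(1.0, abs=0.1)
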