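"""Recover the evoked-LFP propagation delay map and test the extreme pair.

Builds a noiseless 20-trial recording, extracts the LFP band, epochs on
pulse onsets, and reads per-channel peak delays off the trial average;
the channel-pair delay difference is tested against a shuffle null.
"""

import numpy as np

from orgephys import (
    SynthSpec,
    delay_shuffle_test,
    epoch_trials,
    filter_lfp,
    generate_recording,
    peak_map,
    trial_average,
)
from orgephys.synth import GammaBurstSpec

spec = SynthSpec(
    fs_hz=20000.0, duration_s=21.0, n_trials=20, first_onset_s=0.5,
    train_period_s=1.0, train_duration_s=0.5, noise_sd_uv=0.0,
    oscillation=None, spikes=None, gamma_burst=GammaBurstSpec(amp_uv=0.0), seed=3,
)
rec, truth = generate_recording(spec)

lfp = filter_lfp(rec)
tt = epoch_trials(lfp, which_pulse=0, pre_s=0.1, post_s=0.3)
mean, sd = trial_average(tt)
pm = peak_map(mean, tt.t_axis_s)

print("recovered peak delays (ms):")
print(np.round(pm.peak_delay_s.reshape(4, 4) * 1e3, 2))
err = np.max(np.abs(pm.peak_delay_s - truth.true_delays_s)) * rec.fs_hz
print(f"max recovery error: {err:.1f} samples at 20 kHz")

# directional test: does the far (organoid) corner lag the reference?
res = delay_shuffle_test(pm, chan_a=15, chan_b=0, n_shuffles=1000, seed=0,
                         alternative="greater")
print(f"extreme-pair delay: {res['observed_delta_s'] * 1e3:.2f} ms, "
      f"one-sided p = {res['p_value']:.4f} (1000 shuffles)")
# ~5.7 ms with p < 0.01: the propagation signature of a connected graft.
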