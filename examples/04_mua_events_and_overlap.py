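"""Detect MUA events, verify their locality, and test channel overlap.

Threshold detection on the 0.5-3 kHz band, event-triggered averages
across channels (independent channels average to ~0), and the 1-ms-bin
overlap count with its circular-shift null.
"""

import numpy as np

from orgephys import (
    SynthSpec,
    detect_events,
    event_triggered_average,
    filter_mua,
    generate_recording,
    overlap_count,
    overlap_shift_test,
)

spec = SynthSpec(fs_hz=20000.0, duration_s=60.0, n_trials=7, seed=5)
rec, truth = generate_recording(spec)

band = filter_mua(rec)
trains = detect_events(band, k=3.5)
rates = [tr.n_events / rec.duration_s for tr in trains]
print(f"detected event rates (Hz): {np.round(rates, 2)[:8]} ...")
print("  (injected 2 Hz spikes plus the ~4/s noise-crossing floor at k=3.5)")

eta = event_triggered_average(trains, band, target_channel=0)
i0 = int(np.argmin(np.abs(eta.t_axis_s)))
print(f"\nevent-triggered average at lag 0 ({eta.n_events} events):")
print(f"  target channel: {eta.mean[0, i0]:8.2f} uV (spike deflection)")
print(f"  other channels: {np.abs(eta.mean[1:, i0]).max():8.2f} uV max "
      f"(independent activity averages out)")

res = overlap_shift_test(trains[0], trains[15], duration_s=rec.duration_s,
                         n_shifts=10000, seed=2)
print(f"\noverlap channels 0 vs 15: {overlap_count(trains[0], trains[15])} "
      f"shared 1-ms bins; shift-null p = {res['p_value']:.3f}")
# p near 1: co-occurrence is at chance, i.e. the channels record
# independent local firing.
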