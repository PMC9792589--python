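"""Generate a synthetic 16-channel recording and look at its ground truth.

The generator injects a stimulus-evoked LFP whose latency grows linearly
with distance from the visual-cortex-proximal corner pad, theta-locked
spikes, a shared volume-conducted source, and background noise.
"""

import numpy as np

from orgephys import SynthSpec, generate_recording

spec = SynthSpec(fs_hz=20000.0, duration_s=90.0, n_trials=10, seed=42)
rec, truth = generate_recording(spec)

print(f"recording: {rec.n_channels} channels x {rec.duration_s:.0f} s at {rec.fs_hz:.0f} Hz")
print(f"stimulus: {rec.stimulus.n_trials} trains of {rec.stimulus.pulse_rate_hz:.0f} Hz pulses")
print()
print("injected evoked latencies (ms) on the 4x4 grid "
      "(bottom-right = reference corner, nearest visual cortex):")
print(np.round(truth.true_delays_s.reshape(4, 4) * 1e3, 2))
print()
print("injected evoked amplitudes (uV):")
print(np.round(truth.evoked_amp_uv.reshape(4, 4), 1))
print()
print(f"true spike-field PLV per channel (von Mises kappa=2): "
      f"{truth.true_plv[0]:.3f} everywhere")
print(f"spike counts per channel: {[len(s) for s in truth.spike_times_s[:4]]} ...")
# The latency map shows the ~36 ms visual response arriving last (~41.7 ms)
# at the far corner over the graft - the propagation pattern the evoked
# analysis is designed to recover.
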