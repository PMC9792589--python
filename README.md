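# orgephys

Analysis of multichannel extracellular recordings from human cortical
organoids implanted in mouse cortex, recorded through a 4×4 surface
microelectrode grid (500 µm pitch, 20 kHz). The scientific question the
toolchain addresses: does the graft functionally integrate with the host
visual system? The evidence it quantifies, channel by channel:

- **Evoked LFP propagation** — per-channel peak amplitude/latency maps of
  the visual evoked response and a shuffle-based test of the delay between
  cortex-proximal and organoid channels (a connected graft receives the
  response a few ms later than visual cortex).
- **Spectral power** — Morlet time–frequency power in µV²/Hz, band-power
  summaries (δ, θ, α, β, low/high γ), and the anesthetized-vs-awake
  organoid/cortex power ratio with a one-sided two-sample t-test.
- **Multi-unit activity** — −k·σ threshold event detection (k ∈ [3,4]) on
  the 0.5–3 kHz band, rectified MUA power and evoked SNR, event-triggered
  averages for spatial locality, and 1-ms-bin event overlap with a
  10,000-circular-shift permutation null.
- **Spike–field phase locking** — multitaper (DPSS) LFP phase, the
  phase-locking value PLV = |n⁻¹ Σₖ e^{iφₖ}| over phases φₖ at event
  times, bootstrap CIs (resamples of 50 events), stim/no-stim difference
  flags, Rayleigh tests (Z = nR²), and 4–6 Hz spatial locking maps.
- **Preprocessing** — impedance-based channel exclusion (> 4 MΩ), ICA
  removal of uniformly mixed (volume-conducted / line-noise) components,
  and zero-phase Chebyshev II band extraction.

Because such recordings are rarely public, the package includes a
synthetic-data generator (`orgephys.synth`) that produces 16-channel
recordings with all of the above features injected at known parameter
values — evoked delay gradients, von Mises spike locking with
PLV = I₁(κ)/I₀(κ), shared sources, burst suppression — so every analysis
is validated by recovering its own ground truth. See `docs/methods.md`
for the models, defaults, and numerical choices.

## Worked example

```sh
python examples/02_evoked_delay_map.py
```

```
recovered peak delays (ms):
[[41.7  40.85 40.25 40.05]
 [40.85 39.8  39.   38.7 ]
 [40.25 39.   37.9  37.35]
 [40.05 38.7  37.35 36.  ]]
max recovery error: 0.0 samples at 20 kHz
extreme-pair delay: 5.70 ms, one-sided p = 0.0033 (1000 shuffles)
```

The generator injected a linear delay gradient away from the reference
corner (bottom-right, nearest visual cortex, 36 ms) out to the far corner
over the graft (41.7 ms); the peak map recovers every latency exactly, and
the permutation test rejects the null that the 5.7 ms extreme-pair delay
arose from an arbitrary channel labeling — the statistical signature of
activity propagating from host cortex into the organoid. The other
examples cover simulation (`01`), phase locking (`03`: a κ = 2 locked
train recovers PLV 0.671 with 95% CI [0.536, 0.792] against the
I₁(2)/I₀(2) = 0.698 target), MUA events and overlap (`04`), and the full
pipeline (`05`).

A thin CLI wraps the same functions:

```sh
orgephys simulate --seed 1 --out rec.h5 --truth truth.json
orgephys preprocess rec.h5 --out clean.h5 --ica-report ica.json
orgephys lfp clean.h5 --pair 15:0 --out lfp.json
orgephys run --config pipeline.yaml     # full pipeline + JSON report
```

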