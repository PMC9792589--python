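"""Synthetic 16-channel recordings with known ground truth.

The generator emulates the statistical structure the downstream analyses
assume, so that every stage of the pipeline can be exercised and validated
against injected parameters:

* stimulus-evoked biphasic LFP deflections whose latency increases linearly
  with distance from a reference corner channel (the pad closest to visual
  cortex), emulating activity propagating from host cortex into the graft;
* an evoked gamma burst (60-100 Hz) at each pulse onset;
* an ongoing low-frequency oscillation (theta, 5 Hz by default);
* MUA-band spike trains whose spike phases relative to that oscillation
  follow a von Mises distribution with per-channel concentration κ, so the
  true phase-locking value is I1(κ)/I0(κ);
* a shared, uniformly mixed "volume-conducted" source plus 60 Hz line
  noise (one common waveform: both have the identical all-ones mixing
  direction, so they are indistinguishable to any linear unmixing);
* white + 1/f background noise;
* anesthesia burst-suppression epochs with a controllable organoid/cortex
  gamma power ratio.

All outputs are deterministic functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy import signal, special

from .data import ChannelInfo, GRID_PITCH_UM, Recording, Region, StimulusProtocol

__all__ = [
    "SynthSpec",
    "GroundTruth",
    "expected_plv",
    "sample_locked_spikes",
    "generate_recording",
    "generate_anesthesia_epoch",
    "default_grid_channels",
]


def expected_plv(kappa: float) -> float:
    """Mean resultant length of a von Mises distribution: I1(κ)/I0(κ).

    This is the population phase-locking value of spikes whose phases are
    von Mises distributed with concentration ``kappa``.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    # exponentially scaled Bessel ratio is stable for large kappa
    return float(special.i1e(kappa) / special.i0e(kappa))


def sample_locked_spikes(
    rate_hz: float,
    duration_s: float,
    lock_freq_hz: float,
    kappa: float,
    seed: int | np.random.Generator,
    mu: float = np.pi,
) -> np.ndarray:
    """Poisson spike train phase-locked to a cos(2π·f·t) oscillation.

    Spike count is Poisson(rate·duration); each spike is assigned a uniform
    oscillation cycle and a phase drawn from von Mises(mu, kappa), so the
    oscillation phase at spike times has mean resultant length
    :func:`expected_plv` (kappa).  kappa = 0 gives a homogeneous Poisson
    process.
    """
    if rate_hz <= 0 or duration_s <= 0:
        raise ValueError("rate and duration must be positive")
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration_s)
    n_cycles = int(np.floor(duration_s * lock_freq_hz))
    if n_cycles < 1:
        raise ValueError("duration shorter than one oscillation cycle")
    cycles = rng.integers(0, n_cycles, size=n)
    if kappa == 0:
        phases = rng.uniform(-np.pi, np.pi, size=n)
    else:
        phases = rng.vonmises(mu, kappa, size=n)
    # phase of cos(2π f t) at time t is (2π f t) wrapped; invert for t
    times = (cycles + phases / (2 * np.pi)) / lock_freq_hz
    times = times[(times >= 0) & (times < duration_s)]
    times = np.unique(times)
    return times


# ---------------------------------------------------------------------------
# specification dataclasses


@dataclass
class EvokedSpec:
    """Stimulus-evoked biphasic LFP with a linear spatial delay gradient.

    Latency of channel i is ``latency0_s + delay_gradient_s_per_um * d_i``
    where d_i is the Euclidean distance from the reference corner pad.
    Amplitude falls linearly from ``amp_ref_uv`` at the reference to
    ``amp_far_uv`` at the farthest pad.  Defaults reproduce the regime of a
    visual response arriving in cortex at ~36 ms with ~200 µV and reaching
    the far (organoid) corner ~5.7 ms later at ~50 µV.
    """

    amp_ref_uv: float = 200.0
    amp_far_uv: float = 50.0
    latency0_s: float = 0.036
    delay_gradient_s_per_um: float = 5.7e-3 / (3 * np.sqrt(2) * GRID_PITCH_UM)
    neg_width_s: float = 0.006   # Gaussian sd of the negative lobe
    pos_width_s: float = 0.010   # Gaussian sd of the positive lobe
    lobe_gap_s: float = 0.020
    reference_rowcol: Tuple[int, int] = (3, 3)


@dataclass
class GammaBurstSpec:
    """Evoked narrow-band gamma burst at each pulse onset."""

    band_hz: Tuple[float, float] = (60.0, 100.0)
    amp_uv: float = 0.0
    duration_s: float = 0.15


@dataclass
class OscillationSpec:
    """Ongoing low-frequency oscillation (locking target for spikes).

    A scalar ``amp_uv`` is shaped across the grid by ``spatial_gradient``:
    channel i gets amp·(1 − gradient·d_i/d_max), strongest at the
    reference (visual-cortex-proximal) corner.  A uniform oscillation
    would be spatially indistinguishable from volume conduction and be
    removed by the ICA stage; real low-frequency rhythms fall off with
    distance from their source.  Pass an array to set amplitudes directly.
    """

    freq_hz: float = 5.0
    amp_uv: float | np.ndarray = 30.0
    spatial_gradient: float = 0.7


@dataclass
class SpikeSpec:
    """MUA-band spike trains with von Mises phase locking.

    ``amplitude_sd`` is the negative-peak amplitude of each spike waveform
    in units of the channel's MUA-band (0.5-3 kHz) background standard
    deviation.  Kernel: 0.4 ms negative lobe followed by a 0.6 ms positive
    lobe (half-sines), which sits inside the MUA band.
    """

    rate_hz: float = 2.0
    amplitude_sd: float = 6.0
    lock_freq_hz: float = 5.0
    kappa: float | np.ndarray = 2.0
    #: concentration outside stimulation windows; None = same as ``kappa``.
    #: Setting 0 reproduces stimulus-gated locking (locked only during stim).
    kappa_no_stim: Optional[float] = None
    stim_pad_s: float = 0.1
    mu: float = np.pi
    neg_lobe_s: float = 0.0004
    pos_lobe_s: float = 0.0006


@dataclass
class CommonSourceSpec:
    """Shared waveform added with identical weight to every channel.

    Emulates volume conduction plus any globally coherent artifact.  The
    waveform is a bursty (super-Gaussian) low-frequency process so that it
    remains identifiable to blind source separation.
    """

    amp_uv: float = 0.0
    burst_rate_hz: float = 1.0
    smooth_s: float = 0.02


@dataclass
class LineNoiseSpec:
    amp_uv: float = 0.0
    freq_hz: float = 60.0


@dataclass
class AnesthesiaSpec:
    """Burst-suppression structure for anesthetized epochs.

    ``suppression_fraction`` of the recording is near-silent (envelope 5%
    of the burst envelope); during bursts the channels carry broadband
    delta/theta/alpha/beta activity plus gamma whose POWER on
    organoid-labeled channels is scaled by ``gamma_power_scale``
    (amplitude scaled by its square root).
    """

    burst_rate_hz: float = 0.25
    suppression_fraction: float = 0.5
    gamma_power_scale: float = 0.5
    gamma_band_hz: Tuple[float, float] = (30.0, 100.0)
    gamma_amp_uv: float = 40.0
    slow_amp_uv: float = 60.0
    residual: float = 0.05
    amp_jitter: float = 0.02


@dataclass
class SynthSpec:
    """Full specification of a synthetic recording. See module docstring."""

    fs_hz: float = 20000.0
    duration_s: float = 60.0
    n_rows: int = 4
    n_cols: int = 4
    noise_sd_uv: float = 10.0
    evoked: Optional[EvokedSpec] = field(default_factory=EvokedSpec)
    gamma_burst: GammaBurstSpec = field(default_factory=GammaBurstSpec)
    oscillation: Optional[OscillationSpec] = field(default_factory=OscillationSpec)
    spikes: Optional[SpikeSpec] = field(default_factory=SpikeSpec)
    common_source: CommonSourceSpec = field(default_factory=CommonSourceSpec)
    line_noise: LineNoiseSpec = field(default_factory=LineNoiseSpec)
    anesthesia: AnesthesiaSpec = field(default_factory=AnesthesiaSpec)
    # stimulus protocol: trains of pulses; onsets get a seeded uniform
    # jitter so ongoing oscillations are not phase-locked to the trial
    # grid (0.2 s = one cycle of the default 5 Hz oscillation)
    n_trials: int = 20
    train_period_s: float = 8.0
    train_jitter_s: float = 0.2
    first_onset_s: float = 1.0
    pulse_rate_hz: float = 2.0
    pulse_width_s: float = 0.1
    train_duration_s: float = 4.0
    seed: int = 0

    _NESTED = {
        "evoked": EvokedSpec,
        "gamma_burst": GammaBurstSpec,
        "oscillation": OscillationSpec,
        "spikes": SpikeSpec,
        "common_source": CommonSourceSpec,
        "line_noise": LineNoiseSpec,
        "anesthesia": AnesthesiaSpec,
    }

    @classmethod
    def from_dict(cls, d: dict) -> "SynthSpec":
        """Build a spec from plain (e.g. YAML-loaded) nested dictionaries.

        A nested block given as a dict becomes the matching sub-spec;
        ``None`` disables an optional component.
        """
        kwargs = {}
        for k, v in d.items():
            sub = cls._NESTED.get(k)
            if sub is not None and isinstance(v, dict):
                kwargs[k] = sub(**v)
            else:
                kwargs[k] = v
        return cls(**kwargs)


@dataclass
class GroundTruth:
    """Injected parameters, for recovery tests against the analyses."""

    true_delays_s: np.ndarray
    evoked_amp_uv: np.ndarray
    spike_times_s: List[np.ndarray]
    true_plv: np.ndarray
    common_source_trace: Optional[np.ndarray] = None
    band_power_ratio: Optional[dict] = None


# ---------------------------------------------------------------------------
# channel grid helpers


def default_grid_channels(n_rows: int = 4, n_cols: int = 4) -> List[ChannelInfo]:
    """4x4 grid with the study's region assignment.

    Six organoid pads (rows 0-1, cols 0-2: the graft corner), eight cortex
    pads (rows 2-3), two ambiguous pads; the reference / visual-cortex-
    proximal pad is the bottom-right corner (row 3, col 3).
    """
    channels = []
    for r in range(n_rows):
        for c in range(n_cols):
            if r <= 1 and c <= 2:
                region = Region.ORGANOID
            elif r >= 2:
                region = Region.CORTEX
            else:
                region = Region.AMBIGUOUS
            channels.append(
                ChannelInfo(channel_id=r * n_cols + c, row=r, col=c, region=region)
            )
    return channels


def _grid_distances_um(channels: List[ChannelInfo], ref_rowcol: Tuple[int, int]) -> np.ndarray:
    ref_x = ref_rowcol[1] * GRID_PITCH_UM
    ref_y = ref_rowcol[0] * GRID_PITCH_UM
    return np.array([np.hypot(c.x_um - ref_x, c.y_um - ref_y) for c in channels])


# ---------------------------------------------------------------------------
# signal building blocks


def _background_noise(rng: np.random.Generator, n: int, sd_uv: float) -> np.ndarray:
    """White + 1/f Gaussian noise, equal-power mix, total sd = sd_uv."""
    if sd_uv == 0:
        return np.zeros(n)
    white = rng.standard_normal(n)
    # spectrally shaped noise: amplitude ∝ f^-1/2 (power ∝ 1/f), DC removed
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** -0.5
    pink = np.fft.irfft(spec * shape, n=n)
    pink /= pink.std()
    return sd_uv * (white + pink) / np.sqrt(2.0)


def _biphasic_lfp_kernel(spec: EvokedSpec, fs: float) -> Tuple[np.ndarray, int]:
    """Evoked LFP kernel and the index of its (negative) extremum."""
    t = np.arange(-4 * spec.neg_width_s, spec.lobe_gap_s + 4 * spec.pos_width_s, 1 / fs)
    k = -np.exp(-(t**2) / (2 * spec.neg_width_s**2)) + 0.5 * np.exp(
        -((t - spec.lobe_gap_s) ** 2) / (2 * spec.pos_width_s**2)
    )
    return k, int(np.argmin(k))


def _spike_kernel(spec: SpikeSpec, fs: float) -> np.ndarray:
    """Biphasic MUA spike waveform, negative peak normalized to -1."""
    n_neg = max(2, int(round(spec.neg_lobe_s * fs)))
    n_pos = max(2, int(round(spec.pos_lobe_s * fs)))
    k = np.concatenate(
        [-np.sin(np.pi * np.arange(n_neg) / n_neg), 0.4 * np.sin(np.pi * np.arange(n_pos) / n_pos)]
    )
    return k / np.abs(k.min())


def _mua_band_sd(noise_sd_uv: float, fs: float, rng: np.random.Generator) -> float:
    """MUA-band (0.5-3 kHz) sd of the background noise, by construction.

    Estimated once from a noise realization pushed through the same MUA
    band-pass the pipeline uses, so injected spike amplitudes are expressed
    in the units the detector will see.
    """
    if noise_sd_uv == 0:
        return 0.0
    probe = _background_noise(rng, int(fs), noise_sd_uv)
    if fs >= 8000:
        from .preprocess import _mua_sos  # local import to avoid cycle at import time

        sos = _mua_sos(fs)
    else:
        # band cannot be fully represented; use the available high band
        sos = signal.butter(4, (250.0, 0.45 * fs), btype="bandpass", fs=fs, output="sos")
    return float(signal.sosfiltfilt(sos, probe).std())


def _bursty_waveform(rng: np.random.Generator, n: int, fs: float, burst_rate_hz: float,
                     smooth_s: float) -> np.ndarray:
    """Sparse smoothed impulse process: unit-sd, heavy-tailed (super-Gaussian)."""
    x = np.zeros(n)
    n_impulses = rng.poisson(burst_rate_hz * n / fs * 10)
    idx = rng.integers(0, n, size=max(n_impulses, 1))
    x[idx] += rng.standard_normal(idx.size) * 3.0
    win = signal.windows.hann(max(3, int(smooth_s * fs)))
    x = signal.fftconvolve(x, win / win.sum(), mode="same")
    s = x.std()
    return x / s if s > 0 else x


def _band_noise(rng: np.random.Generator, n: int, fs: float, band: Tuple[float, float]) -> np.ndarray:
    """Unit-sd Gaussian noise band-limited to ``band`` (FFT masking)."""
    spec = np.fft.rfft(rng.standard_normal(n))
    f = np.fft.rfftfreq(n, d=1 / fs)
    mask = (f >= band[0]) & (f <= band[1])
    x = np.fft.irfft(spec * mask, n=n)
    s = x.std()
    return x / s if s > 0 else x


# ---------------------------------------------------------------------------
# generators


def generate_recording(spec: SynthSpec) -> Tuple[Recording, GroundTruth]:
    """Generate a stimulus-driven awake recording plus its ground truth.

    Deterministic given ``spec.seed``.  Raises if the recording is too
    short to contain the stimulus protocol.
    """
    fs = spec.fs_hz
    n = int(round(spec.duration_s * fs))
    n_ch = spec.n_rows * spec.n_cols
    rng = np.random.default_rng(spec.seed)
    channels = default_grid_channels(spec.n_rows, spec.n_cols)

    onsets = spec.first_onset_s + np.arange(spec.n_trials) * spec.train_period_s
    if spec.train_jitter_s > 0:
        onsets = onsets + rng.uniform(0, spec.train_jitter_s, size=onsets.size)
    onsets = np.round(onsets * fs) / fs  # snap to the sample grid
    if onsets[-1] + spec.train_duration_s > spec.duration_s:
        raise ValueError(
            "duration too short for the stimulus protocol: last train ends at "
            f"{onsets[-1] + spec.train_duration_s:.1f} s > {spec.duration_s:.1f} s"
        )
    stimulus = StimulusProtocol(
        onsets_s=onsets,
        pulse_width_s=spec.pulse_width_s,
        pulse_rate_hz=spec.pulse_rate_hz,
        train_duration_s=spec.train_duration_s,
    )
    pulse_onsets = stimulus.all_pulse_onsets_s()

    data = np.zeros((n_ch, n), dtype=float)
    t = np.arange(n) / fs

    # --- evoked biphasic LFP with delay gradient
    if spec.evoked is not None:
        ev = spec.evoked
        dists = _grid_distances_um(channels, ev.reference_rowcol)
        d_max = dists.max() if dists.max() > 0 else 1.0
        lat = ev.latency0_s + ev.delay_gradient_s_per_um * dists
        # snap to the sample grid so injected delays are exactly recoverable
        lat = np.round(lat * fs) / fs
        amps = ev.amp_ref_uv + (ev.amp_far_uv - ev.amp_ref_uv) * dists / d_max
        kernel, i_min = _biphasic_lfp_kernel(ev, fs)
        for ci in range(n_ch):
            for onset in pulse_onsets:
                start = int(round((onset + lat[ci]) * fs)) - i_min
                sl = slice(max(start, 0), min(start + kernel.size, n))
                ksl = slice(sl.start - start, sl.stop - start)
                data[ci, sl] += amps[ci] * kernel[ksl]
        true_delays = lat
        evoked_amps = amps
    else:
        true_delays = np.full(n_ch, np.nan)
        evoked_amps = np.zeros(n_ch)

    # --- evoked gamma burst at each pulse onset
    if spec.gamma_burst.amp_uv > 0:
        gb = spec.gamma_burst
        n_burst = int(gb.duration_s * fs)
        env = signal.windows.hann(n_burst)
        for ci in range(n_ch):
            carrier = _band_noise(rng, n, fs, gb.band_hz)
            for onset in pulse_onsets:
                start = int(round(onset * fs))
                sl = slice(start, min(start + n_burst, n))
                data[ci, sl] += gb.amp_uv * env[: sl.stop - sl.start] * carrier[sl]

    # --- ongoing oscillation
    if spec.oscillation is not None:
        osc = spec.oscillation
        if np.ndim(osc.amp_uv) == 0:
            ref = spec.evoked.reference_rowcol if spec.evoked is not None else (3, 3)
            dists = _grid_distances_um(channels, ref)
            d_max = dists.max() if dists.max() > 0 else 1.0
            amp = float(osc.amp_uv) * (1.0 - osc.spatial_gradient * dists / d_max)
        else:
            amp = np.broadcast_to(np.asarray(osc.amp_uv, dtype=float), (n_ch,))
        carrier = np.cos(2 * np.pi * osc.freq_hz * t)
        data += amp[:, None] * carrier[None, :]

    # --- MUA spikes, phase-locked to the oscillation frequency
    spike_times: List[np.ndarray] = [np.array([]) for _ in range(n_ch)]
    true_plv = np.zeros(n_ch)
    if spec.spikes is not None:
        sp = spec.spikes
        kappas = np.broadcast_to(np.asarray(sp.kappa, dtype=float), (n_ch,)).copy()
        mua_sd = _mua_band_sd(spec.noise_sd_uv, fs, np.random.default_rng(spec.seed + 90001))
        amp_uv = sp.amplitude_sd * (mua_sd if mua_sd > 0 else 1.0)
        kernel = _spike_kernel(sp, fs)
        if sp.kappa_no_stim is not None:
            stim_lo = pulse_onsets
            stim_hi = pulse_onsets + spec.pulse_width_s + sp.stim_pad_s

            def _in_stim(times: np.ndarray) -> np.ndarray:
                k = np.searchsorted(stim_lo, times, side="right") - 1
                kc = np.clip(k, 0, stim_lo.size - 1)
                return (k >= 0) & (times < stim_hi[kc])

        for ci in range(n_ch):
            if sp.kappa_no_stim is None:
                st = sample_locked_spikes(
                    sp.rate_hz, spec.duration_s, sp.lock_freq_hz, kappas[ci], rng, mu=sp.mu
                )
            else:
                # stimulus-gated locking: spikes inside stim windows follow
                # kappa, spikes outside follow kappa_no_stim
                st_a = sample_locked_spikes(
                    sp.rate_hz, spec.duration_s, sp.lock_freq_hz, kappas[ci], rng, mu=sp.mu
                )
                st_b = sample_locked_spikes(
                    sp.rate_hz, spec.duration_s, sp.lock_freq_hz, sp.kappa_no_stim, rng,
                    mu=sp.mu,
                )
                st = np.unique(np.concatenate([st_a[_in_stim(st_a)], st_b[~_in_stim(st_b)]]))
            spike_times[ci] = st
            true_plv[ci] = expected_plv(kappas[ci])
            idx = np.round(st * fs).astype(int)
            for i0 in idx:
                sl = slice(i0, min(i0 + kernel.size, n))
                data[ci, sl] += amp_uv * kernel[: sl.stop - sl.start]
            # keep ground-truth times on the sample grid used for injection
            spike_times[ci] = idx[idx < n] / fs

    # --- common (volume-conducted) source + line noise: one shared waveform
    common = None
    if spec.common_source.amp_uv > 0 or spec.line_noise.amp_uv > 0:
        cs = spec.common_source
        common = np.zeros(n)
        if cs.amp_uv > 0:
            common += cs.amp_uv * _bursty_waveform(rng, n, fs, cs.burst_rate_hz, cs.smooth_s)
        if spec.line_noise.amp_uv > 0:
            common += spec.line_noise.amp_uv * np.sin(2 * np.pi * spec.line_noise.freq_hz * t)
        data += common[None, :]

    # --- background noise
    for ci in range(n_ch):
        data[ci] += _background_noise(rng, n, spec.noise_sd_uv)

    rec = Recording(
        data=data,
        fs_hz=fs,
        channels=channels,
        stimulus=stimulus,
        state="awake",
        provenance=f"synthetic recording, seed={spec.seed}",
    )
    gt = GroundTruth(
        true_delays_s=true_delays,
        evoked_amp_uv=evoked_amps,
        spike_times_s=spike_times,
        true_plv=true_plv,
        common_source_trace=common,
    )
    return rec, gt


def generate_anesthesia_epoch(spec: SynthSpec, awake_control: bool = False) -> Recording:
    """Spontaneous epoch with burst suppression (or its awake control).

    Anesthetized: alternating burst/suppression periods; organoid channels'
    gamma POWER scaled by ``spec.anesthesia.gamma_power_scale``.  With
    ``awake_control=True`` the same construction runs with no suppression
    and no gamma scaling, giving the matched awake epoch.
    """
    an = spec.anesthesia
    fs = spec.fs_hz
    n = int(round(spec.duration_s * fs))
    n_ch = spec.n_rows * spec.n_cols
    rng = np.random.default_rng(spec.seed + (1 if awake_control else 2))
    channels = default_grid_channels(spec.n_rows, spec.n_cols)
    t = np.arange(n) / fs

    if awake_control:
        envelope = np.ones(n)
        gamma_scale = 1.0
    else:
        # deterministic alternation, seeded offset in whole seconds so
        # burst/suppression boundaries land on second boundaries: each cycle
        # of length 1/burst_rate is (1-f) burst then f suppression
        cycle_s = 1.0 / an.burst_rate_hz
        offset = float(rng.integers(0, max(1, int(round(cycle_s)))))
        phase = np.mod(t + offset, cycle_s) / cycle_s
        envelope = np.where(phase < (1.0 - an.suppression_fraction), 1.0, an.residual)
        gamma_scale = an.gamma_power_scale

    org = {i for i, c in enumerate(channels) if c.region == Region.ORGANOID}
    data = np.zeros((n_ch, n))
    for ci in range(n_ch):
        jit_slow = 1.0 + an.amp_jitter * rng.standard_normal()
        jit_gamma = 1.0 + an.amp_jitter * rng.standard_normal()
        slow = an.slow_amp_uv * jit_slow * _band_noise(rng, n, fs, (1.0, 25.0))
        g_amp = an.gamma_amp_uv * jit_gamma
        if ci in org:
            g_amp *= np.sqrt(gamma_scale)
        gamma = g_amp * _band_noise(rng, n, fs, an.gamma_band_hz)
        data[ci] = envelope * (slow + gamma) + _background_noise(rng, n, spec.noise_sd_uv)

    return Recording(
        data=data,
        fs_hz=fs,
        channels=channels,
        stimulus=None,
        state="awake" if awake_control else "anesthetized",
        provenance=f"synthetic {'awake control' if awake_control else 'anesthesia'} epoch, "
        f"seed={spec.seed}",
    )
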