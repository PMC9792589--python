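"""Morlet-wavelet time-frequency power, band power, and the organoid/cortex
power-ratio comparison.

Power is reported as one-sided spectral density (µV²/Hz): the squared
magnitude of the analytic Morlet coefficient divided by the wavelet's
equivalent noise bandwidth, so white noise of variance σ² gives a flat
density of 2σ²/fs and a pure tone of amplitude A integrates to A²/2
across frequency.  Fixed-cycle wavelets (n_cycles = 7 by default) on a
logarithmic 1-150 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import ChannelInfo, Recording, Region
from .evoked import TrialTensor

__all__ = [
    "TimeFrequencyArray",
    "BandDefinition",
    "DEFAULT_BANDS",
    "default_freq_grid",
    "morlet_spectrogram",
    "trial_averaged_spectrogram",
    "band_power",
    "region_power_ratio",
]


@dataclass
class TimeFrequencyArray:
    """(channel, frequency, time) power in µV²/Hz, with method provenance."""

    values: np.ndarray
    freqs_hz: np.ndarray
    t_axis_s: np.ndarray
    method: str = "morlet"
    params: dict | None = None


@dataclass
class BandDefinition:
    name: str
    lo_hz: float
    hi_hz: float

    def __post_init__(self) -> None:
        if not (0 < self.lo_hz < self.hi_hz):
            raise ValueError(f"invalid band {self.name}: [{self.lo_hz}, {self.hi_hz}]")


#: Conventional band edges; theta is analysed at 4-6 Hz in the phase-locking
#: module, the broader 4-8 Hz definition is used for band power.
DEFAULT_BANDS: List[BandDefinition] = [
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("low_gamma", 30.0, 60.0),
    BandDefinition("high_gamma", 60.0, 150.0),
]


def default_freq_grid(lo_hz: float = 1.0, hi_hz: float = 150.0, n: int = 60) -> np.ndarray:
    """Logarithmic frequency grid."""
    return np.geomspace(lo_hz, hi_hz, n)


def _morlet_power(x: np.ndarray, fs: float, freqs: np.ndarray, n_cycles: float) -> np.ndarray:
    """Morlet power density for one channel: (n_freqs, n_samples).

    Analytic-signal construction in the frequency domain: multiply the FFT
    by a Gaussian centred on each target frequency (sd = f/n_cycles) with
    the doubling of positive frequencies, then normalise |W|² by the
    wavelet's noise bandwidth 2·σ_f·√π.
    """
    n = x.size
    X = np.fft.fft(x)
    nu = np.fft.fftfreq(n, d=1 / fs)
    out = np.empty((freqs.size, n))
    pos = nu > 0
    for i, f in enumerate(freqs):
        sigma_f = f / n_cycles
        g = np.zeros(n)
        g[pos] = 2.0 * np.exp(-((nu[pos] - f) ** 2) / (2 * sigma_f**2))
        w = np.fft.ifft(X * g)
        out[i] = np.abs(w) ** 2 / (2 * sigma_f * np.sqrt(np.pi))
    return out


def morlet_spectrogram(
    rec: Union[Recording, np.ndarray],
    freqs_hz: Sequence[float] | None = None,
    n_cycles: float = 7.0,
    fs_hz: float | None = None,
) -> TimeFrequencyArray:
    """Morlet time-frequency power for every (included) channel.

    Accepts a :class:`Recording` or a raw (channel, sample) array with
    ``fs_hz``.  Excluded channels yield NaN rows.
    """
    if isinstance(rec, Recording):
        data, fs = rec.data, rec.fs_hz
        included = np.array([c.included for c in rec.channels])
    else:
        if fs_hz is None:
            raise ValueError("fs_hz required for a raw array")
        data, fs = np.atleast_2d(rec), float(fs_hz)
        included = np.ones(data.shape[0], dtype=bool)
    freqs = np.asarray(freqs_hz, dtype=float) if freqs_hz is not None else default_freq_grid()
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("frequency grid must be strictly increasing")
    if freqs[-1] >= fs / 2:
        raise ValueError(f"frequency grid exceeds Nyquist ({fs / 2:g} Hz)")
    n_ch, n = data.shape
    values = np.full((n_ch, freqs.size, n), np.nan)
    for ci in range(n_ch):
        if included[ci]:
            values[ci] = _morlet_power(data[ci], fs, freqs, n_cycles)
    return TimeFrequencyArray(
        values=values,
        freqs_hz=freqs,
        t_axis_s=np.arange(n) / fs,
        method="morlet",
        params={"n_cycles": n_cycles, "fs_hz": fs},
    )


def trial_averaged_spectrogram(
    tt: TrialTensor, freqs_hz: Sequence[float] | None = None, n_cycles: float = 7.0
) -> TimeFrequencyArray:
    """Mean over trials of per-trial Morlet power (stimulus-locked)."""
    if tt.n_trials < 1:
        raise ValueError("need at least one trial")
    freqs = np.asarray(freqs_hz, dtype=float) if freqs_hz is not None else default_freq_grid()
    n_trials, n_ch, n = tt.values.shape
    acc = np.zeros((n_ch, freqs.size, n))
    for k in range(n_trials):
        for ci in range(n_ch):
            acc[ci] += _morlet_power(tt.values[k, ci], tt.fs_hz, freqs, n_cycles)
    acc /= n_trials
    return TimeFrequencyArray(
        values=acc,
        freqs_hz=freqs,
        t_axis_s=tt.t_axis_s,
        method="morlet",
        params={"n_cycles": n_cycles, "fs_hz": tt.fs_hz, "n_trials": n_trials},
    )


def band_power(
    tfa: Union[TimeFrequencyArray, Recording],
    bands: Sequence[BandDefinition] = tuple(DEFAULT_BANDS),
    **morlet_kwargs,
) -> pd.DataFrame:
    """Time- and frequency-averaged power density per (channel, band).

    Rows are channel indices, columns band names, units µV²/Hz.
    """
    if isinstance(tfa, Recording):
        tfa = morlet_spectrogram(tfa, **morlet_kwargs)
    cols: Dict[str, np.ndarray] = {}
    for b in bands:
        sel = (tfa.freqs_hz >= b.lo_hz) & (tfa.freqs_hz < b.hi_hz)
        if not sel.any():
            raise ValueError(f"band {b.name} contains no grid frequencies")
        cols[b.name] = tfa.values[:, sel, :].mean(axis=(1, 2))
    return pd.DataFrame(cols)


def region_power_ratio(
    bp: pd.DataFrame,
    channels: Sequence[ChannelInfo],
    alternative: str = "less",
) -> pd.DataFrame:
    """Organoid band power as a fraction of cortex power, with a t-test.

    Per band: ratio = mean(organoid) / mean(cortex); cortex is the
    reference (ratio 1 by definition).  The p-value is a two-sample
    Student t-test across channels, one-sided (organoid < cortex) by
    default, mirroring the anesthesia contrast.
    """
    org = [i for i, c in enumerate(channels) if c.region == Region.ORGANOID and c.included]
    ctx = [i for i, c in enumerate(channels) if c.region == Region.CORTEX and c.included]
    if len(org) < 2 or len(ctx) < 2:
        raise ValueError("need at least 2 included channels per region")
    rows = []
    for band in bp.columns:
        po = bp.loc[org, band].to_numpy()
        pc = bp.loc[ctx, band].to_numpy()
        t, p = stats.ttest_ind(po, pc, alternative=alternative)
        rows.append(
            {
                "band": band,
                "organoid_ratio": float(po.mean() / pc.mean()),
                "cortex_ratio": 1.0,
                "t": float(t),
                "p_value": float(p),
                "n_organoid": len(org),
                "n_cortex": len(ctx),
            }
        )
    return pd.DataFrame(rows).set_index("band")
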