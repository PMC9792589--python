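"""In-memory data model for multichannel organoid/cortex recordings.

Conventions used throughout the package:

* voltages are microvolts (µV), times are seconds, sample index 0 is t = 0 s;
* epoch and histogram windows are half-open ``[start, end)``;
* channels live on a 4x4 grid with 500 µm pitch by default, and each carries
  a region label (``organoid`` / ``cortex`` / ``ambiguous``) assigned by the
  experimenter, never inferred from the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Optional, Sequence

import numpy as np

GRID_PITCH_UM = 500.0

__all__ = [
    "Region",
    "ChannelInfo",
    "StimulusProtocol",
    "Recording",
    "EventTrain",
    "GRID_PITCH_UM",
]


class Region(str, Enum):
    """Anatomical assignment of an electrode pad."""

    ORGANOID = "organoid"
    CORTEX = "cortex"
    AMBIGUOUS = "ambiguous"


@dataclass
class ChannelInfo:
    """Metadata for one electrode pad on the 4x4, 500 µm-pitch grid.

    ``impedance_ohm`` is the magnitude at 1 kHz; channels above the
    exclusion threshold (4 MΩ by default) are flagged ``included=False``
    by :func:`orgephys.preprocess.exclude_channels` rather than dropped.
    """

    channel_id: int
    row: int
    col: int
    region: Region = Region.AMBIGUOUS
    impedance_ohm: float = 1.4e6
    included: bool = True
    x_um: float = field(default=None)  # type: ignore[assignment]
    y_um: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not (0 <= self.row <= 3 and 0 <= self.col <= 3):
            raise ValueError(f"grid indices out of range: row={self.row}, col={self.col}")
        if self.x_um is None:
            self.x_um = self.col * GRID_PITCH_UM
        if self.y_um is None:
            self.y_um = self.row * GRID_PITCH_UM
        if self.impedance_ohm <= 0:
            raise ValueError("impedance must be positive")
        self.region = Region(self.region)

    def distance_um(self, other: "ChannelInfo") -> float:
        """Euclidean pad-to-pad distance in µm."""
        return float(np.hypot(self.x_um - other.x_um, self.y_um - other.y_um))


@dataclass
class StimulusProtocol:
    """Photic stimulation protocol: trains of light pulses.

    ``onsets_s`` are the onset times of the first pulse of each train;
    within a train, pulses of width ``pulse_width_s`` repeat at
    ``pulse_rate_hz`` for ``train_duration_s``.
    """

    onsets_s: np.ndarray
    pulse_width_s: float = 0.1
    pulse_rate_hz: float = 2.0
    train_duration_s: float = 4.0

    def __post_init__(self) -> None:
        self.onsets_s = np.asarray(self.onsets_s, dtype=float)
        if self.onsets_s.ndim != 1:
            raise ValueError("onsets_s must be 1-D")
        if self.onsets_s.size > 1 and not np.all(np.diff(self.onsets_s) > 0):
            raise ValueError("train onsets must be strictly increasing")
        if self.pulse_width_s > 1.0 / self.pulse_rate_hz + 1e-12:
            raise ValueError("pulse width exceeds the inter-pulse interval")

    @property
    def n_trials(self) -> int:
        return int(self.onsets_s.size)

    def pulse_onsets_s(self, which_pulse: int = 0) -> np.ndarray:
        """Onset time of pulse ``which_pulse`` within each train."""
        n_per_train = int(np.floor(self.train_duration_s * self.pulse_rate_hz + 1e-9))
        if not (0 <= which_pulse < n_per_train):
            raise ValueError(f"pulse index {which_pulse} outside train (n={n_per_train})")
        return self.onsets_s + which_pulse / self.pulse_rate_hz

    def all_pulse_onsets_s(self) -> np.ndarray:
        n_per_train = int(np.floor(self.train_duration_s * self.pulse_rate_hz + 1e-9))
        return (self.onsets_s[:, None] + np.arange(n_per_train) / self.pulse_rate_hz).ravel()


@dataclass
class Recording:
    """A multichannel extracellular recording.

    ``data`` is (n_channels, n_samples) in µV. ``state`` records whether the
    animal was awake or anesthetized; ``provenance`` is a free-text log that
    every processing stage appends to.
    """

    data: np.ndarray
    fs_hz: float
    channels: Sequence[ChannelInfo]
    stimulus: Optional[StimulusProtocol] = None
    state: str = "awake"
    provenance: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channel x sample)")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but {len(self.channels)} channel records"
            )
        if self.state not in ("awake", "anesthetized"):
            raise ValueError(f"unknown state {self.state!r}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def t_axis_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs_hz

    def included_indices(self) -> np.ndarray:
        return np.array([i for i, c in enumerate(self.channels) if c.included], dtype=int)

    def region_indices(self, region: Region | str, included_only: bool = True) -> np.ndarray:
        region = Region(region)
        return np.array(
            [
                i
                for i, c in enumerate(self.channels)
                if c.region == region and (c.included or not included_only)
            ],
            dtype=int,
        )

    def channel_index(self, channel_id: int) -> int:
        for i, c in enumerate(self.channels):
            if c.channel_id == channel_id:
                return i
        raise KeyError(f"no channel with id {channel_id}")

    def with_data(self, data: np.ndarray, note: str = "") -> "Recording":
        """Copy of this recording with new sample data and an appended log line."""
        prov = self.provenance + ("\n" if self.provenance and note else "") + note
        return replace(self, data=data, provenance=prov)


@dataclass
class EventTrain:
    """Detected MUA event times for one channel.

    ``threshold_multiplier`` is the (negative) multiple of the MUA-band
    standard deviation that defined the crossing threshold, and
    ``sd_estimate_uv`` the standard deviation actually used.
    """

    channel_id: int
    event_times_s: np.ndarray
    threshold_multiplier: float = -3.5
    sd_estimate_uv: float = float("nan")

    def __post_init__(self) -> None:
        self.event_times_s = np.asarray(self.event_times_s, dtype=float)
        if self.event_times_s.size > 1 and not np.all(np.diff(self.event_times_s) > 0):
            raise ValueError("event times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return int(self.event_times_s.size)
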