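"""Domain containers shared across the analysis stages.

Voltages are microvolts throughout; times are seconds for behavioral
series and milliseconds for epoch/component timing (the convention of the
ERP literature).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

PRODUCTIONS = ("MA", "MO", "AV")
SOA_LEVELS = (0.8, 1.6, 3.2)


class DegenerateSeriesError(ValueError):
    """Raised when a series has zero variance (DFA undefined)."""


@dataclass
class IKISeries:
    """One block's ordered inter-keypress intervals.

    Order is meaningful: the whole point of the fractal analysis is the
    sequential structure, so nothing here ever sorts the intervals.
    """

    participant_id: str
    production: str  # "MA" or "MO"
    soa: float  # 0.8, 1.6 or 3.2 s
    intervals: np.ndarray  # seconds, strictly positive
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=float)
        if self.intervals.ndim != 1:
            raise ValueError("intervals must be one-dimensional")
        if len(self.intervals) < 1:
            raise ValueError("empty interval series")
        if np.any(self.intervals <= 0):
            raise ValueError("all inter-keypress intervals must be > 0")
        if self.production not in ("MA", "MO"):
            raise ValueError(f"production must be MA or MO, got {self.production!r}")

    def __len__(self) -> int:
        return len(self.intervals)


@dataclass
class DFAResult:
    """Output of detrended fluctuation analysis for one series."""

    window_sizes: np.ndarray  # strictly increasing, min >= 4, max <= N//10
    fluctuations: np.ndarray  # F(n), same units as the input series
    alpha: float  # slope of log F(n) on log n
    intercept: float
    r_squared: float
    classification: str  # anti_persistent | persistent | elevated | nonstationary
    meta: dict[str, Any] = field(default_factory=dict)


@dataclass
class EpochSet:
    """Epoched multichannel EEG: epochs x channels x samples, in μV.

    ``t0_offset_ms`` is the time of the first sample relative to sound
    onset; the paper-faithful configuration is −200 ms with a 600 ms span.
    """

    data: np.ndarray
    fs: float  # Hz
    t0_offset_ms: float
    channel_labels: list[str]
    production: str  # MA | MO | AV
    soa: float
    participant_id: str
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be epochs x channels x samples")
        if self.data.shape[1] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data axis 1")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite voltages in epoch data")
        if self.production not in PRODUCTIONS:
            raise ValueError(f"unknown production condition {self.production!r}")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Per-sample time in ms relative to sound onset."""
        return self.t0_offset_ms + np.arange(self.n_samples) * 1000.0 / self.fs

    def copy_with(self, data: np.ndarray, **meta_updates: Any) -> "EpochSet":
        meta = dict(self.meta)
        meta.update(meta_updates)
        return EpochSet(
            data=data,
            fs=self.fs,
            t0_offset_ms=self.t0_offset_ms,
            channel_labels=list(self.channel_labels),
            production=self.production,
            soa=self.soa,
            participant_id=self.participant_id,
            meta=meta,
        )


@dataclass
class Waveform:
    """Trial-averaged ERP: channels x samples, in μV."""

    data: np.ndarray
    fs: float
    t0_offset_ms: float
    channel_labels: list[str]
    production: str  # MA | MO | AV | C-MA
    soa: float
    participant_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("waveform must be channels x samples")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError("channel_labels length must match data axis 0")

    @property
    def times_ms(self) -> np.ndarray:
        return self.t0_offset_ms + np.arange(self.data.shape[1]) * 1000.0 / self.fs


@dataclass
class ComponentWindow:
    """A named mean-amplitude window over an electrode pool."""

    name: str  # "N1" or "P2"
    center_ms: float
    width_ms: float  # 30 ms in the paper-faithful configuration
    electrode_pool: list[str]

    @property
    def start_ms(self) -> float:
        return self.center_ms - self.width_ms / 2.0

    @property
    def end_ms(self) -> float:
        return self.center_ms + self.width_ms / 2.0


@dataclass
class ComponentMeasure:
    """Windowed mean amplitude for one participant x condition cell."""

    participant_id: str
    production: str
    soa: float
    component: str
    mean_amplitude_uv: float


@dataclass
class SurrogateTestResult:
    """Observed vs shuffled-series F statistics for the factorial ANOVA."""

    observed_f: dict[str, float]  # per main effect, e.g. {"production", "soa"}
    surrogate_f: dict[str, np.ndarray]
    n_shuffles: int
    equivalent_p: dict[str, float]
    seed: int
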