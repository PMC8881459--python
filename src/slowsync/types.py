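"""Shared data containers for signals, spectra, phase statistics and BOLD data.

All time-domain containers store samples as ``[channel x time]`` float arrays
with an explicit sampling rate in Hz.  Spike times, event markers and epoch
windows are in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "MultichannelSignal",
    "RawRecording",
    "LfpSignal",
    "HighFreqSignal",
    "SpikeTrain",
    "EpochWindows",
    "Spectrogram",
    "CoherenceSpectrum",
    "PhaseSeries",
    "EnvelopeSeries",
    "PlvResult",
    "BoldSeries",
    "ConnectivityMap",
    "GroupDiffMap",
    "DEFAULT_BANDS",
]

#: Canonical analysis bands, Hz, half-open [low, high).
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "slow": (0.1, 1.0),
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
    "gamma": (30.0, 70.0),
}


@dataclass
class MultichannelSignal:
    """A bundle of equally sampled channels, shape ``(n_channels, n_samples)``."""

    samples: np.ndarray
    sampling_rate: float
    channel_regions: Optional[list[str]] = None

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass
class RawRecording(MultichannelSignal):
    """Wideband extracellular recording (nominally 20 kHz) with event markers."""

    events: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("raw samples must be finite")
        for name, t in self.events.items():
            if not 0 <= t <= self.duration:
                raise ValueError(f"event {name!r} at {t} s outside record")


@dataclass
class LfpSignal(MultichannelSignal):
    """Band-limited (1-250 Hz) local field potential, nominally 1 kHz."""

    band: tuple[float, float] = (1.0, 250.0)


@dataclass
class HighFreqSignal(MultichannelSignal):
    """400-3000 Hz band of the extracellular signal, used for spike detection."""

    band: tuple[float, float] = (400.0, 3000.0)


@dataclass
class SpikeTrain:
    """Sorted spike times (s) for one channel.

    ``source_threshold`` records the detection threshold when the train comes
    from threshold crossing; generator-produced trains leave it ``None``.
    Trains emitted by detection additionally satisfy ISI > 1 ms.
    """

    times: np.ndarray
    channel: int = 0
    source_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.sort(np.asarray(self.times, dtype=float).ravel())

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class EpochWindows:
    """Contiguous baseline / transition / active windows, seconds."""

    baseline: tuple[float, float]
    transition: tuple[float, float]
    active: tuple[float, float]

    def __post_init__(self) -> None:
        b, t, a = self.baseline, self.transition, self.active
        for lo, hi in (b, t, a):
            if hi < lo:
                raise ValueError("window bounds must be ordered")
        if not (b[1] == t[0] and t[1] == a[0]):
            raise ValueError("windows must be contiguous")

    def window(self, name: str) -> tuple[float, float]:
        return getattr(self, name)

    def assign(self, t: float) -> Optional[str]:
        """Window containing time ``t`` (half-open on the right)."""
        for name in ("baseline", "transition", "active"):
            lo, hi = getattr(self, name)
            if lo <= t < hi:
                return name
        return None


@dataclass
class Spectrogram:
    """Time-frequency power, ``power[frequency, time]`` in units^2/Hz."""

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    window: str = "kaiser"

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.power.shape != (self.frequencies.size, self.times.size):
            raise ValueError("power shape must be (n_freq, n_time)")
        if np.any(self.power < 0):
            raise ValueError("spectrogram power must be non-negative")

    @property
    def df(self) -> float:
        return float(np.median(np.diff(self.frequencies)))

    @property
    def dt(self) -> float:
        if self.times.size < 2:
            return float("nan")
        return float(np.median(np.diff(self.times)))


@dataclass
class CoherenceSpectrum:
    """Welch magnitude-squared coherence on a frequency grid."""

    frequencies: np.ndarray
    msc: np.ndarray
    n_segments: int
    segment_length: float = 2.0
    overlap: float = 0.5

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.msc = np.asarray(self.msc, dtype=float)
        if np.any((self.msc < -1e-9) | (self.msc > 1 + 1e-9)):
            raise ValueError("msc must lie in [0, 1]")
        self.msc = np.clip(self.msc, 0.0, 1.0)

    def band_value(self, band: tuple[float, float], reducer=np.median) -> float:
        lo, hi = band
        sel = (self.frequencies >= lo) & (self.frequencies < hi)
        if not np.any(sel):
            raise ValueError(f"band {band} does not overlap the frequency grid")
        return float(reducer(self.msc[sel]))


@dataclass
class PhaseSeries:
    """Instantaneous phase in (-pi, pi]; 0 marks the oscillation peak."""

    phase: np.ndarray
    sampling_rate: float
    band: Optional[tuple[float, float]] = None
    reliable: bool = True

    def __post_init__(self) -> None:
        phase = np.asarray(self.phase, dtype=float)
        # wrap to (-pi, pi]
        self.phase = -np.mod(-phase + np.pi, 2 * np.pi) + np.pi

    @property
    def n_samples(self) -> int:
        return self.phase.size

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.size) / self.sampling_rate


@dataclass
class EnvelopeSeries:
    """Integrated gamma-band (30-70 Hz) power per 0.5 s step."""

    power: np.ndarray
    step: float = 0.5
    band: tuple[float, float] = (30.0, 70.0)
    one_over_f_corrected: bool = False

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        if np.any(self.power < 0):
            raise ValueError("envelope power must be non-negative")

    @property
    def sampling_rate(self) -> float:
        return 1.0 / self.step


@dataclass
class PlvResult:
    """Phase-locking value with optional surrogate-based significance."""

    plv: float
    n: int
    band: Optional[tuple[float, float]] = None
    surrogate_percentile_95: Optional[float] = None
    significant: Optional[bool] = None
    preferred_phase: Optional[float] = None

    def __post_init__(self) -> None:
        if not -1e-9 <= self.plv <= 1 + 1e-9:
            raise ValueError("PLV must lie in [0, 1]")
        self.plv = float(np.clip(self.plv, 0.0, 1.0))


@dataclass
class BoldSeries:
    """4D BOLD data ``(x, y, z, t)`` with masks and motion regressors."""

    data: np.ndarray
    tr: float = 1.0
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    motion: Optional[np.ndarray] = None  # (t, 6)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BOLD data must be 4D (x, y, z, t)")
        for name, mask in self.masks.items():
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != self.data.shape[:3]:
                raise ValueError(f"mask {name!r} does not match the grid")
            self.masks[name] = mask
        if self.motion is not None:
            self.motion = np.asarray(self.motion, dtype=float)
            if self.motion.shape != (self.data.shape[3], 6):
                raise ValueError("motion must have shape (n_volumes, 6)")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[3]

    def mask_mean(self, name: str) -> np.ndarray:
        mask = self.masks[name]
        if not mask.any():
            raise ValueError(f"mask {name!r} is empty")
        return self.data[mask].mean(axis=0)


@dataclass
class ConnectivityMap:
    """Voxel-wise Pearson r against a seed-mean time course."""

    r: np.ndarray
    seed: str = "seed"
    band: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        finite = self.r[np.isfinite(self.r)]
        if finite.size and np.any(np.abs(finite) > 1 + 1e-9):
            raise ValueError("|r| must not exceed 1")


@dataclass
class GroupDiffMap:
    """Voxel-wise two-sample t map with an |t| > threshold mask."""

    t: np.ndarray
    threshold: float = 2.0
    cluster_p: Optional[float] = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)

    @property
    def suprathreshold(self) -> np.ndarray:
        return np.isfinite(self.t) & (np.abs(self.t) > self.threshold)
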