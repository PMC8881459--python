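"""Interareal and spike-field coupling statistics.

Covers Welch magnitude-squared coherence between LFP channels, the
ultra-slow (0.02-0.5 Hz) coherence of gamma-band power envelopes, Hilbert
instantaneous phase, the phase-locking value

    PLV = (1/N) | sum_j exp(i (theta_ch1(t_j) - theta_ch2(t_j))) |

with circular-shift surrogate significance (PLV must exceed the surrogate
95th percentile AND exceed 0.1), preferred phase differences, and the
locking of spikes to LFP phase (spike PLV = 1 - circular variance = resultant
length of the spike-phase distribution).
"""

from __future__ import annotations

import numpy as np
from scipy import signal

from .spectral import compute_spectrogram
from .types import (
    CoherenceSpectrum,
    EnvelopeSeries,
    LfpSignal,
    MultichannelSignal,
    PhaseSeries,
    PlvResult,
    SpikeTrain,
    Spectrogram,
)

__all__ = [
    "power_coherence",
    "gamma_envelope",
    "envelope_spectrum",
    "ultraslow_envelope_coherence",
    "instantaneous_phase",
    "lfp_plv",
    "plv_significance",
    "preferred_phase_difference",
    "spike_phase_locking",
]


def power_coherence(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate: float,
    segment_s: float = 2.0,
    overlap: float = 0.5,
) -> CoherenceSpectrum:
    """Welch magnitude-squared coherence from 2 s, 50%-overlap segments."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ValueError("signals must have equal length")
    nperseg = int(round(segment_s * sampling_rate))
    if x.size < 2 * nperseg:
        raise ValueError("record must cover at least two segments")
    noverlap = int(round(nperseg * overlap))
    freqs, msc = signal.coherence(
        x, y, fs=sampling_rate, nperseg=nperseg, noverlap=noverlap
    )
    step = nperseg - noverlap
    n_segments = (x.size - noverlap) // step
    return CoherenceSpectrum(
        frequencies=freqs,
        msc=msc,
        n_segments=int(n_segments),
        segment_length=segment_s,
        overlap=overlap,
    )


def gamma_envelope(
    lfp_channel: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] = (30.0, 70.0),
    window_s: float = 2.0,
    overlap: float = 0.75,
) -> EnvelopeSeries:
    """Gamma-band power envelope: 2 s windows, 75% overlap -> one value / 0.5 s."""
    x = np.asarray(lfp_channel, dtype=float).ravel()
    if x.size / sampling_rate < 60.0:
        raise ValueError("record must be at least 60 s to resolve 0.02 Hz")
    spec = compute_spectrogram(
        MultichannelSignal(samples=x[None, :], sampling_rate=sampling_rate),
        window_s=window_s,
        overlap=overlap,
        freq_resolution=1.0 / window_s,
    )
    lo, hi = band
    sel = (spec.frequencies >= lo) & (spec.frequencies < hi)
    power = spec.power[sel].sum(axis=0) * spec.df
    step = window_s * (1 - overlap)
    return EnvelopeSeries(power=power, step=step, band=band)


def envelope_spectrum(
    env: EnvelopeSeries, correct_one_over_f: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Welch spectrum of the envelope, optionally 1/f-corrected.

    The 1/f component is removed by a least-squares linear fit of log power
    against log frequency (over positive frequencies), subtracted in log
    space, i.e. the spectrum is divided by the fitted power law.
    """
    fs = env.sampling_rate
    nperseg = min(env.power.size, int(round(50 * fs)))
    freqs, pxx = signal.welch(
        env.power - env.power.mean(), fs=fs, nperseg=nperseg
    )
    if not correct_one_over_f:
        return freqs, pxx
    pos = (freqs > 0) & (pxx > 0)
    logf, logp = np.log10(freqs[pos]), np.log10(pxx[pos])
    slope, intercept = np.polyfit(logf, logp, 1)
    corrected = pxx.copy()
    corrected[pos] = pxx[pos] / 10 ** (intercept + slope * logf)
    return freqs, corrected


def ultraslow_envelope_coherence(
    e1: EnvelopeSeries,
    e2: EnvelopeSeries,
    band: tuple[float, float] = (0.02, 0.5),
    segment_s: float = 50.0,
) -> float:
    """Welch msc between two power envelopes, averaged over 0.02-0.5 Hz."""
    if e1.power.size != e2.power.size or e1.step != e2.step:
        raise ValueError("envelopes must be aligned")
    fs = e1.sampling_rate
    nperseg = min(e1.power.size, int(round(segment_s * fs)))
    spec = power_coherence(
        e1.power - e1.power.mean(),
        e2.power - e2.power.mean(),
        sampling_rate=fs,
        segment_s=nperseg / fs,
    )
    return spec.band_value(band, reducer=np.mean)


def instantaneous_phase(
    lfp_channel: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float] | None,
    order: int = 3,
    reliability_floor: float = 1e-6,
) -> PhaseSeries:
    """Zero-phase 3rd-order Butterworth band-pass, then analytic-signal angle.

    Phase 0 marks the band-limited oscillation's peak and +/-pi its trough.
    Channels with negligible band power are flagged unreliable.  With
    ``band=None`` the signal is taken as already band-limited and only the
    Hilbert transform is applied.
    """
    x = np.asarray(lfp_channel, dtype=float).ravel()
    if band is None:
        filtered = x
    else:
        nyq = sampling_rate / 2
        lo, hi = band
        if not 0 < lo < hi < nyq:
            raise ValueError(f"band {band} outside (0, {nyq}) Hz")
        sos = signal.butter(order, [lo / nyq, hi / nyq], btype="band", output="sos")
        filtered = signal.sosfiltfilt(sos, x)
    # judge band power on the central half, away from filter edge transients
    mid = slice(x.size // 4, 3 * x.size // 4)
    reliable = bool(
        np.var(filtered[mid]) > reliability_floor * max(np.var(x[mid]), 1e-300)
    )
    phase = np.angle(signal.hilbert(filtered))
    return PhaseSeries(
        phase=phase, sampling_rate=sampling_rate, band=band, reliable=reliable
    )


def lfp_plv(p1: PhaseSeries, p2: PhaseSeries) -> PlvResult:
    """Resultant length of the phase-difference distribution."""
    if p1.n_samples != p2.n_samples:
        raise ValueError("phase series must have equal length")
    if p1.n_samples < 2:
        raise ValueError("need at least two samples")
    diff = p1.phase - p2.phase
    resultant = np.exp(1j * diff).mean()
    return PlvResult(
        plv=float(np.abs(resultant)),
        n=p1.n_samples,
        band=p1.band,
        preferred_phase=float(np.angle(resultant)),
    )


def _circular_shift_surrogate(
    x: np.ndarray, sampling_rate: float, rng: np.random.Generator
) -> np.ndarray:
    min_shift = int(round(sampling_rate))  # >= 1 s
    if x.size <= 2 * min_shift:
        raise ValueError("record too short for a >= 1 s circular shift")
    shift = int(rng.integers(min_shift, x.size - min_shift))
    return np.roll(x, shift)


def plv_significance(
    x: np.ndarray,
    y: np.ndarray,
    sampling_rate: float,
    band: tuple[float, float],
    n_surrogates: int = 200,
    rng_seed: int = 0,
    method: str = "circular_shift",
    plv_floor: float = 0.1,
) -> PlvResult:
    """PLV between two raw channels with surrogate significance.

    Surrogates shuffle one signal in time *before* filtering: either by a
    uniform circular shift of at least 1 s (default, spectrum-preserving) or
    by full sample permutation.  The pair is significant iff its PLV exceeds
    the surrogate 95th percentile and also exceeds ``plv_floor`` (0.1).
    """
    if n_surrogates < 20:
        raise ValueError("need at least 20 surrogates")
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant signal: PLV significance undefined")
    p1 = instantaneous_phase(x, sampling_rate, band)
    p2 = instantaneous_phase(y, sampling_rate, band)
    observed = lfp_plv(p1, p2)
    rng = np.random.default_rng(rng_seed)
    surrogate_plv = np.empty(n_surrogates)
    for i in range(n_surrogates):
        if method == "circular_shift":
            ys = _circular_shift_surrogate(y, sampling_rate, rng)
        elif method == "permute":
            ys = rng.permutation(y)
        else:
            raise ValueError(f"unknown surrogate method {method!r}")
        ps = instantaneous_phase(ys, sampling_rate, band)
        surrogate_plv[i] = lfp_plv(p1, ps).plv
    p95 = float(np.percentile(surrogate_plv, 95))
    return PlvResult(
        plv=observed.plv,
        n=observed.n,
        band=band,
        surrogate_percentile_95=p95,
        significant=bool(observed.plv > p95 and observed.plv > plv_floor),
        preferred_phase=observed.preferred_phase,
    )


def preferred_phase_difference(
    p1: PhaseSeries, p2: PhaseSeries, reliability_floor: float = 0.05
) -> tuple[float, float, bool]:
    """Circular mean of (theta1 - theta2) and its resultant length.

    Returns ``(mean_angle, resultant_length, reliable)``; the mean is flagged
    unreliable when the resultant length falls below 0.05.
    """
    if p1.n_samples != p2.n_samples:
        raise ValueError("phase series must have equal length")
    resultant = np.exp(1j * (p1.phase - p2.phase)).mean()
    r = float(np.abs(resultant))
    return float(np.angle(resultant)), r, r >= reliability_floor


def spike_phase_locking(
    spikes: SpikeTrain | np.ndarray,
    phase: PhaseSeries,
    n_bins: int = 18,
) -> tuple[PlvResult, np.ndarray, np.ndarray]:
    """Locking of spikes to LFP phase.

    Spike phases are the phase samples at each spike time; the spike PLV is
    1 minus the circular variance of that distribution (i.e. its resultant
    length).  Also returns a firing-probability histogram over ``n_bins``
    phase bins (normalized to sum to 1) and its bin edges.
    """
    times = spikes.times if isinstance(spikes, SpikeTrain) else np.asarray(spikes, float)
    if times.size < 2:
        raise ValueError("need at least two spikes for a phase distribution")
    duration = phase.n_samples / phase.sampling_rate
    if np.any(times < 0) or np.any(times > duration):
        raise ValueError("spikes must fall within the phase record")
    idx = np.clip(
        np.round(times * phase.sampling_rate).astype(int), 0, phase.n_samples - 1
    )
    spike_phases = phase.phase[idx]
    resultant = np.exp(1j * spike_phases).mean()
    plv = PlvResult(
        plv=float(np.abs(resultant)),
        n=times.size,
        band=phase.band,
        preferred_phase=float(np.angle(resultant)),
    )
    edges = np.linspace(-np.pi, np.pi, n_bins + 1)
    hist, _ = np.histogram(spike_phases, bins=edges)
    hist = hist / hist.sum()
    return plv, hist, edges
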