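"""Compose wideband extracellular recordings: LFP + spike waveforms + noise."""

from __future__ import annotations

import numpy as np
from scipy import signal

from ..types import MultichannelSignal, RawRecording, SpikeTrain

__all__ = ["biphasic_template", "gen_extracellular"]


def biphasic_template(
    sampling_rate: float = 20000.0,
    duration: float = 0.001,
    amplitude: float = 1.0,
) -> np.ndarray:
    """~1 ms biphasic spike waveform: negative trough then positive rebound.

    Built from one cycle of a Hann-tapered sine so its energy sits in the
    400-3000 Hz detection band.  Peak absolute value equals ``amplitude``.
    """
    n = max(int(round(duration * sampling_rate)), 8)
    t = np.arange(n) / n
    wave = -np.sin(2 * np.pi * t) * np.hanning(n)
    return amplitude * wave / np.max(np.abs(wave))


def gen_extracellular(
    lfp: MultichannelSignal,
    spikes: SpikeTrain | list[SpikeTrain],
    waveform: np.ndarray | None = None,
    noise_sd: float = 0.0,
    sampling_rate: float = 20000.0,
    events: dict[str, float] | None = None,
    channel_regions: list[str] | None = None,
    rng_seed: int = 0,
) -> RawRecording:
    """Upsample ``lfp`` to ``sampling_rate``, insert spike waveforms, add noise.

    ``spikes`` may be one train (inserted on every channel) or one per
    channel.  Spike times outside the record are rejected.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if waveform is None:
        waveform = biphasic_template(sampling_rate)
    waveform = np.asarray(waveform, dtype=float)

    up = int(round(sampling_rate))
    down = int(round(lfp.sampling_rate))
    g = np.gcd(up, down)
    samples = signal.resample_poly(lfp.samples, up // g, down // g, axis=1)
    n = samples.shape[1]
    duration = n / sampling_rate

    trains = spikes if isinstance(spikes, list) else [spikes] * samples.shape[0]
    if len(trains) != samples.shape[0]:
        raise ValueError("need one spike train per channel")
    for ch, train in enumerate(trains):
        for t in train.times:
            if not 0 <= t <= duration:
                raise ValueError(f"spike at {t} s outside the {duration} s record")
            i0 = int(round(t * sampling_rate))
            i1 = min(i0 + waveform.size, n)
            samples[ch, i0:i1] += waveform[: i1 - i0]

    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        samples = samples + rng.normal(0.0, noise_sd, size=samples.shape)

    return RawRecording(
        samples=samples,
        sampling_rate=sampling_rate,
        channel_regions=channel_regions,
        events=events or {},
    )
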