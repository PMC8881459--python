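"""Ground-truth generator for band-limited multichannel LFP-like signals.

Each channel is a sum of sinusoidal components (with per-channel phase
offsets, so interareal phase lags are exactly known) plus independent
Gaussian noise.  Downstream coherence / phase estimators can then be tested
against the generating parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..types import MultichannelSignal

__all__ = ["LfpComponent", "LfpSpec", "gen_coupled_lfp"]


@dataclass(frozen=True)
class LfpComponent:
    """One shared sinusoid: frequency (Hz), amplitude, per-channel phase offsets (rad).

    ``channel_amplitudes`` optionally scales the common amplitude per channel
    (e.g. to confine a component to one channel).
    """

    frequency: float
    amplitude: float
    phase_offsets: tuple[float, ...] = ()
    channel_amplitudes: tuple[float, ...] = ()


@dataclass
class LfpSpec:
    components: list[LfpComponent] = field(default_factory=list)
    noise_sd: float = 0.0
    duration: float = 10.0
    sampling_rate: float = 1000.0
    n_channels: int = 2
    rng_seed: int = 0

    def validate(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_channels < 1:
            raise ValueError("n_channels must be at least 1")
        nyquist = self.sampling_rate / 2
        for comp in self.components:
            if not 0 < comp.frequency < nyquist:
                raise ValueError(
                    f"component frequency {comp.frequency} Hz outside (0, {nyquist}) Hz"
                )
            if len(comp.phase_offsets) not in (0, self.n_channels):
                raise ValueError(
                    "phase_offsets must be empty or give one offset per channel"
                )
            if len(comp.channel_amplitudes) not in (0, self.n_channels):
                raise ValueError(
                    "channel_amplitudes must be empty or give one gain per channel"
                )


def gen_coupled_lfp(spec: LfpSpec) -> MultichannelSignal:
    """Generate ``spec.n_channels`` coupled sinusoid-plus-noise channels.

    Channel ``c`` is ``sum_k a_k cos(2 pi f_k t + phi_kc)`` plus i.i.d.
    Gaussian noise of standard deviation ``spec.noise_sd``.  Identical specs
    and seeds yield byte-identical output.
    """
    spec.validate()
    n = int(round(spec.duration * spec.sampling_rate))
    t = np.arange(n) / spec.sampling_rate
    rng = np.random.default_rng(spec.rng_seed)
    out = np.zeros((spec.n_channels, n))
    for comp in spec.components:
        offsets = comp.phase_offsets or (0.0,) * spec.n_channels
        gains = comp.channel_amplitudes or (1.0,) * spec.n_channels
        for ch, (phi, g) in enumerate(zip(offsets, gains)):
            out[ch] += g * comp.amplitude * np.cos(2 * np.pi * comp.frequency * t + phi)
    if spec.noise_sd > 0:
        out += rng.normal(0.0, spec.noise_sd, size=out.shape)
    return MultichannelSignal(samples=out, sampling_rate=spec.sampling_rate)
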