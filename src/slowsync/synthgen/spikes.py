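"""Phase-locked spike-train generation from a von Mises phase distribution.

The locked / mixed scenario pair mirrors a standard in-silico check: one
train of spikes tightly concentrated at the preferred phase of a 1 Hz
carrier (concentration 20), and a second train that adds the same number of
near-uniform spikes (concentration 0.5).  Spike phases are drawn pooled over
the whole epoch (not per cycle) and mapped to times by inverting the
carrier's unwrapped phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..types import MultichannelSignal, PhaseSeries, SpikeTrain

__all__ = ["SimSpec", "gen_vonmises_spikes", "make_sim_scenarios", "carrier_phase"]


@dataclass
class SimSpec:
    """Configuration of the locked / mixed spiking scenarios."""

    epoch_length: float = 10.0
    carrier_frequency: float = 1.0
    n_locked_spikes: int = 100
    kappa_locked: float = 20.0
    n_diffuse_spikes: int = 100
    kappa_diffuse: float = 0.5
    preferred_phase: float = np.pi
    kernel_width: float = 0.1
    sampling_rate: float = 1000.0
    #: spike phases are drawn pooled over the epoch, not cycle by cycle
    pooled_over_epoch: bool = True
    rng_seed: int = 0

    def validate(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        if self.kappa_locked < 0 or self.kappa_diffuse < 0:
            raise ValueError("kappa values must be non-negative")
        if self.n_locked_spikes < 0 or self.n_diffuse_spikes < 0:
            raise ValueError("spike counts must be non-negative")
        if self.carrier_frequency <= 0 or self.sampling_rate <= 0:
            raise ValueError("frequencies must be positive")


def carrier_phase(
    frequency: float, duration: float, sampling_rate: float
) -> PhaseSeries:
    """Phase of ``cos(2 pi f t)``: 0 at the peak, pi at the trough."""
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    return PhaseSeries(phase=2 * np.pi * frequency * t, sampling_rate=sampling_rate)


def gen_vonmises_spikes(
    phase: PhaseSeries,
    n_spikes: int,
    kappa: float,
    preferred_phase: float,
    rng_seed: int = 0,
) -> SpikeTrain:
    """Place ``n_spikes`` spikes at times where the carrier attains phases
    drawn from von Mises(preferred_phase, kappa).

    Cycles are assigned uniformly at random over the epoch, so locking is
    pooled across the whole record.  Exactly ``n_spikes`` events are emitted;
    no refractory rule is applied here.
    """
    if kappa < 0:
        raise ValueError("kappa must be non-negative")
    if n_spikes < 0:
        raise ValueError("n_spikes must be non-negative")
    if n_spikes == 0:
        return SpikeTrain(times=np.empty(0))

    rng = np.random.default_rng(rng_seed)
    unwrapped = np.unwrap(phase.phase)
    if np.any(np.diff(unwrapped) <= 0):
        raise ValueError("carrier phase must be strictly increasing after unwrapping")
    if kappa > 0:
        draws = rng.vonmises(preferred_phase, kappa, size=n_spikes)
    else:  # kappa == 0 is the uniform circular distribution
        draws = rng.uniform(-np.pi, np.pi, size=n_spikes)

    # map each drawn phase into a uniformly chosen full cycle of the carrier
    start, stop = unwrapped[0], unwrapped[-1]
    n_cycles = int(np.floor((stop - start) / (2 * np.pi)))
    if n_cycles < 1:
        raise ValueError("phase series must cover at least one full carrier cycle")
    cycles = rng.integers(0, n_cycles, size=n_spikes)
    target = start + 2 * np.pi * cycles + np.mod(draws - start, 2 * np.pi)
    times = np.interp(target, unwrapped, phase.times)
    return SpikeTrain(times=times)


def make_sim_scenarios(
    spec: SimSpec,
) -> tuple[SpikeTrain, SpikeTrain, MultichannelSignal]:
    """Build the locked-only and mixed spike trains plus their cosine carrier.

    The locked train holds ``n_locked_spikes`` drawn with ``kappa_locked``;
    the mixed train is the union of the locked train and ``n_diffuse_spikes``
    additional draws with ``kappa_diffuse``.  Counts are pre-refractory.
    """
    spec.validate()
    phase = carrier_phase(spec.carrier_frequency, spec.epoch_length, spec.sampling_rate)
    locked = gen_vonmises_spikes(
        phase,
        spec.n_locked_spikes,
        spec.kappa_locked,
        spec.preferred_phase,
        rng_seed=spec.rng_seed,
    )
    diffuse = gen_vonmises_spikes(
        phase,
        spec.n_diffuse_spikes,
        spec.kappa_diffuse,
        spec.preferred_phase,
        rng_seed=spec.rng_seed + 1,
    )
    mixed = SpikeTrain(times=np.concatenate([locked.times, diffuse.times]))
    t = phase.times
    carrier = MultichannelSignal(
        samples=np.cos(2 * np.pi * spec.carrier_frequency * t)[None, :],
        sampling_rate=spec.sampling_rate,
    )
    return locked, mixed, carrier
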