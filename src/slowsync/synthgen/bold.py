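"""Synthetic 4D BOLD datasets with known region-to-region coupling.

Each named region is driven by unit-variance low-frequency (< 0.1 Hz) latent
signals.  The coupling table gives, per region, its loading in [0, 1] onto
any region's latent; by default a region loads 1.0 onto its own latent.  A
voxel in region ``r`` is therefore

    x(t) = sum_k W[r, k] * s_k(t)  (+ HRF convolution)  + drift + noise

so the population seed-target correlation is controlled exactly: a target
loading ``w`` onto the seed latent alone has ``corr = w / sqrt(w^2 + sd^2/P)``
against a noiseless seed, with ``P`` the latent band power after filtering.
The ventricle carries an independent nuisance latent only; motion regressors
are emitted alongside (and optionally leaked into the data).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from ..types import BoldSeries

__all__ = ["BoldSpec", "box_mask", "gen_bold_dataset"]


def box_mask(
    shape: tuple[int, int, int],
    corner: tuple[int, int, int],
    size: tuple[int, int, int],
) -> np.ndarray:
    """Boolean mask for a 0-based, inclusive-exclusive voxel box."""
    mask = np.zeros(shape, dtype=bool)
    sl = []
    for c, s, dim in zip(corner, size, shape):
        if c < 0 or c + s > dim:
            raise ValueError("mask box exceeds the grid")
        sl.append(slice(c, c + s))
    mask[tuple(sl)] = True
    return mask


def _lowfreq_latent(n: int, tr: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian signal band-limited below 0.1 Hz."""
    x = rng.standard_normal(n)
    nyq = 0.5 / tr
    sos = signal.butter(4, min(0.08 / nyq, 0.99), btype="low", output="sos")
    y = signal.sosfiltfilt(sos, x)
    sd = y.std()
    return y / sd if sd > 0 else y


def double_gamma_hrf(tr: float, duration: float = 30.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, unit sum."""
    from scipy.stats import gamma as gamma_dist

    t = np.arange(0, duration, tr)
    h = gamma_dist.pdf(t, 6) - gamma_dist.pdf(t, 16) / 6.0
    return h / h.sum()


@dataclass
class BoldSpec:
    shape: tuple[int, int, int] = (16, 16, 4)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    #: region -> {latent region -> loading in [0, 1]}; default: identity
    coupling: dict[str, dict[str, float]] = field(default_factory=dict)
    tr: float = 1.0
    n_volumes: int = 500
    noise_sd: float = 0.1
    drift_amplitude: float = 0.0
    signal_amplitude: float = 1.0
    ventricle_amplitude: float = 1.0
    motion_leak: float = 0.0
    hrf: bool = False
    rng_seed: int = 0

    def validate(self) -> None:
        if self.n_volumes < 2 or self.tr <= 0:
            raise ValueError("need n_volumes >= 2 and positive TR")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, mask in self.masks.items():
            if np.asarray(mask).shape != self.shape:
                raise ValueError(f"mask {name!r} exceeds or mismatches the grid")
        for region, row in self.coupling.items():
            for latent, w in row.items():
                if not 0 <= w <= 1:
                    raise ValueError(
                        f"coupling[{region!r}][{latent!r}] = {w} outside [0, 1]"
                    )


def gen_bold_dataset(spec: BoldSpec) -> BoldSeries:
    """Generate a BoldSeries per ``spec`` with known ground-truth coupling."""
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    nt = spec.n_volumes
    regions = [name for name in spec.masks if name != "ventricle"]

    latents = {name: _lowfreq_latent(nt, spec.tr, rng) for name in regions}
    ventricle_latent = _lowfreq_latent(nt, spec.tr, rng)

    # motion: six slowly varying nuisance traces
    motion = np.cumsum(rng.normal(0, 0.02, size=(nt, 6)), axis=0)
    motion -= motion.mean(axis=0)

    data = np.zeros(spec.shape + (nt,))
    kernel = double_gamma_hrf(spec.tr) if spec.hrf else None
    for region in regions:
        row = spec.coupling.get(region, {region: 1.0})
        tc = np.zeros(nt)
        for latent, w in row.items():
            if latent not in latents:
                raise ValueError(f"unknown latent region {latent!r}")
            tc += w * latents[latent]
        if kernel is not None:
            tc = signal.fftconvolve(tc, kernel)[:nt]
        data[spec.masks[region]] += spec.signal_amplitude * tc

    if "ventricle" in spec.masks:
        data[spec.masks["ventricle"]] += spec.ventricle_amplitude * ventricle_latent

    if spec.drift_amplitude > 0:
        t = np.arange(nt) * spec.tr
        drift = spec.drift_amplitude * (
            t / t[-1] - 0.5 + 0.3 * np.cos(2 * np.pi * 0.005 * t)
        )
        data += drift

    if spec.motion_leak > 0:
        data += spec.motion_leak * motion.sum(axis=1)

    if spec.noise_sd > 0:
        data += rng.normal(0, spec.noise_sd, size=data.shape)

    masks = {k: np.asarray(v, dtype=bool) for k, v in spec.masks.items()}
    if "brain" not in masks:
        masks["brain"] = np.ones(spec.shape, dtype=bool)
    return BoldSeries(data=data, tr=spec.tr, masks=masks, motion=motion)
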