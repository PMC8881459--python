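"""Seed-based resting-state BOLD connectivity at desk scale.

Preprocessing drops equilibration volumes, regresses out six motion traces
plus the mean ventricular signal (optionally the global intracerebral mean),
band-passes 0.01-0.1 Hz with a zero-phase filter, and optionally smooths
spatially.  Connectivity is the Pearson correlation of every voxel against
the seed-mean time course; group contrasts use voxel-wise two-sample t tests
on Fisher-z-transformed r with an |t| > 2 threshold and an optional
permutation max-cluster correction.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage, signal, stats
from sklearn.cluster import KMeans

from .types import BoldSeries, ConnectivityMap, GroupDiffMap

__all__ = [
    "preprocess_bold",
    "seed_map",
    "ap_profile",
    "kmeans_partition",
    "group_diff_map",
]


def _regress_out(data2d: np.ndarray, regressors: np.ndarray) -> np.ndarray:
    """OLS residuals of each row of ``data2d`` (voxel x time) on regressors."""
    t = data2d.shape[1]
    design = np.column_stack([np.ones(t), regressors])
    beta, *_ = np.linalg.lstsq(design, data2d.T, rcond=None)
    return data2d - (design @ beta).T


def preprocess_bold(
    series: BoldSeries,
    band: tuple[float, float] | None = (0.01, 0.1),
    drop: int = 120,
    global_signal: bool = False,
    smooth_fwhm_mm: float = 0.0,
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0),
    filter_order: int = 2,
) -> BoldSeries:
    """Drop volumes, regress nuisance covariates, band-pass, optionally smooth."""
    nt = series.n_volumes
    if nt <= drop + 6 * filter_order:
        raise ValueError("too few volumes after dropping for stable filtering")
    data = series.data[..., drop:]
    motion = series.motion[drop:] if series.motion is not None else None
    masks = series.masks

    regs = []
    if motion is not None:
        regs.append(motion)
    if "ventricle" in masks:
        if not masks["ventricle"].any():
            raise ValueError("ventricle mask is empty")
        regs.append(data[masks["ventricle"]].mean(axis=0)[:, None])
    if global_signal:
        brain = masks.get("brain", np.ones(data.shape[:3], dtype=bool))
        if not brain.any():
            raise ValueError("brain mask is empty")
        regs.append(data[brain].mean(axis=0)[:, None])

    shape = data.shape[:3]
    flat = data.reshape(-1, data.shape[3])
    if regs:
        flat = _regress_out(flat, np.column_stack(regs))
    else:
        flat = flat - flat.mean(axis=1, keepdims=True)

    if band is not None:
        nyq = 0.5 / series.tr
        lo, hi = band
        sos = signal.butter(
            filter_order, [lo / nyq, min(hi / nyq, 0.999)], btype="band", output="sos"
        )
        flat = signal.sosfiltfilt(sos, flat, axis=1)
    data = flat.reshape(shape + (flat.shape[1],))

    if smooth_fwhm_mm > 0:
        sigmas = [
            smooth_fwhm_mm / (2 * np.sqrt(2 * np.log(2))) / z for z in voxel_size_mm
        ]
        data = ndimage.gaussian_filter(data, sigma=sigmas + [0.0])

    return BoldSeries(data=data, tr=series.tr, masks=masks, motion=motion)


def _corr_with(data: np.ndarray, reference: np.ndarray) -> np.ndarray:
    """Pearson r of every voxel time course against ``reference``."""
    flat = data.reshape(-1, data.shape[3])
    ref = reference - reference.mean()
    ref_ss = float(np.dot(ref, ref))
    x = flat - flat.mean(axis=1, keepdims=True)
    num = x @ ref
    denom = np.sqrt((x**2).sum(axis=1) * ref_ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), np.nan)
    return np.clip(r, -1.0, 1.0, out=r).reshape(data.shape[:3])


def seed_map(series: BoldSeries, seed: str | np.ndarray = "seed") -> ConnectivityMap:
    """Voxel-wise Pearson r against the seed-mean time course."""
    mask = series.masks[seed] if isinstance(seed, str) else np.asarray(seed, bool)
    if not mask.any():
        raise ValueError("seed mask is empty")
    r = _corr_with(series.data, series.data[mask].mean(axis=0))
    return ConnectivityMap(r=r, seed=seed if isinstance(seed, str) else "seed")


def ap_profile(
    series: BoldSeries,
    seed: str | np.ndarray,
    chain: list[str | np.ndarray],
) -> np.ndarray:
    """Correlation of the seed mean with each midline seed, anterior->posterior.

    Voxels shared between the reference seed and a chain seed are excluded
    from the chain seed with a warning.
    """
    if len(chain) < 1:
        raise ValueError("need at least one midline seed")
    seed_mask = series.masks[seed] if isinstance(seed, str) else np.asarray(seed, bool)
    ref = series.data[seed_mask].mean(axis=0)
    ref = ref - ref.mean()
    out = np.empty(len(chain))
    for i, item in enumerate(chain):
        mask = series.masks[item] if isinstance(item, str) else np.asarray(item, bool)
        if np.any(mask & seed_mask):
            warnings.warn(f"chain seed {i} overlaps the reference seed; excluding overlap")
            mask = mask & ~seed_mask
        tc = series.data[mask].mean(axis=0)
        tc = tc - tc.mean()
        out[i] = float(
            np.dot(tc, ref) / np.sqrt(np.dot(tc, tc) * np.dot(ref, ref))
        )
    return out


def kmeans_partition(
    profiles: np.ndarray, k: int, rng_seed: int = 0, n_init: int = 10
) -> np.ndarray:
    """K-means labels over voxel connectivity profiles, deterministic per seed."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2:
        raise ValueError("profiles must be (n_voxels, n_features)")
    if not np.all(np.isfinite(profiles)):
        raise ValueError("profiles must be finite")
    if k < 1 or k > profiles.shape[0]:
        raise ValueError("k must be between 1 and the number of voxels")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=rng_seed)
    return km.fit_predict(profiles)


def group_diff_map(
    maps_a: list[ConnectivityMap],
    maps_b: list[ConnectivityMap],
    threshold: float = 2.0,
    fisher_z: bool = True,
    n_permutations: int = 0,
    rng_seed: int = 0,
) -> GroupDiffMap:
    """Voxel-wise two-sample t map (group A minus B) on Fisher-z'd r.

    With ``n_permutations > 0`` a max-cluster-size permutation p (label
    shuffles on the suprathreshold mask) replaces external cluster FWE
    correction.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least two maps per group")
    shape = maps_a[0].r.shape
    stack_a = np.stack([m.r for m in maps_a], axis=-1)
    stack_b = np.stack([m.r for m in maps_b], axis=-1)
    if stack_b.shape[:3] != shape:
        raise ValueError("map grids differ between groups")
    if fisher_z:
        stack_a = np.arctanh(np.clip(stack_a, -0.999999, 0.999999))
        stack_b = np.arctanh(np.clip(stack_b, -0.999999, 0.999999))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, _ = stats.ttest_ind(stack_a, stack_b, axis=-1)

    cluster_p = None
    if n_permutations > 0:
        observed = _max_cluster(np.abs(t) > threshold)
        rng = np.random.default_rng(rng_seed)
        pooled = np.concatenate([stack_a, stack_b], axis=-1)
        na = stack_a.shape[-1]
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled.shape[-1])
            pa, pb = pooled[..., perm[:na]], pooled[..., perm[na:]]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                tp, _ = stats.ttest_ind(pa, pb, axis=-1)
            if _max_cluster(np.abs(tp) > threshold) >= observed:
                exceed += 1
        cluster_p = (exceed + 1) / (n_permutations + 1)
    return GroupDiffMap(t=t, threshold=threshold, cluster_p=cluster_p)


def _max_cluster(mask: np.ndarray) -> int:
    labels, n = ndimage.label(np.nan_to_num(mask.astype(float)) > 0)
    if n == 0:
        return 0
    return int(np.max(ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))))
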