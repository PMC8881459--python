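"""File formats: flat binary + JSON sidecar for ephys, CSV spike times,
NIfTI-1 for BOLD, HDF5 for spectra, YAML for generator specs."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .synthgen import BoldSpec, LfpComponent, LfpSpec, SimSpec
from .types import BoldSeries, LfpSignal, MultichannelSignal, RawRecording, Spectrogram, SpikeTrain

__all__ = [
    "write_recording",
    "read_recording",
    "write_spike_trains",
    "read_spike_trains",
    "write_bold",
    "read_bold",
    "write_spectrogram",
    "read_spectrogram",
    "load_lfp_spec",
    "load_sim_spec",
    "load_bold_spec",
]


def write_recording(rec: MultichannelSignal, stem: Path | str) -> None:
    """Little-endian float32, channel-major flat binary + JSON sidecar."""
    stem = Path(stem)
    rec.samples.astype("<f4").tofile(stem.with_suffix(".bin"))
    sidecar = {
        "fs": rec.sampling_rate,
        "channels": rec.n_channels,
        "regions": rec.channel_regions,
        "events": getattr(rec, "events", {}),
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def read_recording(stem: Path | str, raw: bool = True) -> MultichannelSignal:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    data = np.fromfile(stem.with_suffix(".bin"), dtype="<f4").astype(float)
    samples = data.reshape(meta["channels"], -1)
    if raw:
        return RawRecording(
            samples=samples,
            sampling_rate=meta["fs"],
            channel_regions=meta.get("regions"),
            events=meta.get("events") or {},
        )
    return LfpSignal(
        samples=samples, sampling_rate=meta["fs"], channel_regions=meta.get("regions")
    )


def write_spike_trains(trains: list[SpikeTrain], path: Path | str) -> None:
    rows = [
        {"channel": t.channel, "time_s": time} for t in trains for time in t.times
    ]
    pd.DataFrame(rows, columns=["channel", "time_s"]).to_csv(path, index=False)


def read_spike_trains(path: Path | str) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    return [
        SpikeTrain(times=g["time_s"].to_numpy(), channel=int(ch))
        for ch, g in df.groupby("channel")
    ]


def write_bold(series: BoldSeries, out_dir: Path | str, stem: str = "bold") -> None:
    """NIfTI-1 series (TR in the header) + mask images + motion text file."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(series.data.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, series.tr))
    nib.save(img, out_dir / f"{stem}.nii")
    for name, mask in series.masks.items():
        nib.save(
            nib.Nifti1Image(mask.astype(np.uint8), affine=np.eye(4)),
            out_dir / f"{stem}_mask_{name}.nii",
        )
    if series.motion is not None:
        np.savetxt(out_dir / f"{stem}_motion.txt", series.motion, fmt="%.8f")


def read_bold(out_dir: Path | str, stem: str = "bold") -> BoldSeries:
    out_dir = Path(out_dir)
    img = nib.load(out_dir / f"{stem}.nii")
    tr = float(img.header.get_zooms()[3]) or 1.0
    masks = {}
    for p in sorted(out_dir.glob(f"{stem}_mask_*.nii")):
        name = p.stem.replace(f"{stem}_mask_", "")
        masks[name] = np.asanyarray(nib.load(p).dataobj).astype(bool)
    motion_path = out_dir / f"{stem}_motion.txt"
    motion = np.loadtxt(motion_path) if motion_path.exists() else None
    return BoldSeries(
        data=np.asanyarray(img.dataobj).astype(float), tr=tr, masks=masks, motion=motion
    )


def write_spectrogram(spec: Spectrogram, path: Path | str) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("power", data=spec.power)
        f.create_dataset("frequencies", data=spec.frequencies)
        f.create_dataset("times", data=spec.times)
        f.attrs["window"] = spec.window


def read_spectrogram(path: Path | str) -> Spectrogram:
    with h5py.File(path, "r") as f:
        return Spectrogram(
            power=f["power"][()],
            frequencies=f["frequencies"][()],
            times=f["times"][()],
            window=str(f.attrs.get("window", "kaiser")),
        )


def load_lfp_spec(path: Path | str) -> LfpSpec:
    cfg = yaml.safe_load(Path(path).read_text())
    comps = [
        LfpComponent(
            frequency=c["frequency"],
            amplitude=c["amplitude"],
            phase_offsets=tuple(c.get("phase_offsets", ())),
            channel_amplitudes=tuple(c.get("channel_amplitudes", ())),
        )
        for c in cfg.pop("components", [])
    ]
    return LfpSpec(components=comps, **cfg)


def load_sim_spec(path: Path | str) -> SimSpec:
    return SimSpec(**(yaml.safe_load(Path(path).read_text()) or {}))


def load_bold_spec(path: Path | str) -> BoldSpec:
    from .synthgen import box_mask

    cfg = yaml.safe_load(Path(path).read_text())
    shape = tuple(cfg.pop("shape"))
    masks = {
        name: box_mask(shape, tuple(box["corner"]), tuple(box["size"]))
        for name, box in cfg.pop("masks", {}).items()
    }
    return BoldSpec(shape=shape, masks=masks, **cfg)
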