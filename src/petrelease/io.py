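"""On-disk formats: NIfTI volumes with JSON sidecars, sinogram archives.

All volumes are written as NIfTI-1 with a diagonal affine carrying the
voxel size in mm; 4D dynamic images get a JSON sidecar with the frame
timing and decay-correction state.  Micro-parameter maps are one NIfTI per
parameter plus a sidecar with the structural constraints and seed.
Sinogram sets are NumPy ``.npz`` archives with a JSON metadata entry.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from petrelease.acquisition import DynamicImage, Framing, SinogramSet
from petrelease.phantom import MicroParamMap

__all__ = [
    "save_volume",
    "load_volume",
    "save_dynamic",
    "load_dynamic",
    "save_mask",
    "load_mask",
    "save_microparam_map",
    "load_microparam_map",
    "save_sinograms",
    "load_sinograms",
    "sha256_of",
]


class FormatError(ValueError):
    pass


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def save_volume(path, data: np.ndarray, voxel_size_mm: float) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), _affine(voxel_size_mm))
    img.header.set_zooms((voxel_size_mm,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))
    return path


def load_volume(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    zooms = img.header.get_zooms()
    return data, float(zooms[0])


def save_mask(path, mask: np.ndarray, voxel_size_mm: float) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(mask, dtype=np.int16), _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def load_mask(path):
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.int16), float(img.header.get_zooms()[0])


def save_dynamic(path, dynimg: DynamicImage) -> tuple:
    """Write a 4D NIfTI plus its frame-timing JSON sidecar."""
    path = Path(path)
    save_volume(path, dynimg.data, dynimg.voxel_size_mm)
    sidecar = path.with_suffix("").with_suffix("")  # strip .nii.gz
    sidecar = Path(str(sidecar) + ".json")
    meta = {
        "frame_starts_s": dynimg.framing.starts_s.tolist(),
        "frame_durations_s": dynimg.framing.durations_s.tolist(),
        "decay_corrected": bool(dynimg.decay_corrected),
        "voxel_size_mm": dynimg.voxel_size_mm,
    }
    sidecar.write_text(json.dumps(meta, indent=2))
    return path, sidecar


def load_dynamic(path) -> DynamicImage:
    path = Path(path)
    data, voxel = load_volume(path)
    sidecar = Path(str(path.with_suffix("").with_suffix("")) + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing timing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    framing = Framing(
        np.asarray(meta["frame_starts_s"]), np.asarray(meta["frame_durations_s"])
    )
    if data.ndim != 4 or data.shape[3] != framing.n_frames:
        raise FormatError(
            f"sidecar frame count {framing.n_frames} does not match 4D extent "
            f"{data.shape}"
        )
    return DynamicImage(data, framing, voxel, bool(meta["decay_corrected"]))


_PARAM_NAMES = ("K1", "k2", "k3", "k4", "VB")


def save_microparam_map(directory, pmap: MicroParamMap, prefix: str = "truth") -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in _PARAM_NAMES:
        save_volume(directory / f"{prefix}_{name}.nii.gz", getattr(pmap, name),
                    pmap.voxel_size_mm)
    save_mask(directory / f"{prefix}_labels.nii.gz", pmap.labels, pmap.voxel_size_mm)
    sidecar = directory / f"{prefix}_params.json"
    sidecar.write_text(json.dumps(
        {"voxel_size_mm": pmap.voxel_size_mm, "space": pmap.space,
         "meta": pmap.meta}, indent=2))
    return directory


def load_microparam_map(directory, prefix: str = "truth") -> MicroParamMap:
    directory = Path(directory)
    arrays = {}
    for name in _PARAM_NAMES:
        arrays[name], voxel = load_volume(directory / f"{prefix}_{name}.nii.gz")
    labels, _ = load_mask(directory / f"{prefix}_labels.nii.gz")
    meta = json.loads((directory / f"{prefix}_params.json").read_text())
    return MicroParamMap(
        K1=arrays["K1"].astype(float), k2=arrays["k2"].astype(float),
        k3=arrays["k3"].astype(float), k4=arrays["k4"].astype(float),
        VB=arrays["VB"].astype(float), labels=labels,
        voxel_size_mm=meta["voxel_size_mm"], space=meta.get("space", "phantom"),
        meta=meta.get("meta", {}),
    )


def save_sinograms(path, sino: SinogramSet) -> Path:
    path = Path(path)
    np.savez_compressed(
        path,
        prompts=sino.prompts.astype(np.int64),
        trues=sino.trues.astype(np.float32),
        randoms=sino.randoms.astype(np.float32),
        scatter=sino.scatter.astype(np.float32),
        attenuation=sino.attenuation.astype(np.float32),
        frame_starts_s=sino.framing.starts_s,
        frame_durations_s=sino.framing.durations_s,
        meta=json.dumps({"count_scale": sino.count_scale, **sino.meta}),
    )
    return path if path.suffix == ".npz" else path.with_suffix(path.suffix + ".npz")


def load_sinograms(path) -> SinogramSet:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        framing = Framing(z["frame_starts_s"], z["frame_durations_s"])
        return SinogramSet(
            prompts=z["prompts"].astype(float),
            trues=z["trues"].astype(float),
            randoms=z["randoms"].astype(float),
            scatter=z["scatter"].astype(float),
            attenuation=z["attenuation"].astype(float),
            count_scale=float(meta.pop("count_scale")),
            framing=framing,
            meta=meta,
        )


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()
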