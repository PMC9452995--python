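"""File formats: PNG / NIfTI images and a portable array container.

Images travel as 8-bit grayscale PNG (display convention, values clipped
and rounded to 0–255) or as NIfTI-1 single-slice volumes (float, lossless).
Complex k-space data and boolean masks travel in a simple portable
container: a ``.npy`` binary payload next to a ``.json`` sidecar recording
shape, dtype, the DFT convention and any provenance (mask pattern,
fraction, seed) — readable by any numpy without this package.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

from .sampling import KSpace, SamplingMask

__all__ = [
    "write_image",
    "read_image",
    "save_array",
    "load_array",
    "save_mask",
    "load_mask",
    "save_kspace",
    "load_kspace",
]

DFT_CONVENTION = "orthonormal, DC-centred (fftshift)"


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a magnitude image as 8-bit PNG or NIfTI-1, by extension."""
    path = Path(path)
    img = np.abs(image) if np.iscomplexobj(image) else np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D image")
    if path.suffix == ".png":
        iio.imwrite(path, np.clip(np.round(img), 0, 255).astype(np.uint8))
    elif path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        nib.save(nib.Nifti1Image(img.astype(np.float64), affine=np.eye(4)), path)
    else:
        raise ValueError(f"unsupported image extension: {path.name}")


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2-D image (PNG or NIfTI-1) as a float array."""
    path = Path(path)
    if path.suffix == ".png":
        arr = np.asarray(iio.imread(path), dtype=float)
        if arr.ndim == 3:  # collapse an RGB(A) read of a gray image
            arr = arr[..., 0]
        return arr
    if path.suffix == ".nii" or path.name.endswith(".nii.gz"):
        arr = np.asarray(nib.load(path).get_fdata(), dtype=float)
        return np.squeeze(arr)
    raise ValueError(f"unsupported image extension: {path.name}")


def save_array(path: str | Path, arr: np.ndarray, meta: dict | None = None) -> None:
    """Write ``path.npy`` + ``path.json`` (shape/dtype/convention sidecar)."""
    base = Path(path)
    base.parent.mkdir(parents=True, exist_ok=True)
    np.save(base.with_suffix(".npy"), arr)
    sidecar = {
        "shape": list(arr.shape),
        "dtype": str(arr.dtype),
        "dft_convention": DFT_CONVENTION,
    }
    if meta:
        sidecar.update(meta)
    base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_array(path: str | Path) -> tuple[np.ndarray, dict]:
    base = Path(path)
    arr = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return arr, meta


def save_mask(path: str | Path, mask: SamplingMask) -> None:
    save_array(
        path,
        mask.support,
        meta={
            "kind": "sampling_mask",
            "pattern": mask.pattern,
            "fraction": mask.fraction,
            "seed": mask.seed,
        },
    )


def load_mask(path: str | Path) -> SamplingMask:
    arr, meta = load_array(path)
    if meta.get("kind") != "sampling_mask":
        raise ValueError(f"{path}: not a sampling-mask container")
    return SamplingMask(
        support=arr.astype(bool),
        pattern=meta.get("pattern", "custom"),
        seed=int(meta.get("seed", 0)),
    )


def save_kspace(path: str | Path, y: KSpace) -> None:
    """Store samples and mask side by side (``<path>.npy/json`` + ``<path>_mask``)."""
    save_array(path, y.samples, meta={"kind": "kspace"})
    base = Path(path)
    save_mask(base.with_name(base.stem + "_mask"), y.mask)


def load_kspace(path: str | Path) -> KSpace:
    arr, meta = load_array(path)
    if meta.get("kind") != "kspace":
        raise ValueError(f"{path}: not a k-space container")
    base = Path(path)
    mask = load_mask(base.with_name(base.stem + "_mask"))
    return KSpace(samples=arr.astype(complex), mask=mask)
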