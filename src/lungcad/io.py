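"""File I/O: PNG/TIFF slices, NIfTI stacks with phase-tag sidecars, models.

Intensity convention: images are stored as 16-bit integers (PNG/TIFF) or
float NIfTI and presented to the pipeline as float arrays scaled to
[0, 1] (min–max over the file for integer inputs with unknown range,
plain /65535 for our own 16-bit exports).
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import nibabel as nib
import numpy as np

__all__ = [
    "read_image",
    "write_image",
    "write_mask",
    "read_stack",
    "write_stack",
    "read_sequences",
    "write_sequences",
]


def read_image(path: str | Path) -> np.ndarray:
    """Load a 2-D slice (PNG/TIFF/NIfTI) as float in [0, 1]."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    else:
        data = np.asarray(iio.imread(path)).astype(float)
    if data.ndim != 2:
        data = np.squeeze(data)
    lo, hi = data.min(), data.max()
    if hi > 1.0:
        data = (data - lo) / (hi - lo) if hi > lo else np.zeros_like(data)
    return data


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write a [0, 1] float image as 16-bit PNG/TIFF or float NIfTI."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(np.asarray(image, dtype=np.float32), np.eye(4)),
                 str(path))
    else:
        scaled = np.clip(np.asarray(image, dtype=float), 0, 1)
        iio.imwrite(path, (scaled * 65535).astype(np.uint16))


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    """Write an integer label mask as 8-bit PNG or integer NIfTI."""
    path = Path(path)
    if path.suffix in (".nii", ".gz"):
        nib.save(nib.Nifti1Image(np.asarray(mask, dtype=np.int16), np.eye(4)),
                 str(path))
    else:
        iio.imwrite(path, np.asarray(mask, dtype=np.uint8))


def read_stack(path: str | Path) -> tuple[np.ndarray, list[float] | None]:
    """Load a 3-D/4-D NIfTI stack plus phase tags from its JSON sidecar."""
    path = Path(path)
    data = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
    sidecar = path.with_suffix("").with_suffix(".json") \
        if path.suffix == ".nii" else Path(str(path) + ".json")
    tags = None
    if sidecar.exists():
        tags = json.loads(sidecar.read_text()).get("phase_tags")
    return data, tags


def write_stack(path: str | Path, frames: np.ndarray,
                phase_tags: list[float] | None = None) -> None:
    """Write frames (T, H, W) as NIfTI-1 with phase tags in a sidecar JSON."""
    path = Path(path)
    arr = np.asarray(frames, dtype=np.float32)
    nib.save(nib.Nifti1Image(np.moveaxis(arr, 0, -1), np.eye(4)), str(path))
    if phase_tags is not None:
        sidecar = Path(str(path).removesuffix(".nii") + ".json")
        sidecar.write_text(json.dumps({"phase_tags": list(map(float, phase_tags))}))


def read_sequences(path: str | Path) -> list[np.ndarray]:
    """Read symbol sequences: one whitespace-separated line per sequence."""
    lines = Path(path).read_text().strip().splitlines()
    return [np.array(line.split(), dtype=np.int64) for line in lines if line.strip()]


def write_sequences(path: str | Path, sequences) -> None:
    Path(path).write_text(
        "\n".join(" ".join(str(int(s)) for s in seq) for seq in sequences) + "\n")
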