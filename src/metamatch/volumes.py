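"""3D anatomical volumes: NIfTI I/O, center cropping, per-image mean normalization."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = ["VolumeSample", "read_volume", "write_volume", "center_crop", "mean_normalize"]


@dataclass
class VolumeSample:
    """One participant's T1-like intensity grid plus intracranial volume (mm³)."""

    intensities: np.ndarray
    icv: float
    participant_id: str
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D grid, got ndim={self.intensities.ndim}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume intensities must be finite")
        if not (np.isfinite(self.icv) and self.icv > 0):
            raise ValueError(f"ICV must be positive, got {self.icv}")
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]


def read_volume(path: str | Path, icv: float, participant_id: str | None = None) -> VolumeSample:
    """Read a 3D NIfTI-1 volume; ICV is supplied separately (from a table)."""
    path = Path(path)
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    pid = participant_id if participant_id is not None else path.name.split(".")[0]
    return VolumeSample(data, icv, pid, affine=np.asarray(img.affine))


def write_volume(sample: VolumeSample, path: str | Path) -> None:
    img = nib.Nifti1Image(sample.intensities.astype(np.float32), sample.affine)
    nib.save(img, str(Path(path)))


def center_crop(vol: np.ndarray, target_shape: Sequence[int]) -> np.ndarray:
    """Crop a 3D grid to ``target_shape`` about its center.

    When a margin is odd the extra voxel is dropped from the high-index side,
    i.e. the low-side offset is floor((size − target)/2).
    """
    vol = np.asarray(vol)
    if vol.ndim != 3:
        raise ValueError(f"expected 3D input, got ndim={vol.ndim}")
    target = tuple(int(t) for t in target_shape)
    if len(target) != 3 or any(t <= 0 for t in target):
        raise ValueError(f"target shape must be 3 positive ints, got {target_shape}")
    for axis, (s, t) in enumerate(zip(vol.shape, target)):
        if t > s:
            raise ValueError(f"target {t} exceeds input size {s} on axis {axis}")
    lo = [(s - t) // 2 for s, t in zip(vol.shape, target)]
    sl = tuple(slice(l, l + t) for l, t in zip(lo, target))
    return vol[sl]


def mean_normalize(vol: np.ndarray) -> np.ndarray:
    """Divide a volume by its mean intensity, so the output has mean 1."""
    vol = np.asarray(vol, dtype=float)
    m = vol.mean()
    if m == 0 or not np.isfinite(m):
        raise ValueError("cannot mean-normalize a volume with zero or non-finite mean")
    return vol / m
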