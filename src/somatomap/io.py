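"""NIfTI and table I/O helpers shared across stages."""

from __future__ import annotations

import numpy as np
import pandas as pd

import nibabel as nib

__all__ = [
    "save_volume",
    "load_volume",
    "save_events",
    "load_events",
]


def _affine(voxel_size_mm) -> np.ndarray:
    sizes = np.broadcast_to(voxel_size_mm, (3,)).astype(float)
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = sizes
    return aff


def save_volume(path, data: np.ndarray, voxel_size_mm=1.5) -> None:
    """Write a 3D/4D array as float32 NIfTI-1 with a diagonal affine."""
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))


def load_volume(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; returns (data, voxel sizes in mm)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), np.asarray(img.header.get_zooms()[:3])


def save_events(path, events, trial_duration_s: float = 1.0) -> None:
    """Write (onset_s, finger) events as a tab-separated table."""
    df = pd.DataFrame(events, columns=["onset_s", "finger"])
    df.insert(1, "duration_s", trial_duration_s)
    df.to_csv(path, sep="\t", index=False)


def load_events(path) -> list[tuple[float, int]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["onset_s"].astype(float), df["finger"].astype(int)))
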