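"""NIfTI read/write helpers for 2D slices."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np


def write_nifti(path: str | Path, array: np.ndarray, pixel_spacing: float) -> Path:
    """Write a 2D array as a single-slice float32 NIfTI."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = np.asarray(array, dtype=np.float32)[:, :, None]
    affine = np.diag([pixel_spacing, pixel_spacing, 1.0, 1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_nifti(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a single-slice NIfTI back to (2D array, pixel spacing)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim == 3:
        data = data[:, :, 0]
    spacing = float(img.header.get_zooms()[0])
    return data, spacing
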