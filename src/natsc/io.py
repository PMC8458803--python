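"""NIfTI-1 volume I/O helpers (isotropic voxel size stored in the header)."""

from __future__ import annotations

import nibabel as nib
import numpy as np


def save_volume(path, data, voxel_size: float):
    """Write a 3-D or 4-D array as NIfTI-1 with an isotropic-diagonal affine."""
    data = np.asarray(data)
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms((voxel_size,) * 3 + ((1.0,) if data.ndim == 4 else ()))
    nib.save(img, str(path))


def load_volume(path):
    """Read a NIfTI volume; returns (data, voxel_size)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj), float(img.header.get_zooms()[0])
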