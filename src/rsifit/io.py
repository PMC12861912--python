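"""Reading and writing signal stacks, b-value files and parameter maps.

Conventions
-----------
* b-value files follow the FSL single-line convention: whitespace-separated
  ascending values.
* In memory a signal stack is ``(n_bvalues, *spatial)``.  NIfTI files store
  the b dimension last (``x, y, z, b``) and are transposed on load; NumPy
  ``.npy`` files and CSV files (one row per voxel, one column per b-value)
  are also accepted for desk-scale work.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .diffusion import BValueSchedule
from .exceptions import InvalidInputError


def read_bvals(path) -> BValueSchedule:
    """Read an FSL-style whitespace-separated b-value file."""
    text = Path(path).read_text().split()
    if not text:
        raise InvalidInputError(f"empty b-value file: {path}")
    return BValueSchedule(tuple(float(v) for v in text))


def write_bvals(schedule: BValueSchedule, path) -> None:
    Path(path).write_text(" ".join(f"{v:g}" for v in schedule.values) + "\n")


def _is_nifti(path: Path) -> bool:
    return path.name.endswith((".nii", ".nii.gz"))


def load_signal_stack(path) -> np.ndarray:
    """Load a signal stack, returning ``(n_b, *spatial)``."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        data = np.asanyarray(nib.load(str(path)).dataobj, dtype=float)
        if data.ndim < 2:
            raise InvalidInputError("NIfTI stack must be at least 2-D")
        return np.moveaxis(data, -1, 0)
    if path.suffix == ".npy":
        return np.load(path)
    if path.suffix == ".csv":
        # rows = voxels, columns = b-values -> (n_b, n_voxels)
        return pd.read_csv(path, header=None).to_numpy(dtype=float).T
    raise InvalidInputError(f"unsupported stack format: {path.suffix!r}")


def save_signal_stack(stack: np.ndarray, path) -> None:
    """Save a ``(n_b, *spatial)`` stack in the format implied by suffix."""
    path = Path(path)
    stack = np.asarray(stack, dtype=float)
    if _is_nifti(path):
        import nibabel as nib

        img = nib.Nifti1Image(np.moveaxis(stack, 0, -1), affine=np.eye(4))
        nib.save(img, str(path))
    elif path.suffix == ".npy":
        np.save(path, stack)
    elif path.suffix == ".csv":
        pd.DataFrame(stack.reshape(stack.shape[0], -1).T).to_csv(
            path, header=False, index=False
        )
    else:
        raise InvalidInputError(f"unsupported stack format: {path.suffix!r}")


def save_parameter_map(values: np.ndarray, path) -> None:
    """Save one parameter image (NaN outside the fitted mask)."""
    path = Path(path)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(np.asarray(values, float), np.eye(4)), str(path))
    elif path.suffix == ".npy":
        np.save(path, values)
    elif path.suffix == ".csv":
        np.savetxt(path, np.atleast_2d(values), delimiter=",")
    else:
        raise InvalidInputError(f"unsupported map format: {path.suffix!r}")
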