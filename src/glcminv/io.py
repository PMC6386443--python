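"""Reading images and writing GLCMs/features to disk.

2D images are read with imageio (PNG) or tifffile (TIFF); 3D volumes with
nibabel (NIfTI).  Masks use the same formats with nonzero meaning inside
the region of interest.  GLCMs are written as dense CSV matrices or JSON
objects; feature vectors as one-row-per-image CSV or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .features import FeatureVector
from .glcm import GLCMDistribution

NIFTI_SUFFIXES = (".nii", ".nii.gz")
TIFF_SUFFIXES = (".tif", ".tiff")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path: str | Path) -> np.ndarray:
    """Read a 2D (PNG/TIFF) or 3D (NIfTI) gray-scale image as a float array."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image: {path}")
    if _is_nifti(path):
        import nibabel as nib

        return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if path.suffix.lower() in TIFF_SUFFIXES:
        import tifffile

        arr = tifffile.imread(str(path))
    else:
        import imageio.v3 as iio

        arr = iio.imread(str(path))
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        # RGB(A) -> luminance
        arr = arr[..., 0] * 0.2989 + arr[..., 1] * 0.587 + arr[..., 2] * 0.114
    return arr


def read_mask(path: str | Path) -> np.ndarray:
    """Read a binary ROI mask; any nonzero value counts as inside."""
    return read_image(path) != 0


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an array to PNG/TIFF (rescaled to 16-bit) or NIfTI (as-is)."""
    path = Path(path)
    arr = np.asarray(image, dtype=float)
    if _is_nifti(path):
        import nibabel as nib

        nib.save(nib.Nifti1Image(arr, affine=np.eye(4)), str(path))
        return
    lo, hi = arr.min(), arr.max()
    scaled = np.zeros_like(arr) if hi == lo else (arr - lo) / (hi - lo)
    data = np.round(scaled * 65535).astype(np.uint16)
    if path.suffix.lower() in TIFF_SUFFIXES:
        import tifffile

        tifffile.imwrite(str(path), data)
    else:
        import imageio.v3 as iio

        iio.imwrite(str(path), data)


def glcm_to_csv(glcm: GLCMDistribution, path: str | Path) -> None:
    np.savetxt(path, glcm.matrix, delimiter=",")


def glcm_to_json(glcm: GLCMDistribution, path: str | Path) -> None:
    payload = {
        "n_levels": glcm.n_levels,
        "variant": glcm.variant,
        "matrix": glcm.matrix.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def glcm_from_json(path: str | Path) -> GLCMDistribution:
    payload = json.loads(Path(path).read_text())
    return GLCMDistribution(
        matrix=np.asarray(payload["matrix"], dtype=float),
        n_levels=int(payload["n_levels"]),
        variant=payload["variant"],
    )


def features_to_frame(
    rows: Sequence[FeatureVector], ids: Optional[Sequence[str]] = None
) -> pd.DataFrame:
    """Stack feature vectors into a table with id, variant and n_levels columns."""
    records = []
    for k, fv in enumerate(rows):
        rec: Dict[str, object] = {
            "id": ids[k] if ids is not None else k,
            "variant": fv.variant,
            "n_levels": fv.n_levels,
        }
        rec.update(fv.values)
        records.append(rec)
    return pd.DataFrame(records)
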