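"""Reading and writing MetaImage (.mhd/.raw) and NIfTI (.nii/.nii.gz) volumes.

SimpleITK does the heavy lifting.  On disk the fastest-varying axis is x;
SimpleITK hands the array back as ``[z, y, x]`` which we transpose so that the
in-memory convention of :mod:`jointatlas.volumes` holds: array axis 0 pairs
with ``spacing[0]`` (the x spacing of the file).  Spacing and origin survive a
round trip; direction cosines other than identity are not supported.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .volumes import LA_LABEL_MAP, ImageVolume, LabelVolume

_SUPPORTED_SUFFIXES = (".mhd", ".nii", ".nii.gz")


def _check_path(path: str | Path) -> str:
    p = str(path)
    if not any(p.endswith(s) for s in _SUPPORTED_SUFFIXES):
        raise ValueError(f"unsupported volume format: {p} (expected one of {_SUPPORTED_SUFFIXES})")
    return p


def read_image(path: str | Path) -> ImageVolume:
    """Read a scalar volume, returning intensities as float64."""
    img = sitk.ReadImage(_check_path(path))
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0).astype(np.float64)
    return ImageVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()))


def write_image(vol: ImageVolume, path: str | Path) -> None:
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, _check_path(path))


def read_labels(path: str | Path, label_map: dict[int, str] | None = None) -> LabelVolume:
    """Read an integer label volume.

    If a sidecar ``<stem>.labels.json`` exists next to the file it supplies
    the label map; otherwise the left-atrium roster is assumed.
    """
    p = _check_path(path)
    img = sitk.ReadImage(p)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.round(data)
        if not np.allclose(data, rounded):
            raise ValueError(f"{p}: label volume contains non-integer values")
        data = rounded.astype(np.int16)
    if label_map is None:
        sidecar = Path(_sidecar_path(p))
        if sidecar.exists():
            label_map = {int(k): v for k, v in json.loads(sidecar.read_text()).items()}
        else:
            label_map = dict(LA_LABEL_MAP)
    return LabelVolume(data, tuple(img.GetSpacing()), tuple(img.GetOrigin()), label_map)


def write_labels(vol: LabelVolume, path: str | Path) -> None:
    """Write an integer label volume plus a sidecar JSON with the label map."""
    p = _check_path(path)
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0).astype(np.int16)))
    img.SetSpacing(vol.spacing)
    img.SetOrigin(vol.origin)
    sitk.WriteImage(img, p)
    Path(_sidecar_path(p)).write_text(json.dumps({str(k): v for k, v in vol.label_map.items()}, indent=1))


def _sidecar_path(p: str) -> str:
    for s in _SUPPORTED_SUFFIXES:
        if p.endswith(s):
            return p[: -len(s)] + ".labels.json"
    raise ValueError(p)
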