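"""In-memory containers for 3D image and label volumes.

Conventions used throughout the package
---------------------------------------
* Voxel indices are 0-based.  ``data[i, j, k]`` lives at the physical point
  ``origin + (i, j, k) * spacing`` (millimetres); axis 0 of the array pairs
  with ``spacing[0]``, and so on.  No axis permutation is ever applied
  in-memory; file readers/writers take care of the conversion from the
  on-disk axis order.
* All geometry (spacing, origin, transform parameters) is expressed in
  physical millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Anatomical label roster carried end-to-end: background, the LA chamber,
#: the four pulmonary veins and the appendage.
LA_LABEL_MAP: dict[int, str] = {
    0: "background",
    1: "LA_chamber",
    2: "LSPV",
    3: "LIPV",
    4: "RSPV",
    5: "RIPV",
    6: "LAA",
}

#: Foreground labels making up the whole left atrium.
LA_FOREGROUND_LABELS: tuple[int, ...] = (1, 2, 3, 4, 5, 6)


@dataclass(frozen=True)
class Grid:
    """Geometry of a voxel lattice: shape, spacing (mm/voxel) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) < 1 for s in self.shape):
            raise ValueError(f"grid shape must be three axes each >= 1, got {self.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"grid spacing must be three positive values, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    def physical_points(self) -> np.ndarray:
        """Physical coordinates of every voxel, shape ``(*shape, 3)``."""
        axes = [self.origin[a] + np.arange(self.shape[a]) * self.spacing[a] for a in range(3)]
        pts = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1)
        return pts

    def to_index(self, points: np.ndarray) -> np.ndarray:
        """Map physical points (…, 3) to continuous voxel indices."""
        return (np.asarray(points, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def to_physical(self, indices: np.ndarray) -> np.ndarray:
        """Map (continuous) voxel indices (…, 3) to physical points."""
        return np.asarray(self.origin) + np.asarray(indices, dtype=float) * np.asarray(self.spacing)

    def center(self) -> np.ndarray:
        """Physical coordinate of the grid centre."""
        return self.to_physical((np.asarray(self.shape, dtype=float) - 1.0) / 2.0)

    def extent_mm(self) -> np.ndarray:
        """Physical side lengths of the grid in mm."""
        return (np.asarray(self.shape, dtype=float) - 1.0) * np.asarray(self.spacing)


@dataclass
class ImageVolume:
    """A 3D scalar image on a regular grid with physical geometry.

    Parameters
    ----------
    data:
        3D float array of intensities.
    spacing:
        Voxel size (mm) per array axis.
    origin:
        Physical coordinate (mm) of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3 or any(s < 1 for s in self.data.shape):
            raise ValueError(f"image data must be 3D with each axis >= 1, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume | LabelVolume") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.spacing, self.origin)


@dataclass
class LabelVolume:
    """A 3D integer label volume sharing grid geometry with an image.

    Every voxel value must be a key of ``label_map``; the default roster is
    the left-atrium anatomy (chamber, four pulmonary veins, appendage).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    label_map: dict[int, str] = field(default_factory=lambda: dict(LA_LABEL_MAP))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if not np.issubdtype(self.data.dtype, np.integer):
            if not np.all(self.data == np.round(self.data)):
                raise ValueError("label data must be integer-valued")
            self.data = self.data.astype(np.int16)
        else:
            self.data = self.data.astype(np.int16)
        if self.data.ndim != 3:
            raise ValueError(f"label data must be 3D, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacing components must be > 0, got {self.spacing}")
        present = set(np.unique(self.data).tolist())
        unknown = present - set(self.label_map)
        if unknown:
            raise ValueError(f"label values {sorted(unknown)} not in label_map {sorted(self.label_map)}")

    @property
    def grid(self) -> Grid:
        return Grid(self.data.shape, self.spacing, self.origin)

    def same_grid(self, other: "ImageVolume | LabelVolume") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def binary(self, labels: tuple[int, ...] = LA_FOREGROUND_LABELS) -> np.ndarray:
        """Boolean mask of the union of the given labels."""
        return np.isin(self.data, labels)

    def copy(self) -> "LabelVolume":
        return LabelVolume(self.data.copy(), self.spacing, self.origin, dict(self.label_map))
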