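"""Voxel-grid geometry for anisotropic confocal stacks.

All physical quantities are in micrometres.  Axis order is ``(z, y, x)``
throughout the package: confocal stacks are acquired as a stack of xy
optical sections with a coarser axial step, so the first array axis is the
anisotropic one.  Voxel centres sit at ``origin + (index + 0.5) * voxel_size``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default confocal voxel size (dz, dy, dx) in um: 63x oil objective,
#: zoom 1, 0.32 um z-interval.
DEFAULT_VOXEL_SIZE = (0.32, 0.13, 0.13)

CHANNEL_ROLES = ("cellfill", "puncta", "marker")  # plus "presyn:<type>"


@dataclass(frozen=True)
class VoxelGridSpec:
    """Shape, physical voxel size and origin of a 3D stack.

    Parameters
    ----------
    shape : tuple of int
        ``(nz, ny, nx)`` voxel counts.
    voxel_size : tuple of float
        ``(dz, dy, dx)`` in um.  Defaults to the standard confocal
        acquisition geometry (0.32, 0.13, 0.13).
    origin : tuple of float
        Physical position of the grid corner (um).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3:
            raise ValueError(f"grid must be 3D, got shape {self.shape!r}")
        if any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be positive, got {self.shape!r}")
        if any(float(v) <= 0 for v in self.voxel_size):
            raise ValueError(
                f"voxel sizes must be positive, got {self.voxel_size!r}"
            )
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(
            self, "voxel_size", tuple(float(v) for v in self.voxel_size)
        )
        object.__setattr__(
            self, "origin", tuple(float(v) for v in self.origin)
        )

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    @property
    def extent(self) -> np.ndarray:
        """Physical size of the grid (um), shape (3,)."""
        return np.asarray(self.shape) * np.asarray(self.voxel_size)

    def voxel_centers(self, indices: np.ndarray) -> np.ndarray:
        """Physical centres (um) of voxels given integer indices, shape (n, 3)."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return (
            np.asarray(self.origin)
            + (idx + 0.5) * np.asarray(self.voxel_size)
        )

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Integer voxel indices containing physical points (um), shape (n, 3)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = (pts - np.asarray(self.origin)) / np.asarray(self.voxel_size)
        return np.floor(rel).astype(np.int64)

    def contains_point(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points falling inside the grid."""
        idx = self.point_to_index(points)
        return np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)

    def axes_um(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis voxel-centre coordinates in um."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.voxel_size[a]
            for a in range(3)
        )

    def to_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "voxel_size": list(self.voxel_size),
            "origin": list(self.origin),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VoxelGridSpec":
        return cls(
            shape=tuple(d["shape"]),
            voxel_size=tuple(d.get("voxel_size", DEFAULT_VOXEL_SIZE)),
            origin=tuple(d.get("origin", (0.0, 0.0, 0.0))),
        )


@dataclass
class VoxelChannel:
    """One fluorescence channel: a non-negative 3D intensity grid.

    ``role`` identifies what the channel images: ``cellfill`` (cytosolic
    fill of the target cell), ``puncta`` (postsynaptic puncta label),
    ``presyn:<type>`` (presynaptic neurite label of one interneuron class,
    e.g. ``presyn:PV``) or ``marker`` (presynaptic active-zone marker).
    """

    data: np.ndarray
    grid: VoxelGridSpec
    role: str = "puncta"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"channel data must be 3D, got ndim={self.data.ndim}")
        if tuple(self.data.shape) != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("channel intensities must be finite")
        if np.any(self.data < 0):
            raise ValueError("channel intensities must be non-negative")
        base = self.role.split(":", 1)[0]
        if base not in CHANNEL_ROLES and base != "presyn":
            raise ValueError(f"unknown channel role {self.role!r}")

    @property
    def presyn_type(self) -> str | None:
        """Cell-type label for presynaptic channels, else None."""
        if self.role.startswith("presyn:"):
            return self.role.split(":", 1)[1]
        return None
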