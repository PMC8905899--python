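"""Voxel lattice container shared by every pipeline stage.

All grids in a case (physical dose, LET_d, RBE, HU, structure masks) live on
one isotropic lattice.  Conventions: 0-based indices, axis order (x, y, z),
world coordinates in mm with voxel-center mapping
``world = origin + (index + 0.5) * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class VoxelGrid:
    """A 3-D scalar field on an isotropic voxel lattice.

    Parameters
    ----------
    data
        Array of shape ``(nx, ny, nz)``.
    spacing
        Isotropic voxel spacing in mm (default 1.5 mm).
    origin
        World coordinate (mm) of the corner of voxel (0, 0, 0).
    """

    data: np.ndarray
    spacing: float = 1.5
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("VoxelGrid data must be 3-D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing) ** 3

    @property
    def voxel_volume_cm3(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_lattice(self, other: "VoxelGrid", atol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= atol
            and bool(np.allclose(self.origin, other.origin, atol=atol))
        )

    def voxel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates (mm) of voxel centers, one 1-D array per axis."""
        return tuple(
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing
            for a in range(3)
        )  # type: ignore[return-value]

    def copy_with(self, data: np.ndarray) -> "VoxelGrid":
        if data.shape != self.shape:
            raise ValueError("replacement data has different shape")
        return VoxelGrid(data, spacing=self.spacing, origin=self.origin.copy())


def require_same_lattice(*grids: VoxelGrid) -> None:
    ref = grids[0]
    for g in grids[1:]:
        if not ref.same_lattice(g):
            raise ValueError(
                f"grids are not co-registered: {ref.shape}/{ref.spacing} vs "
                f"{g.shape}/{g.spacing}"
            )
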