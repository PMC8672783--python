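"""Core in-memory containers shared across the pipeline.

Image stacks are stored in ``(z, y, x)`` axis order, matching the page
order of a multi-page TIFF: axis 0 is the optical (slow, coarsely
sampled) axis, axes 1-2 are the in-plane axes.  Physical voxel spacing
is carried alongside the raw array so that every downstream geometric
quantity (volumes, surface areas, structuring-element radii) is
computed in micrometres rather than voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ImageStack:
    """A 3D grayscale image with anisotropic physical voxel spacing.

    Parameters
    ----------
    data
        Array of shape ``(nz, ny, nx)``; any numeric dtype.
    spacing
        Physical size of one voxel along ``(z, y, x)`` in micrometres.
        The default matches confocal acquisition at 0.088 um in-plane
        and 0.480 um between slices.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (0.480, 0.088, 0.088)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"stack must be 3D, got shape {arr.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in um^3."""
        return float(np.prod(self.spacing))

    @property
    def physical_volume(self) -> float:
        """Total imaged volume in um^3."""
        return self.voxel_volume * self.data.size

    def mip(self) -> np.ndarray:
        """Maximum-intensity projection along the optical (z) axis."""
        return self.data.max(axis=0)


#: number of um^3 in one mm^3, used when reporting lacunar densities.
UM3_PER_MM3: float = 1e9


@dataclass
class LacunaRecord:
    """One segmented osteocyte lacuna.

    ``volume`` and ``surface_area`` are in physical units (um^3 / um^2);
    ``centroid`` is in um in ``(z, y, x)`` order.  ``canaliculi_count``
    is filled by the canaliculus counting step and is ``0`` until then.
    """

    label: int
    volume: float
    surface_area: float
    centroid: tuple[float, float, float]
    canaliculi_count: int = 0
    touches_border: bool = False


@dataclass
class LCNMetrics:
    """Scan-level lacunar-canalicular summary.

    Attributes
    ----------
    lac_density
        Lacunae per mm^3 of imaged bone (Lac.N).
    mean_lac_volume
        Mean lacunar volume in um^3 (Lac.V); NaN when no lacunae.
    mean_canaliculi_per_lacuna
        Mean canaliculi per lacuna (Cn/Lac); NaN when no lacunae.
    canalicular_density
        Mean over lacunae of canaliculi count / lacunar surface area,
        in 1/um^2 (Cn.N); NaN when no lacunae.
    acellular_area_fraction
        Percent of projected area devoid of stain, or NaN if not
        computed for this scan.
    n_lacunae
        Number of retained (interior, volume-filtered) lacunae.
    """

    lac_density: float
    mean_lac_volume: float
    mean_canaliculi_per_lacuna: float
    canalicular_density: float
    acellular_area_fraction: float = float("nan")
    n_lacunae: int = 0
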