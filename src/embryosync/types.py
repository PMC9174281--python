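"""Core data containers shared across the pipeline.

Coordinates follow one convention everywhere: *isotropic units*, where one
unit equals the in-plane pixel pitch ``dx`` (0.8 µm by default).  The axial
coordinate is stored pre-scaled by the anisotropy factor ``dz/dx`` (2.5 by
default), so dividing a stored ``z`` by that factor recovers the slice index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Default voxel pitch (dx, dy, dz) in µm.
DEFAULT_SPACING: tuple[float, float, float] = (0.8, 0.8, 2.0)


@dataclass
class VoxelGrid:
    """One 3D fluorescence volume at a single time point.

    Parameters
    ----------
    intensities : ndarray, shape (nz, ny, nx)
        Non-negative intensity volume, indexed ``(z, y, x)``.
    spacing : (dx, dy, dz)
        Voxel pitch in µm.
    time : float
        Acquisition time in hours.
    frame_index : int
        Position of this volume in the time series.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    time: float = 0.0
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3D (z, y, x) array")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if np.any(self.intensities < 0):
            raise ValueError("intensities must be non-negative")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be strictly positive")

    @property
    def anisotropy(self) -> float:
        """Axial-to-lateral pitch ratio dz/dx (2.5 for 0.8/0.8/2.0 µm)."""
        return self.spacing[2] / self.spacing[0]

    def copy_with(self, intensities: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(
            intensities=intensities,
            spacing=self.spacing,
            time=self.time,
            frame_index=self.frame_index,
        )


@dataclass
class NucleusObservation:
    """One detected (or simulated) nucleus centroid at one frame.

    ``x``/``y``/``z`` are isotropic units (1 unit = dx µm); ``z`` carries the
    dz/dx pre-scaling, so ``z / anisotropy`` is the slice index.
    """

    embryo_id: str
    frame_index: int
    time: float
    x: float
    y: float
    z: float
    volume: float = 0.0
    label: int = -1


@dataclass
class DetectionParams:
    """Tunable knobs of the nucleus-detection chain (voxel units)."""

    background_radius: float = 10.0
    equalize_mode: str = "stretch"  # "stretch" | "hist" | "none"
    denoise_radius: int = 1
    min_component_size: int = 64
    subdivision_factor: float = 1.5
    max_subdivision_iters: int = 10

    def __post_init__(self) -> None:
        if self.background_radius <= 0 or self.denoise_radius < 0:
            raise ValueError("radii must be positive")
        if self.min_component_size <= 0 or self.subdivision_factor <= 0:
            raise ValueError("size threshold and subdivision factor must be positive")
        if self.max_subdivision_iters < 1:
            raise ValueError("max_subdivision_iters must be >= 1")
        if self.equalize_mode not in ("stretch", "hist", "none"):
            raise ValueError("equalize_mode must be 'stretch', 'hist' or 'none'")


OBSERVATION_COLUMNS = [
    "embryo_id",
    "frame",
    "time_h",
    "x",
    "y",
    "z",
    "volume_voxels",
]


def observations_to_frame(observations) -> "pd.DataFrame":
    """Stack NucleusObservation records into the tidy coordinate table."""
    import pandas as pd

    rows = [
        (o.embryo_id, o.frame_index, o.time, o.x, o.y, o.z, o.volume)
        for o in observations
    ]
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def frame_to_observations(df) -> list[NucleusObservation]:
    """Inverse of :func:`observations_to_frame`."""
    return [
        NucleusObservation(
            embryo_id=str(r.embryo_id),
            frame_index=int(r.frame),
            time=float(r.time_h),
            x=float(r.x),
            y=float(r.y),
            z=float(r.z),
            volume=float(r.volume_voxels),
        )
        for r in df.itertuples(index=False)
    ]
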