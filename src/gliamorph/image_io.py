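"""Reading and writing z-stacks with physical voxel spacing.

The in-memory container is :class:`VoxelGrid`: a 3D intensity array in
fixed (z, y, x) axis order plus the physical voxel spacing ``(dz, dy, dx)``
in micrometres. Spacing always comes from the user (config or call site),
never from TIFF tags, so a run is reproducible bit-for-bit regardless of
what the acquisition software wrote into the file. Intensities are kept as
raw counts; thresholding operates on the native histogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelGrid", "read_stack", "write_stack"]


@dataclass
class VoxelGrid:
    """A single-channel 3D image stack with anisotropic voxel spacing.

    Parameters
    ----------
    data:
        3D scalar intensity array in (z, y, x) order.
    spacing:
        Physical voxel pitch ``(dz, dy, dx)`` in µm; all strictly positive.
    source_id:
        Free-text provenance string (file path, phantom seed, ...).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    source_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D (z, y, x) array, got ndim={self.data.ndim}")
        if any(s < 1 for s in self.data.shape):
            raise ValueError(f"every dimension must be >= 1, got shape {self.data.shape}")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3:
            raise ValueError("spacing must be (dz, dy, dx)")
        if not all(np.isfinite(s) and s > 0 for s in spacing):
            raise ValueError(f"spacing values must be strictly positive and finite, got {spacing}")
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.spacing
        return dz * dy * dx


def read_stack(path: str | Path, spacing: tuple[float, float, float]) -> VoxelGrid:
    """Read a single-channel multi-page TIFF into a :class:`VoxelGrid`.

    Page order maps to z. Intensities are preserved without rescaling.

    Raises
    ------
    FileNotFoundError / OSError
        If the file cannot be read.
    ValueError
        If the image carries more than one channel (the error names the
        channel count) or the spacing is invalid.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        n_channels = 1
        for ch_axis in ("S", "C"):
            if ch_axis in axes:
                n_channels *= series.shape[axes.index(ch_axis)]
        if n_channels != 1:
            raise ValueError(
                f"{path} has {n_channels} channels; expected a single-channel stack"
            )
        data = series.asarray()
    data = np.squeeze(data)
    if data.ndim == 2:  # single page
        data = data[np.newaxis, :, :]
    if data.ndim != 3:
        raise ValueError(f"{path}: cannot interpret axes {axes!r} as a (z, y, x) stack")
    return VoxelGrid(data=data, spacing=spacing, source_id=str(path))


def write_stack(grid: VoxelGrid, path: str | Path) -> Path:
    """Write a :class:`VoxelGrid` as a multi-page grayscale TIFF.

    Lossless round-trip with :func:`read_stack` for integer dtypes.
    """
    path = Path(path)
    tifffile.imwrite(path, grid.data, photometric="minisblack")
    return path
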