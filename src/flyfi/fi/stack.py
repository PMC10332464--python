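"""Calibrated z-stacks: TIFF I/O and the 2-D maximum-intensity projection.

The MIP exists for presentation only; every quantitative path in this
package consumes the 3-D stack directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

DEFAULT_Z_INTERVAL_UM = 1.08


@dataclass
class ZStack:
    """3-D voxel intensity array with physical calibration.

    ``voxels`` is indexed ``(slice, row, col)``; intensities are
    non-negative.  ``pixel_size_um`` is the in-plane pixel pitch and
    ``z_interval_um`` the axial spacing between optical sections.
    """

    voxels: np.ndarray
    pixel_size_um: float
    z_interval_um: float = DEFAULT_Z_INTERVAL_UM
    bit_depth: int = 16
    brain_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        if v.ndim != 3 or v.shape[0] < 1:
            raise ValueError("voxels must be a 3-D (slice, row, col) array")
        if np.any(v < 0):
            raise ValueError("intensities must be non-negative")
        if not (self.pixel_size_um > 0 and self.z_interval_um > 0):
            raise ValueError("calibration values must be positive")
        self.voxels = v

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.voxels.shape)


def read_zstack(path, pixel_size_um: float | None = None,
                z_interval_um: float | None = None) -> ZStack:
    """Read a single-channel multi-page TIFF as a :class:`ZStack`.

    Calibration comes from the arguments when given, else from the TIFF
    tags (ImageJ ``spacing`` + X resolution); if neither supplies a
    value the file is rejected.  Multi-channel / RGB input is rejected:
    quantification is defined on one fluorophore channel.
    """
    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        if page.samplesperpixel != 1:
            raise ValueError("single-channel required (got multi-channel or RGB TIFF)")
        axes = tif.series[0].axes
        if any(ax in axes for ax in ("C", "S")):
            raise ValueError("single-channel required (got multi-channel or RGB TIFF)")
        data = tif.asarray()
        if pixel_size_um is None:
            try:
                num, den = page.tags["XResolution"].value
                if num:
                    pixel_size_um = den / num
            except (KeyError, TypeError, ValueError):
                pixel_size_um = None
        if z_interval_um is None:
            meta = tif.imagej_metadata or {}
            spacing = meta.get("spacing")
            z_interval_um = float(spacing) if spacing else None

    if data.ndim == 2:
        data = data[None, :, :]
    if data.ndim != 3:
        raise ValueError("single-channel required (got multi-channel or RGB TIFF)")
    if pixel_size_um is None:
        raise ValueError("missing calibration: pixel_size_um not given and not in TIFF tags")
    if z_interval_um is None:
        raise ValueError("missing calibration: z_interval_um not given and not in TIFF tags")
    return ZStack(np.asarray(data, dtype=float), float(pixel_size_um),
                  float(z_interval_um))


def write_zstack(stack: ZStack, path) -> None:
    """Write a stack as a 16-bit multi-page TIFF with calibration tags."""
    data = np.clip(np.round(stack.voxels), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(
        str(path),
        data,
        imagej=True,
        resolution=(1.0 / stack.pixel_size_um, 1.0 / stack.pixel_size_um),
        metadata={"spacing": stack.z_interval_um, "unit": "um", "axes": "ZYX"},
    )


def max_intensity_projection(stack: ZStack) -> np.ndarray:
    """Per-pixel maximum across slices — the 2-D presentation image."""
    return stack.voxels.max(axis=0)
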