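"""ROI contours and per-slice / per-neuron intensity measurement.

Measurement rule
----------------
A pixel belongs to an ROI iff its center lies strictly inside the
polygon by the even-odd (crossing-number) rule.  Pixel centers sit at
integer coordinates, 0-based, with ``x`` = column and ``y`` = row.  This
crisp convention makes every measurement bit-reproducible.

A neuron's fluorescence intensity (FI) is the sum of per-slice intensity
sums over its inclusive z-window, by default 11 slices centered on the
neuron.  One polygon is reused across the window unless per-slice
polygons are supplied.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .stack import ZStack

DEFAULT_Z_WINDOW = 11
_CLUSTERS = ("PAL", "PPL1", "PPL2", "PPM1/2", "PPM3", "PAM", "VUM")


def _segments_intersect(p1, p2, p3, p4) -> bool:
    def orient(a, b, c):
        return (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])

    d1, d2 = orient(p3, p4, p1), orient(p3, p4, p2)
    d3, d4 = orient(p1, p2, p3), orient(p1, p2, p4)
    return ((d1 > 0) != (d2 > 0)) and ((d3 > 0) != (d4 > 0))


def _is_simple(poly: np.ndarray) -> bool:
    n = len(poly)
    edges = [(poly[i], poly[(i + 1) % n]) for i in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            if j == i + 1 or (i == 0 and j == n - 1):
                continue  # adjacent edges share a vertex
            if _segments_intersect(*edges[i], *edges[j]):
                return False
    return True


@dataclass(frozen=True)
class RoiContour:
    """Closed polygon plus inclusive z-window naming one neuron."""

    neuron_id: str
    cluster: str
    hemisphere: str
    polygon: np.ndarray  # (n, 2) float, columns (x, y); closed implicitly
    z_first: int
    z_last: int

    def __post_init__(self) -> None:
        poly = np.asarray(self.polygon, dtype=float)
        if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
            raise ValueError("polygon needs >= 3 (x, y) vertices")
        if not _is_simple(poly):
            raise ValueError("polygon is self-intersecting")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")
        if self.cluster not in _CLUSTERS:
            raise ValueError(f"unknown cluster {self.cluster!r}")
        if not (0 <= self.z_first <= self.z_last):
            raise ValueError("need 0 <= z_first <= z_last")
        object.__setattr__(self, "polygon", poly)

    @property
    def n_slices(self) -> int:
        return self.z_last - self.z_first + 1


@dataclass(frozen=True)
class SliceMeasurement:
    slice_index: int
    area_px: int
    area_um2: float
    intensity_sum: float
    intensity_mean: float


@dataclass(frozen=True)
class NeuronMeasurement:
    neuron_id: str
    cluster: str
    hemisphere: str
    slices: tuple[SliceMeasurement, ...]
    neuron_fi: float

    @property
    def n_slices(self) -> int:
        return len(self.slices)


def polygon_mask(polygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean membership mask: pixel centers inside by the even-odd rule.

    Vectorized crossing-number test over the polygon's bounding box;
    pixels outside the box are trivially outside.
    """
    poly = np.asarray(polygon, dtype=float)
    h, w = shape
    x0 = max(int(np.floor(poly[:, 0].min())), 0)
    x1 = min(int(np.ceil(poly[:, 0].max())), w - 1)
    y0 = max(int(np.floor(poly[:, 1].min())), 0)
    y1 = min(int(np.ceil(poly[:, 1].max())), h - 1)
    mask = np.zeros(shape, dtype=bool)
    if x0 > x1 or y0 > y1:
        return mask
    ys, xs = np.mgrid[y0:y1 + 1, x0:x1 + 1]
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(poly)
    for i in range(n):
        xa, ya = poly[i]
        xb, yb = poly[(i + 1) % n]
        crosses = (ya > ys) != (yb > ys)
        if not crosses.any():
            continue
        with np.errstate(divide="ignore", invalid="ignore"):
            x_int = xa + (ys - ya) * (xb - xa) / (yb - ya)
        inside ^= crosses & (xs < x_int)
    mask[y0:y1 + 1, x0:x1 + 1] = inside
    return mask


def measure_roi_slice(
    stack: ZStack,
    roi: RoiContour,
    slice_index: int,
    subtract_background: str = "none",
) -> SliceMeasurement:
    """Area and intensity of one ROI on one optical section.

    ``subtract_background="median"`` subtracts the slice-wide median
    intensity (a background estimate) from every member pixel before
    summing; the default is the raw sum.
    """
    if not (roi.z_first <= slice_index <= roi.z_last):
        raise ValueError(
            f"slice {slice_index} outside ROI z-window [{roi.z_first}, {roi.z_last}]"
        )
    if slice_index >= stack.n_slices:
        raise ValueError("slice index exceeds stack depth")
    plane = stack.voxels[slice_index]
    mask = polygon_mask(roi.polygon, plane.shape)
    area_px = int(mask.sum())
    if area_px == 0:
        raise ValueError("empty ROI: polygon contains no pixel centers")
    values = plane[mask]
    if subtract_background == "median":
        values = values - float(np.median(plane))
    elif subtract_background != "none":
        raise ValueError("subtract_background must be 'median' or 'none'")
    total = float(values.sum())
    return SliceMeasurement(
        slice_index=slice_index,
        area_px=area_px,
        area_um2=area_px * stack.pixel_size_um**2,
        intensity_sum=total,
        intensity_mean=total / area_px,
    )


def measure_neuron(
    stack: ZStack,
    roi: RoiContour,
    per_slice_polygons=None,
    subtract_background: str = "none",
) -> NeuronMeasurement:
    """Aggregate one neuron's FI over its inclusive z-window.

    The ROI polygon is applied to every slice in ``[z_first, z_last]``;
    ``per_slice_polygons`` (one polygon per slice, same length as the
    window) overrides it for re-drawn contours.  ``neuron_fi`` is the sum
    of the per-slice intensity sums.
    """
    if roi.z_last >= stack.n_slices:
        raise ValueError(
            f"ROI z-window [{roi.z_first}, {roi.z_last}] exceeds stack depth "
            f"{stack.n_slices}"
        )
    indices = range(roi.z_first, roi.z_last + 1)
    if per_slice_polygons is not None:
        if len(per_slice_polygons) != roi.n_slices:
            raise ValueError("per_slice_polygons must cover the full z-window")
        rois = [
            RoiContour(roi.neuron_id, roi.cluster, roi.hemisphere,
                       poly, roi.z_first, roi.z_last)
            for poly in per_slice_polygons
        ]
    else:
        rois = [roi] * roi.n_slices
    slices = tuple(
        measure_roi_slice(stack, r, z, subtract_background=subtract_background)
        for r, z in zip(rois, indices)
    )
    return NeuronMeasurement(
        neuron_id=roi.neuron_id,
        cluster=roi.cluster,
        hemisphere=roi.hemisphere,
        slices=slices,
        neuron_fi=float(sum(s.intensity_sum for s in slices)),
    )


# --- ROI JSON schema -------------------------------------------------------
# {"neurons": [{"id": str, "cluster": str, "hemisphere": "L|R",
#               "z_first": int, "z_last": int, "polygon": [[x, y], ...]}]}

def read_rois_json(path) -> list[RoiContour]:
    with open(path) as fh:
        payload = json.load(fh)
    rois = []
    for rec in payload["neurons"]:
        rois.append(
            RoiContour(
                neuron_id=str(rec["id"]),
                cluster=str(rec["cluster"]),
                hemisphere=str(rec["hemisphere"]),
                polygon=np.asarray(rec["polygon"], dtype=float),
                z_first=int(rec["z_first"]),
                z_last=int(rec["z_last"]),
            )
        )
    return rois


def write_rois_json(rois, path) -> None:
    payload = {
        "neurons": [
            {
                "id": r.neuron_id,
                "cluster": r.cluster,
                "hemisphere": r.hemisphere,
                "z_first": int(r.z_first),
                "z_last": int(r.z_last),
                "polygon": [[float(x), float(y)] for x, y in r.polygon],
            }
            for r in rois
        ]
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
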