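"""Automatic neuron detection against a cluster atlas.

Blob candidates come from a 3-D difference-of-Gaussians response
thresholded at local maxima.  Each candidate is assigned to the nearest
atlas cluster whose catchment (placement radius + margin) contains it.
Candidates falling in a non-quantifiable region (the dense PAM blob)
are counted and flagged but receive no contour; accepted neurons get a
circular contour at 2.5 sigma and an 11-slice z-window centered on
their peak slice, clipped at stack edges.

The published workflow draws contours by hand; this detector exists so
the pipeline can run end-to-end against ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as _ndi
from skimage.feature import peak_local_max

from .roi import DEFAULT_Z_WINDOW, RoiContour
from .stack import ZStack


@dataclass(frozen=True)
class ClusterDef:
    """One atlas entry: centroid (x, y, z) in voxels and catchment radius."""

    label: str
    hemisphere: str
    centroid: tuple[float, float, float]
    radius: float
    quantifiable: bool = True


@dataclass(frozen=True)
class ClusterAtlas:
    clusters: tuple[ClusterDef, ...]

    def assign(self, x: float, y: float, z: float,
               margin: float, pam_margin: float) -> ClusterDef | None:
        """Nearest cluster whose catchment contains the point, else None."""
        best, best_d = None, math.inf
        for c in self.clusters:
            reach = c.radius + (margin if c.quantifiable else pam_margin)
            d = math.dist((x, y, z), c.centroid)
            if d <= reach and d < best_d:
                best, best_d = c, d
        return best


@dataclass(frozen=True)
class DetectionResult:
    """Accepted contours plus flagged (unquantifiable) candidates."""

    contours: tuple[RoiContour, ...]
    flagged: tuple[dict, ...]  # {"cluster", "hemisphere", "x", "y", "z", "reason"}

    def count(self, cluster: str | None = None) -> int:
        if cluster is None:
            return len(self.contours)
        return sum(1 for c in self.contours if c.cluster == cluster)


def _circle_polygon(cx: float, cy: float, radius: float, n_vertices: int = 24):
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(angles),
                            cy + radius * np.sin(angles)])


def detect_neurons(
    stack: ZStack,
    atlas: ClusterAtlas,
    dog_sigma_low: float = 1.4,
    dog_sigma_high: float = 2.8,
    threshold: float = 100.0,
    min_separation: int = 2,
    roi_sigma: float = 2.0,
    z_window: int = DEFAULT_Z_WINDOW,
    assign_margin: float = 3.0,
    pam_margin: float = 6.0,
) -> DetectionResult:
    """Detect blob-like neurons and return atlas-assigned ROI contours.

    Thresholds are defaults tuned on the synthetic fixtures; the
    published counting is manual.  Candidates outside every catchment
    are dropped; those in non-quantifiable clusters are flagged with
    reason ``"unquantifiable - high neuronal density"``.
    """
    if not (stack.pixel_size_um > 0 and stack.z_interval_um > 0):
        raise ValueError("stack must be calibrated")
    dog = (_ndi.gaussian_filter(stack.voxels, dog_sigma_low)
           - _ndi.gaussian_filter(stack.voxels, dog_sigma_high))
    coords = peak_local_max(
        dog, min_distance=min_separation, threshold_abs=threshold,
        exclude_border=False,
    )
    contours: list[RoiContour] = []
    flagged: list[dict] = []
    per_cluster_idx: dict[tuple[str, str], int] = {}
    half = z_window // 2
    n_slices = stack.n_slices
    # stable order: by (cluster, z, y, x)
    for z, y, x in sorted(map(tuple, coords)):
        cluster = atlas.assign(float(x), float(y), float(z),
                               assign_margin, pam_margin)
        if cluster is None:
            continue
        if not cluster.quantifiable:
            flagged.append(
                {"cluster": cluster.label, "hemisphere": cluster.hemisphere,
                 "x": int(x), "y": int(y), "z": int(z),
                 "reason": "unquantifiable - high neuronal density"}
            )
            continue
        key = (cluster.label, cluster.hemisphere)
        per_cluster_idx[key] = per_cluster_idx.get(key, 0) + 1
        z_first = max(0, int(z) - half)
        z_last = min(n_slices - 1, z_first + z_window - 1)
        z_first = max(0, z_last - z_window + 1)  # clip from the top too
        contours.append(
            RoiContour(
                neuron_id=f"{cluster.hemisphere}-{cluster.label}-{per_cluster_idx[key]:02d}",
                cluster=cluster.label,
                hemisphere=cluster.hemisphere,
                polygon=_circle_polygon(float(x), float(y), 2.5 * roi_sigma),
                z_first=z_first,
                z_last=z_last,
            )
        )
    return DetectionResult(tuple(contours), tuple(flagged))
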