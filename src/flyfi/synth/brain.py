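"""Synthetic whole-mount brain z-stacks with per-neuron ground truth.

The generator lays out the stereotyped dopaminergic clusters of the
adult fly brain — five quantifiable clusters of ~40 neurons per
hemisphere (PAL 5, PPL1 12, PPL2 7, PPM1/2 9, PPM3 7), a dense
100-neuron PAM blob that cannot be resolved per neuron, and a VUM
placeholder — renders every neuron as an isotropic 3-D Gaussian blob on
a noisy background, and returns the stack together with the exact
neuron table and circumscribing ROI contours.

Under the "treated" condition each cluster's amplitude is multiplied by
its attenuation factor while neuron positions are unchanged, so neuron
number is preserved and only intensity drops.  With the default
attenuation (0.58 everywhere except PPM1/2 at 1.0) the ground-truth
whole-brain FI reduction is (31 x 0.42) / 40 = 32.55%.

Cluster centroids and exact per-cluster counts are package conventions
chosen inside the published approximate totals; they make count tests
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ..fi.detect import ClusterAtlas, ClusterDef
from ..fi.roi import RoiContour
from ..fi.stack import ZStack

CONDITIONS = ("control", "treated")
QUANTIFIABLE = ("PAL", "PPL1", "PPL2", "PPM1/2", "PPM3")

_GAUSS3D = (2.0 * math.pi) ** 1.5  # integral of exp(-r^2/2s^2) = _GAUSS3D * s^3


@dataclass(frozen=True)
class ClusterSpec:
    """Atlas entry: geometry and rendering parameters for one cluster.

    ``centroid`` is (x, y, z) in voxels for the right hemisphere; the
    left hemisphere mirrors it about the image midline.
    """

    label: str
    n_per_hemisphere: int
    centroid: tuple[float, float, float]
    placement_radius: float
    peak_amplitude: float = 1000.0
    blob_sigma: float = 2.0
    quantifiable: bool = True

    def __post_init__(self) -> None:
        if self.n_per_hemisphere < 0:
            raise ValueError("neuron count must be >= 0")
        if not (self.peak_amplitude > 0 and self.blob_sigma > 0
                and self.placement_radius > 0):
            raise ValueError("amplitude, sigma and radius must be positive")


@dataclass(frozen=True)
class NoiseModel:
    gaussian_sd: float = 20.0  # 2% of the default peak amplitude
    poisson: bool = False

    def __post_init__(self) -> None:
        if self.gaussian_sd < 0:
            raise ValueError("noise sd must be >= 0")


def _default_clusters() -> tuple[ClusterSpec, ...]:
    return (
        ClusterSpec("PAL", 5, (170.0, 35.0, 10.0), 9.0),
        ClusterSpec("PPL1", 12, (260.0, 80.0, 12.0), 15.0),
        ClusterSpec("PPL2", 7, (250.0, 125.0, 11.0), 11.0),
        ClusterSpec("PPM1/2", 9, (175.0, 120.0, 12.0), 12.0),
        ClusterSpec("PPM3", 7, (205.0, 130.0, 11.0), 11.0),
        ClusterSpec("PAM", 100, (200.0, 40.0, 11.0), 10.0,
                    peak_amplitude=800.0, quantifiable=False),
        # present in the atlas but carries no neurons by default
        ClusterSpec("VUM", 0, (152.0, 75.0, 10.0), 4.0, quantifiable=False),
    )


def _default_attenuation() -> dict:
    # PPM1/2 spared; the four other quantifiable clusters share 0.58
    return {"PAL": 0.58, "PPL1": 0.58, "PPL2": 0.58, "PPM3": 0.58,
            "PPM1/2": 1.0, "PAM": 0.58, "VUM": 0.58}


@dataclass(frozen=True)
class SyntheticBrainConfig:
    """Full parameterization of one synthetic brain experiment."""

    image_shape: tuple[int, int, int] = (24, 160, 300)  # (slices, rows, cols)
    pixel_size_um: float = 0.25
    z_interval_um: float = 1.08
    clusters: tuple[ClusterSpec, ...] = field(default_factory=_default_clusters)
    attenuation: dict = field(default_factory=_default_attenuation)
    background_level: float = 50.0  # 5% of the default peak amplitude
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    hemispheres: tuple[str, ...] = ("L", "R")
    z_flatten: float = 0.35  # axial compression of placement spheres
    min_separation: float = 7.0  # voxels, between quantifiable neurons
    z_window: int = 11  # slices per neuron ROI

    def __post_init__(self) -> None:
        ns, h, w = self.image_shape
        if ns < 1 or h < 1 or w < 1:
            raise ValueError("image shape must be positive")
        if not (self.pixel_size_um > 0 and self.z_interval_um > 0):
            raise ValueError("calibration must be positive")
        if self.background_level < 0:
            raise ValueError("background must be >= 0")
        if not set(self.hemispheres) <= {"L", "R"} or not self.hemispheres:
            raise ValueError("hemispheres must be a non-empty subset of L, R")
        for spec in self.clusters:
            factor = self.attenuation.get(spec.label, 1.0)
            if not (0.0 < factor <= 1.0):
                raise ValueError(f"attenuation for {spec.label} must be in (0, 1]")
            for hemi in self.hemispheres:
                cx, cy, cz = self._centroid(spec, hemi)
                reach = spec.placement_radius + 2.5 * spec.blob_sigma + 1.0
                if not (reach <= cx <= w - 1 - reach
                        and reach <= cy <= h - 1 - reach
                        and 0.0 <= cz <= ns - 1):
                    raise ValueError(
                        f"cluster {spec.label} ({hemi}) falls outside image bounds"
                    )

    def _centroid(self, spec: ClusterSpec, hemisphere: str):
        cx, cy, cz = spec.centroid
        if hemisphere == "L":
            cx = self.image_shape[2] - 1 - cx
        return cx, cy, cz

    def cluster(self, label: str) -> ClusterSpec:
        for spec in self.clusters:
            if spec.label == label:
                return spec
        raise KeyError(label)

    def single_hemisphere(self, hemisphere: str = "R") -> "SyntheticBrainConfig":
        return replace(self, hemispheres=(hemisphere,))


@dataclass(frozen=True)
class GroundTruth:
    """Exact neuron table and totals for one generated brain.

    ``true_fi`` is the analytic whole-space blob integral
    ``amplitude x (2 pi)^{3/2} sigma^3``; ``true_total_fi`` sums it over
    the quantifiable neurons (the published totals exclude PAM).
    """

    condition: str
    neurons: pd.DataFrame  # id, cluster, hemisphere, x, y, z, quantifiable,
    #                        amplitude, sigma, true_fi
    true_total_fi: float
    true_total_fi_all: float

    def count(self, quantifiable: bool | None = None,
              hemisphere: str | None = None) -> int:
        df = self.neurons
        if quantifiable is not None:
            df = df[df["quantifiable"] == quantifiable]
        if hemisphere is not None:
            df = df[df["hemisphere"] == hemisphere]
        return len(df)


def default_atlas(config: SyntheticBrainConfig | None = None) -> ClusterAtlas:
    """Atlas (cluster centroids + catchment radii) matching a config."""
    config = config or SyntheticBrainConfig()
    defs = [
        ClusterDef(spec.label, hemi, config._centroid(spec, hemi),
                   spec.placement_radius, quantifiable=spec.quantifiable)
        for hemi in config.hemispheres
        for spec in config.clusters
    ]
    return ClusterAtlas(tuple(defs))


def _sample_in_ball(rng: np.random.Generator) -> np.ndarray:
    while True:
        p = rng.uniform(-1.0, 1.0, size=3)
        if p @ p <= 1.0:
            return p


def _place_cluster(rng, config, spec, hemisphere, placed):
    """Sample neuron centers in the cluster's (z-flattened) sphere.

    Quantifiable neurons keep ``min_separation`` from every other
    quantifiable neuron so that each is individually resolvable; the
    PAM blob deliberately has no such constraint.
    """
    cx, cy, cz = config._centroid(spec, hemisphere)
    # sequential rejection sampling can paint itself into a corner, so a
    # failed cluster is restarted from scratch with fresh draws
    for _restart in range(100):
        centers: list[np.ndarray] = []
        ok = True
        for _ in range(spec.n_per_hemisphere):
            for _attempt in range(1000):
                ux, uy, uz = _sample_in_ball(rng)
                pos = np.array([
                    cx + spec.placement_radius * ux,
                    cy + spec.placement_radius * uy,
                    cz + spec.placement_radius * uz * config.z_flatten,
                ])
                if not spec.quantifiable:
                    break
                if all(np.linalg.norm(pos - q) >= config.min_separation
                       for q in placed + centers):
                    break
            else:
                ok = False
                break
            centers.append(pos)
        if ok:
            if spec.quantifiable:
                placed.extend(centers)
            return centers
    raise RuntimeError(
        f"could not place {spec.n_per_hemisphere} neurons in cluster "
        f"{spec.label} with min separation {config.min_separation}"
    )


def _render_blob(volume: np.ndarray, center, amplitude: float, sigma: float) -> None:
    ns, h, w = volume.shape
    x, y, z = center
    r = int(math.ceil(4.0 * sigma))
    z0, z1 = max(0, int(z) - r), min(ns - 1, int(z) + r)
    y0, y1 = max(0, int(y) - r), min(h - 1, int(y) + r)
    x0, x1 = max(0, int(x) - r), min(w - 1, int(x) + r)
    zz, yy, xx = np.mgrid[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1]
    d2 = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2
    volume[z0:z1 + 1, y0:y1 + 1, x0:x1 + 1] += (
        amplitude * np.exp(-d2 / (2.0 * sigma**2))
    )


def _circle_polygon(cx, cy, radius, n_vertices=24):
    angles = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + radius * np.cos(angles),
                            cy + radius * np.sin(angles)])


def generate_brain(
    config: SyntheticBrainConfig | None = None,
    condition: str = "control",
    seed: int | None = None,
    brain_id: str = "",
) -> tuple[ZStack, GroundTruth, list[RoiContour]]:
    """Render one brain under ``condition`` and return stack + ground truth.

    For a fixed seed the neuron positions (and the noise field) are
    identical across conditions: only the cluster attenuation factors
    differ, so treated brains preserve neuron number and lose intensity.
    Returned contours circumscribe each quantifiable neuron at
    2.5 sigma with an 11-slice z-window centered on its peak slice
    (clipped at stack edges).
    """
    config = config or SyntheticBrainConfig()
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}")
    rng = np.random.default_rng(config.seed if seed is None else seed)

    volume = np.full(config.image_shape, float(config.background_level))
    rows = []
    rois: list[RoiContour] = []
    ns = config.image_shape[0]
    half = config.z_window // 2
    placed: list[np.ndarray] = []
    for hemisphere in config.hemispheres:
        for spec in config.clusters:
            factor = (config.attenuation.get(spec.label, 1.0)
                      if condition == "treated" else 1.0)
            amplitude = spec.peak_amplitude * factor
            centers = _place_cluster(rng, config, spec, hemisphere, placed)
            for i, pos in enumerate(centers, start=1):
                x, y, z = (float(v) for v in pos)
                _render_blob(volume, (x, y, z), amplitude, spec.blob_sigma)
                neuron_id = f"{hemisphere}-{spec.label}-{i:02d}"
                rows.append(
                    {"id": neuron_id, "cluster": spec.label,
                     "hemisphere": hemisphere, "x": x, "y": y, "z": z,
                     "quantifiable": spec.quantifiable,
                     "amplitude": amplitude, "sigma": spec.blob_sigma,
                     "true_fi": amplitude * _GAUSS3D * spec.blob_sigma**3}
                )
                if spec.quantifiable:
                    z_peak = int(round(z))
                    z_first = max(0, z_peak - half)
                    z_last = min(ns - 1, z_first + config.z_window - 1)
                    z_first = max(0, z_last - config.z_window + 1)
                    rois.append(
                        RoiContour(
                            neuron_id=neuron_id, cluster=spec.label,
                            hemisphere=hemisphere,
                            polygon=_circle_polygon(x, y, 2.5 * spec.blob_sigma),
                            z_first=z_first, z_last=z_last,
                        )
                    )

    if config.noise.poisson:
        volume = rng.poisson(np.clip(volume, 0.0, None)).astype(float)
    if config.noise.gaussian_sd > 0:
        volume = volume + rng.normal(0.0, config.noise.gaussian_sd, volume.shape)
    np.clip(volume, 0.0, None, out=volume)

    neurons = pd.DataFrame(rows)
    quantifiable_fi = float(neurons.loc[neurons["quantifiable"], "true_fi"].sum())
    truth = GroundTruth(
        condition=condition,
        neurons=neurons,
        true_total_fi=quantifiable_fi,
        true_total_fi_all=float(neurons["true_fi"].sum()),
    )
    stack = ZStack(
        voxels=volume,
        pixel_size_um=config.pixel_size_um,
        z_interval_um=config.z_interval_um,
        brain_id=brain_id,
        condition=condition,
    )
    return stack, truth, rois
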