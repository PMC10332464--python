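"""HPLC-ECD catecholamine quantification.

Covers the chromatogram side (peak detection, linear-baseline
integration, identification by retention time, confirmation by standard
spiking) and the arithmetic side: the V1-V8 normalization chain that
converts peak areas into per-fly-head catecholamine amounts, plus the
dopamine oxidative-turnover index (DOPAC + HVA) / DA.

Notes on the V chain
--------------------
V5 (total catecholamine in the whole extract) is reconstructed as
``V2 * extract_volume / injection_volume``; it is the only reading under
which V6 = V5 / N is an amount per fly head.  ``extract_volume``
defaults to 300 uL and is echoed into every report.  The
``dilution_factor`` (default 2) accounts for the 1:1 mix of extract
with 5% TCA before injection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from scipy import signal as _sig

__all__ = [
    "Chromatogram",
    "Peak",
    "CatecholamineQuant",
    "detect_and_integrate",
    "identify_peaks",
    "confirm_by_spiking",
    "quantify",
    "turnover_ratio",
    "read_chromatogram_csv",
    "write_chromatogram_csv",
]

DEFAULT_EXTRACT_VOLUME_UL = 300.0
DEFAULT_DILUTION_FACTOR = 2.0


@dataclass(frozen=True)
class Chromatogram:
    """Detector response sampled along retention time (minutes)."""

    time: np.ndarray
    signal: np.ndarray
    label: str = ""
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        if t.shape != s.shape or t.ndim != 1:
            raise ValueError("time and signal must be equal-length 1-D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("time must be strictly increasing")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "signal", s)


@dataclass(frozen=True)
class Peak:
    analyte: str | None
    apex_time: float
    t_start: float
    t_end: float
    area: float
    height: float

    def __post_init__(self) -> None:
        if not (self.t_start < self.apex_time < self.t_end):
            raise ValueError("peak bounds must bracket the apex")
        if self.area < 0:
            raise ValueError("peak area must be >= 0")

    def relabel(self, analyte: str | None) -> "Peak":
        return Peak(analyte, self.apex_time, self.t_start, self.t_end,
                    self.area, self.height)


def _rolling_median_baseline(signal: np.ndarray, window: int) -> np.ndarray:
    # Median over a window much wider than any peak tracks the slow
    # baseline while ignoring the peaks themselves.
    window = max(3, window | 1)  # odd
    return _ndi.median_filter(signal, size=window, mode="nearest")


def detect_and_integrate(
    chrom: Chromatogram,
    min_height: float = 1.0,
    min_prominence: float = 1.0,
    baseline_window_fraction: float = 0.25,
    bound_fraction: float = 0.01,
) -> list[Peak]:
    """Detect peaks and integrate them above a linear local baseline.

    A rolling-median baseline estimate (window = ``baseline_window_fraction``
    of the trace) locates peak bounds: walking outward from each apex, a
    bound is placed where the baseline-corrected signal stays below
    ``bound_fraction`` of the peak height (or at the minimum toward the
    neighbouring peak).  The reported area is the trapezoidal integral of
    the signal above the straight line joining the baseline values at the
    two bounds.

    Peaks are returned ordered by apex time; a flat trace yields ``[]``.
    """
    t, s = chrom.time, chrom.signal
    if t.size < 10:
        raise ValueError("chromatogram too short (need >= 10 samples)")
    window = int(round(baseline_window_fraction * s.size))
    base = _rolling_median_baseline(s, window)
    corrected = s - base

    idx, _ = _sig.find_peaks(corrected, height=min_height, prominence=min_prominence)
    if idx.size == 0:
        return []

    peaks: list[Peak] = []
    for k, i_apex in enumerate(idx):
        height = float(corrected[i_apex])
        thresh = bound_fraction * height
        left_stop = idx[k - 1] if k > 0 else 0
        right_stop = idx[k + 1] if k + 1 < idx.size else s.size - 1
        if k > 0:  # split shared valleys at the minimum between apexes
            left_stop = left_stop + int(np.argmin(corrected[left_stop:i_apex + 1]))
        if k + 1 < idx.size:
            right_stop = i_apex + int(np.argmin(corrected[i_apex:right_stop + 1]))
        i_lo = i_apex
        while i_lo > left_stop and corrected[i_lo - 1] > thresh:
            i_lo -= 1
        i_hi = i_apex
        while i_hi < right_stop and corrected[i_hi + 1] > thresh:
            i_hi += 1
        if i_lo == i_apex or i_hi == i_apex:
            continue  # no support on one side; not an integrable peak
        # linear baseline between the bounds, anchored on the smooth estimate
        line = np.interp(
            t[i_lo:i_hi + 1], [t[i_lo], t[i_hi]], [base[i_lo], base[i_hi]]
        )
        area = float(np.trapezoid(s[i_lo:i_hi + 1] - line, t[i_lo:i_hi + 1]))
        peaks.append(
            Peak(
                analyte=None,
                apex_time=float(t[i_apex]),
                t_start=float(t[i_lo]),
                t_end=float(t[i_hi]),
                area=max(area, 0.0),
                height=height,
            )
        )
    peaks.sort(key=lambda p: p.apex_time)
    return peaks


def identify_peaks(
    sample_peaks, standard_peaks, tolerance_min: float = 0.2
) -> list[Peak]:
    """Label sample peaks by nearest standard retention time.

    Each sample peak inherits the analyte label of the standard peak
    whose apex lies nearest within ``tolerance_min``; otherwise it stays
    unassigned.  Ties break to the smallest time difference, then to the
    earlier-eluting standard.
    """
    standards = sorted(
        (p for p in standard_peaks if p.analyte), key=lambda p: p.apex_time
    )
    labeled = []
    for p in sample_peaks:
        best = None
        best_dt = math.inf
        for std in standards:  # sorted: first hit wins ties
            dt = abs(p.apex_time - std.apex_time)
            if dt <= tolerance_min and dt < best_dt:
                best, best_dt = std, dt
        labeled.append(p.relabel(best.analyte if best else None))
    return labeled


def confirm_by_spiking(
    sample_peaks, spiked_peaks, labels, min_relative_increase: float = 0.10
) -> pd.DataFrame:
    """Confirm analyte identities by comparing spiked vs plain sample.

    A label is *confirmed* when its peak area in the spiked run exceeds
    its area in the plain run by more than ``min_relative_increase``
    (relative).  Labels absent from the spiked run are reported as
    ``not found``.
    """
    s_area = {p.analyte: p.area for p in sample_peaks if p.analyte}
    k_area = {p.analyte: p.area for p in spiked_peaks if p.analyte}
    rows = []
    for label in labels:
        a0 = s_area.get(label)
        a1 = k_area.get(label)
        if a1 is None:
            verdict = "not found"
        elif a0 is None:
            verdict = "confirmed"  # appears only after spiking
        elif a1 > a0 * (1.0 + min_relative_increase):
            verdict = "confirmed"
        else:
            verdict = "not confirmed"
        rows.append(
            {
                "analyte": label,
                "area_sample": a0 if a0 is not None else float("nan"),
                "area_spiked": a1 if a1 is not None else float("nan"),
                "verdict": verdict,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class CatecholamineQuant:
    """Inputs and outputs of the V1-V8 normalization chain for one analyte.

    Inputs: standard concentration ``c_std`` (ng/mL) and injection volume
    ``i_std`` (uL); standard and sample peak areas ``a_std``/``a_samp``;
    sample injection volume ``i_samp`` (uL); protein concentration
    ``p_samp`` (ug/uL); ``n_heads`` fly heads; extract volume (uL) and
    TCA dilution factor.
    """

    analyte: str
    c_std: float
    a_std: float
    i_std: float
    a_samp: float
    i_samp: float
    n_heads: int
    p_samp: float
    extract_volume: float = DEFAULT_EXTRACT_VOLUME_UL
    dilution_factor: float = DEFAULT_DILUTION_FACTOR
    v1: float = field(init=False, default=float("nan"))  # ng standard injected
    v2: float = field(init=False, default=float("nan"))  # ng in injected extract
    v3: float = field(init=False, default=float("nan"))  # ug protein injected
    v4: float = field(init=False, default=float("nan"))  # ng per ug protein
    v5: float = field(init=False, default=float("nan"))  # ng in whole extract
    v6: float = field(init=False, default=float("nan"))  # ng per head (diluted)
    v7: float = field(init=False, default=float("nan"))  # ng per head (actual)
    v8: float = field(init=False, default=float("nan"))  # pg per head

    def to_dict(self) -> dict:
        return asdict(self)


def quantify(q: CatecholamineQuant) -> CatecholamineQuant:
    """Run the V1-V8 chain in place and return the completed record.

    V1 = C_Std * I_Std / 1000         (ng of standard injected)
    V2 = A_Samp * V1 / A_Std          (ng in the injected extract)
    V3 = P_Samp * I_Samp              (ug protein injected)
    V4 = V2 / V3                      (ng per ug protein)
    V5 = V2 * extract_volume / I_Samp (ng in the whole extract)
    V6 = V5 / N                       (ng per fly head, TCA-diluted)
    V7 = V6 / dilution_factor         (ng per fly head)
    V8 = V7 * 1000                    (pg per fly head)
    """
    for name in ("c_std", "a_std", "i_std", "a_samp", "i_samp", "p_samp",
                 "extract_volume", "dilution_factor"):
        value = getattr(q, name)
        if not value > 0:
            raise ValueError(f"{name} must be > 0 (got {value})")
    if not (isinstance(q.n_heads, (int, np.integer)) and q.n_heads >= 1):
        raise ValueError(f"n_heads must be an integer >= 1 (got {q.n_heads})")
    q.v1 = q.c_std * q.i_std / 1000.0
    q.v2 = q.a_samp * q.v1 / q.a_std
    q.v3 = q.p_samp * q.i_samp
    q.v4 = q.v2 / q.v3
    q.v5 = q.v2 * (q.extract_volume / q.i_samp)
    q.v6 = q.v5 / q.n_heads
    q.v7 = q.v6 / q.dilution_factor
    q.v8 = q.v7 * 1000.0
    return q


def turnover_ratio(da: float, dopac: float, hva: float) -> float:
    """Dopamine oxidative-turnover index (DOPAC + HVA) / DA."""
    if da == 0:
        raise ValueError("turnover undefined for DA = 0")
    if da < 0 or dopac < 0 or hva < 0:
        raise ValueError("concentrations must be non-negative")
    return (dopac + hva) / da


def read_chromatogram_csv(path, label: str = "") -> Chromatogram:
    """Read a ``time_min,signal`` CSV."""
    df = pd.read_csv(path, comment="#")
    if not {"time_min", "signal"} <= set(df.columns):
        raise ValueError("chromatogram CSV needs columns time_min,signal")
    return Chromatogram(df["time_min"].to_numpy(float),
                        df["signal"].to_numpy(float), label=label)


def write_chromatogram_csv(chrom: Chromatogram, path) -> None:
    pd.DataFrame({"time_min": chrom.time, "signal": chrom.signal}).to_csv(
        path, index=False
    )
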