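"""Whole-protein-normalized (stain-free) blot densitometry.

Quantifies a target band relative to the total protein signal of its
lane, removing the dependence on a loading-control band.  Input is a
densitometry table (lane totals + band volumes) as exported by any
gel-documentation package; image segmentation is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["LaneDensitometry", "wpn_normalize", "percent_change",
           "read_lane_table", "write_lane_table"]


@dataclass(frozen=True)
class LaneDensitometry:
    """Densitometry readout for one gel lane."""

    lane_id: str
    condition: str
    total_signal: float
    bands: dict

    def __post_init__(self) -> None:
        if self.total_signal <= 0:
            raise ValueError(f"lane {self.lane_id}: total signal must be > 0")
        for band, vol in self.bands.items():
            if vol < 0:
                raise ValueError(f"lane {self.lane_id}: band {band} volume < 0")
            if vol > self.total_signal:
                raise ValueError(
                    f"lane {self.lane_id}: band {band} volume exceeds lane total"
                )


def wpn_normalize(lanes, reference_lane_id: str) -> pd.DataFrame:
    """Whole-protein normalization against a reference lane.

    Each lane gets a normalization factor NF = total_ref / total_lane;
    normalized band volume = raw volume x NF.  The reference lane's NF
    is exactly 1, and multiplying one lane's loading (total and bands)
    by a scalar leaves its normalized bands unchanged.

    Returns a tidy frame with one row per (lane, band).
    """
    by_id = {lane.lane_id: lane for lane in lanes}
    if reference_lane_id not in by_id:
        raise ValueError(f"reference lane {reference_lane_id!r} not in table")
    total_ref = by_id[reference_lane_id].total_signal
    rows = []
    for lane in lanes:
        nf = total_ref / lane.total_signal
        for band, vol in lane.bands.items():
            rows.append(
                {
                    "lane_id": lane.lane_id,
                    "condition": lane.condition,
                    "band": band,
                    "total_signal": lane.total_signal,
                    "normalization_factor": nf,
                    "raw_volume": vol,
                    "normalized_volume": vol * nf,
                }
            )
    return pd.DataFrame(rows)


def percent_change(control_norm: float, treated_norm: float) -> float:
    """Percent reduction, (control - treated) / control x 100.

    Positive when the treated signal is lower; an increase comes out
    negative.
    """
    if control_norm == 0:
        raise ValueError("control value is zero; percent change undefined")
    return (control_norm - treated_norm) / control_norm * 100.0


def read_lane_table(path) -> list[LaneDensitometry]:
    """Read ``lane_id,condition,total_signal,band,volume`` CSV."""
    df = pd.read_csv(path)
    required = {"lane_id", "condition", "total_signal", "band", "volume"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lane table missing columns: {sorted(missing)}")
    lanes = []
    for (lane_id, condition, total), sub in df.groupby(
        ["lane_id", "condition", "total_signal"], sort=False
    ):
        bands = dict(zip(sub["band"].astype(str), sub["volume"].astype(float)))
        lanes.append(LaneDensitometry(str(lane_id), str(condition), float(total), bands))
    return lanes


def write_lane_table(lanes, path) -> None:
    rows = [
        {
            "lane_id": lane.lane_id,
            "condition": lane.condition,
            "total_signal": lane.total_signal,
            "band": band,
            "volume": vol,
        }
        for lane in lanes
        for band, vol in lane.bands.items()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
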