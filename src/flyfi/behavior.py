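"""Negative-geotaxis (climbing) metrics.

A fly is tapped to the bottom of a column and the height it climbs in a
fixed window (12 s) is recorded, typically over three trials per fly.
Per-fly speed is the mean of that fly's trial heights divided by the
window, so group statistics have n = flies, not trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as _stats

DEFAULT_WINDOW_S = 12.0

__all__ = ["MobilityRecord", "climbing_speed", "group_mobility_stats",
           "read_mobility_csv", "write_mobility_csv"]


@dataclass(frozen=True)
class MobilityRecord:
    """Climbing trials for one fly."""

    fly_id: str
    group: str
    trial_heights: tuple[float, ...]
    column_height: float

    def __post_init__(self) -> None:
        if len(self.trial_heights) < 1:
            raise ValueError("at least one trial required")
        if self.column_height <= 0:
            raise ValueError("column height must be positive")
        for h in self.trial_heights:
            if h < 0 or h > self.column_height:
                raise ValueError(
                    f"height {h} outside [0, column height {self.column_height}]"
                )

    @property
    def mean_height(self) -> float:
        return float(np.mean(self.trial_heights))


def climbing_speed(record: MobilityRecord, window_s: float = DEFAULT_WINDOW_S) -> float:
    """Mean trial height divided by the climbing window (length/second)."""
    if window_s <= 0:
        raise ValueError("window must be positive")
    return record.mean_height / window_s


def group_mobility_stats(
    records,
    control_group: str = "control",
    treated_group: str = "treated",
    window_s: float = DEFAULT_WINDOW_S,
    top_fraction: float = 1.0,
    alpha: float = 0.05,
) -> dict:
    """Compare climbing performance between two groups.

    Returns group mean +/- SEM of per-fly speed, the percent decline of
    the treated mean versus control, each group's success rate (fraction
    of flies whose mean height reaches ``top_fraction * column_height``),
    and a two-tailed unpaired t-test on per-fly speeds.
    """
    ctrl = [r for r in records if r.group == control_group]
    trt = [r for r in records if r.group == treated_group]
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need >= 2 flies per group")

    sp_c = np.array([climbing_speed(r, window_s) for r in ctrl])
    sp_t = np.array([climbing_speed(r, window_s) for r in trt])
    mean_c, mean_t = float(sp_c.mean()), float(sp_t.mean())
    test = _stats.unpaired_t_test(sp_c, sp_t, alpha=alpha)

    def _success(rs) -> float:
        return float(
            np.mean([r.mean_height >= top_fraction * r.column_height for r in rs])
        )

    return {
        "n_control": len(ctrl),
        "n_treated": len(trt),
        "mean_speed_control": mean_c,
        "sem_speed_control": _stats.sem(sp_c),
        "mean_speed_treated": mean_t,
        "sem_speed_treated": _stats.sem(sp_t),
        "percent_decline": (mean_c - mean_t) / mean_c * 100.0 if mean_c else float("nan"),
        "success_rate_control": _success(ctrl),
        "success_rate_treated": _success(trt),
        "t_statistic": test.statistic,
        "p_value": test.p_value,
        "significant": test.significant,
    }


def read_mobility_csv(path, column_height: float) -> list[MobilityRecord]:
    """Read a long-format trial table: ``fly_id,group,trial,height``."""
    df = pd.read_csv(path)
    required = {"fly_id", "group", "trial", "height"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"mobility table missing columns: {sorted(missing)}")
    records = []
    for (fly, group), sub in df.groupby(["fly_id", "group"], sort=True):
        heights = tuple(float(h) for h in sub.sort_values("trial")["height"])
        records.append(MobilityRecord(str(fly), str(group), heights, column_height))
    return records


def write_mobility_csv(records, path) -> None:
    rows = [
        {"fly_id": r.fly_id, "group": r.group, "trial": t + 1, "height": h}
        for r in records
        for t, h in enumerate(r.trial_heights)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
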