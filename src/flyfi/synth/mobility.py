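"""Synthetic negative-geotaxis records with a known climbing decline."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ..behavior import MobilityRecord


@dataclass(frozen=True)
class MobilityConfig:
    n_flies: int = 12  # per group
    trials_per_fly: int = 3
    control_mean_height: float = 80.0
    effect: float = 0.33  # fractional decline of the treated mean
    noise_sd: float = 5.0
    column_height: float = 100.0

    def __post_init__(self) -> None:
        if self.n_flies < 1 or self.trials_per_fly < 1:
            raise ValueError("need >= 1 fly and >= 1 trial")
        if not 0.0 <= self.effect < 1.0:
            raise ValueError("effect must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if not 0 < self.control_mean_height <= self.column_height:
            raise ValueError("control mean must lie within the column")


#: Effect sizes for the two exposure windows: 33% decline at 24 h,
#: 60% at 48 h.
MOBILITY_PRESETS = {
    "pq_24h": MobilityConfig(effect=0.33),
    "pq_48h": MobilityConfig(effect=0.60),
}
_TIMEPOINT_ALIASES = {"24h": "pq_24h", "48h": "pq_48h"}


def generate_mobility(
    config: MobilityConfig | None = None,
    timepoint: str = "pq_24h",
    seed: int = 0,
) -> list[MobilityRecord]:
    """Draw control + treated climbing records for one timepoint.

    Treated heights are drawn with mean ``control_mean x (1 - effect)``;
    all heights are clipped into ``[0, column_height]`` (negligible at
    the default noise level).  With ``noise_sd = 0`` the recovered
    decline equals the configured effect exactly.
    """
    if config is None:
        key = _TIMEPOINT_ALIASES.get(timepoint, timepoint)
        if key not in MOBILITY_PRESETS:
            raise ValueError(f"unknown timepoint {timepoint!r}")
        config = MOBILITY_PRESETS[key]
    rng = np.random.default_rng(seed)
    records = []
    for group, mean in (
        ("control", config.control_mean_height),
        ("treated", config.control_mean_height * (1.0 - config.effect)),
    ):
        for i in range(config.n_flies):
            heights = mean + rng.normal(0.0, config.noise_sd,
                                        config.trials_per_fly)
            heights = np.clip(heights, 0.0, config.column_height)
            records.append(
                MobilityRecord(
                    fly_id=f"{group}{i + 1:02d}",
                    group=group,
                    trial_heights=tuple(float(h) for h in heights),
                    column_height=config.column_height,
                )
            )
    return records
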