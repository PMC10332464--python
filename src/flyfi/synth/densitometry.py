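"""Synthetic blot densitometry tables with unequal lane loading."""

from __future__ import annotations

import numpy as np

from ..blot import LaneDensitometry

#: Fixed two-lane fixture whose whole-protein-normalized TH signal drops
#: exactly 15%: 1122 * 50000 / 55000 = 1020; (1200 - 1020) / 1200 = 0.15.
PAPER_DEFAULT = (
    LaneDensitometry("lane1", "control", 50_000.0, {"TH": 1_200.0}),
    LaneDensitometry("lane2", "treated", 55_000.0, {"TH": 1_122.0}),
)


def generate_densitometry(config="paper_default", seed: int | None = None
                          ) -> list[LaneDensitometry]:
    """Emit a lane table, either the fixed fixture or a randomized layout.

    ``config="paper_default"`` returns the packaged two-lane fixture.
    Otherwise ``config`` is a dict with keys ``n_lanes_per_group``,
    ``base_total``, ``band_fraction``, ``loading_cv`` (per-lane loading
    multiplier spread) and ``treatment_effect`` (fractional reduction of
    the treated band relative to lane protein); loading multiplies total
    and band alike, so normalized bands are invariant to it.
    """
    if config == "paper_default":
        return list(PAPER_DEFAULT)
    if not isinstance(config, dict):
        raise ValueError("config must be 'paper_default' or a dict")
    n = int(config.get("n_lanes_per_group", 3))
    base_total = float(config.get("base_total", 50_000.0))
    band_fraction = float(config.get("band_fraction", 0.024))
    loading_cv = float(config.get("loading_cv", 0.1))
    effect = float(config.get("treatment_effect", 0.15))
    band = str(config.get("band", "TH"))
    rng = np.random.default_rng(seed)
    lanes = []
    for condition, reduction in (("control", 0.0), ("treated", effect)):
        for i in range(n):
            loading = float(rng.lognormal(0.0, loading_cv))
            total = base_total * loading
            volume = base_total * band_fraction * (1.0 - reduction) * loading
            lanes.append(
                LaneDensitometry(f"{condition}{i + 1}", condition, total,
                                 {band: volume})
            )
    return lanes
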