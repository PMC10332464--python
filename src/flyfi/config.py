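"""Run configuration: defaults, JSON round-trip, and the run manifest.

Conventions used in every file this package writes: 0-based pixel
indices, inclusive z-ranges, CSV tables with headers, JSON for ROI /
ground-truth / config payloads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields


@dataclass
class RunConfig:
    """Configuration for an end-to-end experiment run."""

    # acquisition defaults
    z_interval_um: float = 1.08
    z_window: int = 11
    pixel_size_um: float = 0.25
    # detection thresholds
    dog_sigma_low: float = 1.4
    dog_sigma_high: float = 2.8
    detection_threshold: float = 100.0
    min_separation: int = 2
    # analysis
    alpha: float = 0.05
    subtract_background: str = "median"  # for the group-comparison pipeline
    n_brains_per_group: int = 12
    # reproducibility
    seed: int = 1
    # paths
    atlas_file: str = ""
    output_dir: str = "results"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = json.load(fh)
        known = {f.name for f in fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**payload)

    def digest(self) -> str:
        """Stable hash of the canonical JSON encoding."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()
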