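"""Synthetic HPLC-ECD chromatograms with known peak areas.

Peaks are Gaussians whose area is exactly proportional to the analyte
amount (``area = response_factor x amount``), superimposed on a slowly
drifting baseline plus white noise.  Default retention order is
DOPAC < DA < HVA; the numeric retention times are generator defaults
(configurable), not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ..hplc import Chromatogram

DEFAULT_RETENTION_TIMES = {"DOPAC": 3.5, "DA": 5.0, "HVA": 8.0}


@dataclass(frozen=True)
class ChromatogramConfig:
    duration_min: float = 10.0
    sampling_hz: float = 5.0  # detector output rate
    sigma_min: float = 0.08  # peak width (minutes)
    response_factor: float = 100.0  # area units per amount unit
    baseline_level: float = 2.0
    baseline_drift: float = 0.5  # linear rise over the whole run
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_min <= 0 or self.sampling_hz <= 0 or self.sigma_min <= 0:
            raise ValueError("duration, sampling rate and sigma must be positive")


def generate_chromatogram(
    concentrations: dict,
    retention_times: dict | None = None,
    config: ChromatogramConfig | None = None,
    seed: int | None = None,
    label: str = "",
) -> Chromatogram:
    """Render a chromatogram for the given analyte amounts.

    ``concentrations`` maps analyte -> amount (>= 0); every analyte must
    have a distinct retention time.  Pairs of peaks closer than
    4 x sigma set ``metadata["overlap_warning"]``.
    """
    config = config or ChromatogramConfig()
    rts = dict(retention_times or DEFAULT_RETENTION_TIMES)
    for analyte, amount in concentrations.items():
        if amount < 0:
            raise ValueError(f"negative amount for {analyte}")
        if analyte not in rts:
            raise ValueError(f"no retention time for {analyte}")
    times = sorted(rts[a] for a in concentrations)
    if len(set(times)) != len(times):
        raise ValueError("retention times must be distinct")
    overlap = any(
        t2 - t1 < 4.0 * config.sigma_min for t1, t2 in zip(times, times[1:])
    )

    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(config.duration_min * 60.0 * config.sampling_hz)) + 1
    t = np.arange(n) / (60.0 * config.sampling_hz)
    signal = (config.baseline_level
              + config.baseline_drift * t / config.duration_min)
    for analyte, amount in concentrations.items():
        if amount == 0:
            continue
        area = config.response_factor * amount
        amplitude = area / (config.sigma_min * math.sqrt(2.0 * math.pi))
        signal = signal + amplitude * np.exp(
            -((t - rts[analyte]) ** 2) / (2.0 * config.sigma_min**2)
        )
    if config.noise_sd > 0:
        signal = signal + rng.normal(0.0, config.noise_sd, n)
    meta = {
        "overlap_warning": overlap,
        "retention_times": {a: rts[a] for a in concentrations},
        "true_areas": {
            a: config.response_factor * c for a, c in concentrations.items()
        },
    }
    return Chromatogram(t, signal, label=label, metadata=meta)


def generate_hplc_experiment(
    sample_amounts: dict,
    standard_amounts: dict | None = None,
    spike_fraction: float = 0.5,
    retention_times: dict | None = None,
    config: ChromatogramConfig | None = None,
    seed: int = 0,
) -> dict:
    """Generate the standard / sample / spiked chromatogram triple.

    The spiked run is the sample plus ``spike_fraction`` of the standard
    amounts (the 10 uL spike vs the 20 uL standard injection), so every
    standard analyte's peak area strictly increases in the spiked trace.
    """
    standard_amounts = standard_amounts or {a: 1.0 for a in DEFAULT_RETENTION_TIMES}
    spiked = {
        a: sample_amounts.get(a, 0.0) + spike_fraction * standard_amounts.get(a, 0.0)
        for a in set(sample_amounts) | set(standard_amounts)
    }
    return {
        "standard": generate_chromatogram(
            standard_amounts, retention_times, config, seed=seed, label="standard"),
        "sample": generate_chromatogram(
            sample_amounts, retention_times, config, seed=seed + 1, label="sample"),
        "spiked": generate_chromatogram(
            spiked, retention_times, config, seed=seed + 2, label="spiked"),
    }
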