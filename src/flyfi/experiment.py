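"""End-to-end orchestration: simulate -> quantify -> compare -> report.

``run_experiment`` reproduces the full workflow on synthetic data and
writes six report files plus a manifest into the output directory:

* ``neurons.csv`` — per-neuron FI for every brain
* ``fi_comparison.csv`` — per-cluster and whole-brain group comparison
* ``mobility_summary.csv`` — climbing decline at both exposure windows
* ``hplc_quant.csv`` — per-head catecholamine amounts and DA turnover
* ``wpn.csv`` — whole-protein-normalized blot table
* ``wpn_summary.csv`` — percent change of the normalized target band
* ``manifest.json`` — package version, seeds, config echo + hash

Outputs are deterministic: identical config + seed give byte-identical
CSV payloads.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from . import __version__, behavior, blot, hplc
from .config import RunConfig
from .fi import compare_groups, measure_neuron, summarize_brain
from .synth import (
    SyntheticBrainConfig,
    generate_brain,
    generate_densitometry,
    generate_hplc_experiment,
    generate_mobility,
)
from .synth.mobility import MOBILITY_PRESETS

REPORT_FILES = (
    "neurons.csv", "fi_comparison.csv", "mobility_summary.csv",
    "hplc_quant.csv", "wpn.csv", "wpn_summary.csv",
)

# synthetic catecholamine amounts (arbitrary units feeding known-area
# peaks): DA and DOPAC depleted, HVA raised under treatment
_HPLC_AMOUNTS = {
    "control": {"DA": 1.0, "DOPAC": 0.30, "HVA": 0.20},
    "treated": {"DA": 0.55, "DOPAC": 0.25, "HVA": 0.30},
}
_HPLC_PARAMS = dict(c_std=200.0, i_std=20.0, i_samp=50.0, p_samp=1.0,
                    n_heads=15)


def quantify_synthetic_brains(config: RunConfig, brain_config=None):
    """Generate and quantify both brain groups via ground-truth ROIs."""
    brain_config = brain_config or SyntheticBrainConfig()
    groups = {"control": [], "treated": []}
    rows = []
    n = config.n_brains_per_group
    for condition in ("control", "treated"):
        offset = 0 if condition == "control" else n
        for i in range(n):
            seed = config.seed + offset + i
            brain_id = f"{condition}-{i + 1:02d}"
            stack, _, rois = generate_brain(
                brain_config, condition=condition, seed=seed, brain_id=brain_id)
            measurements = [
                measure_neuron(stack, roi,
                               subtract_background=config.subtract_background)
                for roi in rois
            ]
            groups[condition].append(
                summarize_brain(measurements, brain_id, condition))
            rows.extend(
                {"brain_id": brain_id, "condition": condition,
                 "neuron_id": m.neuron_id, "cluster": m.cluster,
                 "hemisphere": m.hemisphere, "n_slices": m.n_slices,
                 "neuron_fi": m.neuron_fi}
                for m in measurements
            )
    return groups, pd.DataFrame(rows)


def _mobility_report(config: RunConfig) -> pd.DataFrame:
    rows = []
    for i, timepoint in enumerate(sorted(MOBILITY_PRESETS)):
        records = generate_mobility(timepoint=timepoint,
                                    seed=config.seed + 100 + i)
        summary = behavior.group_mobility_stats(records, alpha=config.alpha)
        rows.append({"timepoint": timepoint, **summary})
    return pd.DataFrame(rows)


def _hplc_report(config: RunConfig) -> pd.DataFrame:
    rows = []
    per_head = {}
    for j, (condition, amounts) in enumerate(sorted(_HPLC_AMOUNTS.items())):
        runs = generate_hplc_experiment(amounts, seed=config.seed + 200 + 10 * j)
        std_peaks = hplc.identify_peaks(
            hplc.detect_and_integrate(runs["standard"]),
            _reference_peaks(runs["standard"]),
        )
        samp_peaks = hplc.identify_peaks(
            hplc.detect_and_integrate(runs["sample"]), std_peaks)
        areas_std = {p.analyte: p.area for p in std_peaks if p.analyte}
        per_head[condition] = {}
        for analyte in sorted(amounts):
            samp = next((p for p in samp_peaks if p.analyte == analyte), None)
            if samp is None:
                continue
            quant = hplc.quantify(hplc.CatecholamineQuant(
                analyte=analyte, a_std=areas_std[analyte], a_samp=samp.area,
                **_HPLC_PARAMS))
            per_head[condition][analyte] = quant.v8
            rows.append({"condition": condition, **quant.to_dict()})
    for condition, amounts in sorted(per_head.items()):
        rows.append({
            "condition": condition, "analyte": "turnover_(DOPAC+HVA)/DA",
            "v8": hplc.turnover_ratio(amounts["DA"], amounts["DOPAC"],
                                      amounts["HVA"]),
        })
    return pd.DataFrame(rows)


def _reference_peaks(standard_chrom) -> list[hplc.Peak]:
    # the generator's retention metadata is the label source for its own
    # standard trace (analyte identities of a standard mix are known)
    rts = standard_chrom.metadata["retention_times"]
    return [
        hplc.Peak(analyte, rt, rt - 1e-3, rt + 1e-3, 0.0, 0.0)
        for analyte, rt in rts.items()
    ]


def run_experiment(config: RunConfig | None = None, out_dir=None,
                   brain_config=None) -> dict:
    """Run the full synthetic workflow and write the report bundle."""
    config = config or RunConfig()
    out = Path(out_dir if out_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    groups, neuron_table = quantify_synthetic_brains(config, brain_config)
    comparison = compare_groups(groups["control"], groups["treated"],
                                alpha=config.alpha)
    mobility = _mobility_report(config)
    hplc_table = _hplc_report(config)
    lanes = generate_densitometry("paper_default")
    wpn_table = blot.wpn_normalize(lanes, reference_lane_id=lanes[0].lane_id)
    th = wpn_table[wpn_table["band"] == "TH"].set_index("condition")
    wpn_summary = pd.DataFrame([{
        "band": "TH",
        "control_normalized": th.loc["control", "normalized_volume"],
        "treated_normalized": th.loc["treated", "normalized_volume"],
        "percent_change": blot.percent_change(
            th.loc["control", "normalized_volume"],
            th.loc["treated", "normalized_volume"]),
    }])

    neuron_table.to_csv(out / "neurons.csv", index=False)
    comparison.to_csv(out / "fi_comparison.csv", index=False)
    mobility.to_csv(out / "mobility_summary.csv", index=False)
    hplc_table.to_csv(out / "hplc_quant.csv", index=False)
    wpn_table.to_csv(out / "wpn.csv", index=False)
    wpn_summary.to_csv(out / "wpn_summary.csv", index=False)
    manifest = {
        "package": "flyfi",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_sha256": config.digest(),
        "reports": list(REPORT_FILES),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return {
        "comparison": comparison,
        "mobility": mobility,
        "hplc": hplc_table,
        "wpn_summary": wpn_summary,
        "manifest": manifest,
        "out_dir": out,
    }
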