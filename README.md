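# flyfi

Fluorescence-microscopy quantification of dopaminergic neurodegeneration in
whole-mount *Drosophila* brains, packaged as a library + CLI and fully
exercisable on synthetic ground-truthed data.

The core assay measures per-neuron fluorescence intensity (FI) from z-stacks
via ROI contours — each neuron aggregated over an 11-slice window at 1.08 µm
spacing — then sums neuron → cluster → whole brain, counts neurons against a
cluster atlas (PAL, PPL1, PPL2, PPM1/2, PPM3, plus the unquantifiable dense
PAM blob), and compares treated vs control groups. Companion modules cover:

- **`flyfi.synth`** — ground-truth generators: two-condition brain z-stacks
  (40 quantifiable + 100 PAM neurons per hemisphere, cluster-specific signal
  attenuation with neuron number preserved), chromatograms with known peak
  areas, blot lane tables with unequal loading, and climbing-assay records
  with a configurable decline.
- **`flyfi.fi`** — z-stack I/O (single-channel multi-page TIFF), maximum
  intensity projection (presentation only; quantification always consumes the
  3-D stack), pixel-center/even-odd ROI measurement, DoG blob detection
  against the atlas, and group comparison.
- **`flyfi.hplc`** — peak detection + linear-baseline integration,
  identification by retention time, confirmation by standard spiking, the
  V1–V8 normalization chain to pg catecholamine per fly head, and the DA
  turnover index (DOPAC + HVA)/DA.
- **`flyfi.blot`** — whole-protein (stain-free) normalization: band volume ×
  total_ref/total_lane, no loading control required.
- **`flyfi.behavior`** — negative-geotaxis climbing speed, percent decline,
  success rate.
- **`flyfi.stats`** — SEM, two-tailed unpaired (pooled) t-test, one-way
  ANOVA, and the Newman–Keuls step-down studentized-range procedure.

## CLI

A single entry point `flyfi` with subcommands:

```sh
flyfi simulate brain --seed 42 --out sim/            # TIFF + ground truth + ROI JSON
flyfi simulate mobility --timepoint pq_24h --out mob.csv
flyfi quantify-fi --stack sim/brain_control.tif --rois sim/rois_control.json --out quant/
flyfi count-neurons --stack sim/brain_control.tif --atlas atlas.json
flyfi compare --control ctrl_dir/ --treated trt_dir/ --out comparison.csv
flyfi hplc-quant --sample samp.csv --standard std.csv --params params.json --out quant.csv
flyfi wpn --table lanes.csv --reference lane1 --out wpn.csv
flyfi geotaxis --table mob.csv --column-height 100
flyfi stats ttest --table groups.csv
flyfi run-experiment --seed 1 --out reports/         # full synthetic workflow
```

Conventions in every file written: 0-based pixel indices, inclusive z-ranges,
CSV with headers, JSON for ROI/ground-truth/config payloads. ROI JSON schema:

```json
{"neurons": [{"id": "R-PAL-01", "cluster": "PAL", "hemisphere": "R",
              "z_first": 5, "z_last": 15, "polygon": [[x, y], ...]}]}
```

## Notes

- Measurement rule: a pixel belongs to an ROI iff its center is strictly
  inside the polygon (even-odd rule) — bit-reproducible, and validated in the
  test suite against an exhaustive pixel-center oracle and shapely.
- `measure_neuron`/`measure_roi_slice` default to raw intensity sums;
  `subtract_background="median"` subtracts the slice median. The end-to-end
  group pipeline uses median subtraction by default
  (`RunConfig.subtract_background`), which is what recovers the generator's
  ground-truth reduction unbiasedly; the setting is echoed in the run
  manifest.
- The PAM cluster is detected but flagged `unquantifiable - high neuronal
  density`; it never receives ROI contours.
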