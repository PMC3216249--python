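# mmrscreen

Quantitative screening analysis for DNA mismatch-repair (MMR) protein
expression on western blots: densitometric quantification of the MLH1
(80 kDa) and MSH2 (100 kDa) bands, the smaller-over-larger **MMR
ratio** statistic, replicate reproducibility summaries, and
cohort-level bimodality analysis that flags a putative carrier
subpopulation. A synthetic blot/cohort generator with known ground
truth stands in for patient samples.

## Modules

| module | what it does |
| --- | --- |
| `mmrscreen.blot_synth` | Synthetic lane profiles, multi-lane blot images, dilution series, replicate panels and screening cohorts, with PHA stimulation and gene-dosage effects and full ground truth |
| `mmrscreen.densitometry` | Lane extraction, band localisation, integration, equivalent-area background subtraction, detectability (LOD) calling |
| `mmrscreen.ratio_stats` | MMR ratio = min(MLH1, MSH2) / max(MLH1, MSH2); replicate mean ± SD and pooled summaries |
| `mmrscreen.cohort_analysis` | Histogram, 1/2-component Gaussian-mixture EM fit, BIC + separation bimodality verdict, posterior mode assignment, lower-mode proportion |
| `mmrscreen.workflow` | simulate → quantify → ratio → cohort orchestration, seeding, manifest with checksums |
| `mmrscreen.presets` | Named presets: `figure1b` (dilution series, 10 µg detection limit), `table2-sw480` / `table2-wbc1..4` (reproducibility panel), `figure3` (N=50 screening cohort) |

## CLI

```sh
# full pipeline on the N=50 screening-cohort preset
mmrscreen run-all --preset figure3 --seed 1 --out runs/demo

# individual stages
mmrscreen simulate-cohort --preset figure3 --seed 1 --out runs/sim
mmrscreen quantify --profiles runs/sim/profiles.csv \
    --manifest runs/sim/lane_manifest.csv --out runs/measurements.csv
mmrscreen ratio --measurements runs/measurements.csv --out runs/ratios.csv
mmrscreen cohort --ratios runs/ratios.csv --out runs/cohort --seed 1 --plot

# dilution-series blot as 16-bit TIFF; replicate reproducibility panel
mmrscreen simulate-blot --dilution-preset figure1b --out fig1b.tif
mmrscreen reproducibility --n-reps 6 --seed 0 --out repro.csv
```

`run-all` writes `ground_truth.csv`, `profiles.csv`, `measurements.csv`,
`ratios.csv`, `cohort_report.json`, `assignments.csv` and a
`manifest.json` with per-file checksums; two runs with the same config
and seed are byte-identical.

## Notes

- All randomness flows from explicit seeds; cohorts derive per-subject
  child seeds so growing a cohort never reshuffles earlier subjects.
- Net densities are never clamped: a non-positive or non-detectable
  band makes the sample's ratio *undefined* (excluded from summaries,
  flagged in QC), never imputed.
- Mixture components are reported sorted by mean descending
  (component 0 = upper mode); a cohort that is not bimodal screens all
  subjects negative.
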