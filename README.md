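# laserlesion

Analysis pipeline for in vitro laser-damage experiments: fluorescence
damage-mask construction, fusion with calibrated thermal video, probit
dose-response thresholding with quality gates, and the reciprocity /
damage-frequency / concurrent-exposure interaction statistics — exercised
end-to-end against a synthetic data generator with known ground truth.

## Modules

| Module | What it does |
| --- | --- |
| `laserlesion.synthetic` | Generates two-channel live/dead images, thermal video stacks and binary dose-response logs with analytic ground truth (death region, dead-cell centroids, boundary isotherm temperature). Includes the deterministic 93-exposure dose-response table reconstruction. |
| `laserlesion.fileio` | TIFF/JSON-sidecar/CSV readers and writers with strict validation. |
| `laserlesion.mask` | Damage-mask construction: bleed-through correction, contrast enhancement, quadtree RATS thresholding at four stringencies, 10-erode/10-dilate cleaning, single-contiguous-region finalisation. |
| `laserlesion.thermo` | Hotspot detection, mask registration (flip/rotate/scale/translate), minimum-boundary-SD mask selection, threshold-temperature history extraction, irradiance→temperature standard curve. |
| `laserlesion.scoring` | Automated photothermal/photochemical binary lesion scoring and QC exclusion heuristics. |
| `laserlesion.probit` | Maximum-likelihood probit on log10 dose, ED_p estimation, Fieller fiducial limits with heterogeneity correction, slope/fiducial quality gates, deterministic-threshold detection. |
| `laserlesion.exposure` | Radiant-exposure arithmetic, Bunsen–Roscoe reciprocity testing, exact-binomial damage frequencies, concurrent-exposure interaction classification. |
| `laserlesion.cli` / `laserlesion.demo` | Click CLI wiring all stages plus a reproducible demo. |

## CLI

```bash
laserlesion simulate-images  --out img.tif --phenotype photothermal --seed 1
laserlesion simulate-thermal --out vid.tif --seed 2
laserlesion simulate-doses   --out doses.csv --ed50 10.70 --slope 8 --n 200
laserlesion simulate-doses   --table1 --out table1.csv

laserlesion mask    --in img.tif --out maskset/
laserlesion align   --mask-set maskset/ --thermal vid.tif --out result.json
laserlesion score   --in img.tif --beam beam.json --phenotype auto --out score.json
laserlesion probit  --log doses.csv --p 0.25 --p 0.5 --out fit.json
laserlesion determinism --log table1.csv
laserlesion frequency --k 4 --n 12
laserlesion interact  --pa 0.25 --pb 0.0 --k 22 --n 22
laserlesion demo --seed 1 --out demo_report/
```

All subcommands exit non-zero on error and log structured JSON (stage,
parameters, duration) to stderr. Defaults for every tunable live in
`src/laserlesion/defaults.yaml`; user YAML configs are schema-validated
before any stage runs.

## Conventions

Pixel coordinates are `(row, col)`, 0-based, origin top-left; windows are
half-open. Lengths in µm, temperatures in °C, irradiance in W cm⁻²,
radiant exposure in J cm⁻², durations in s. Fluorescence images are
2-page 16-bit TIFFs (green, red) with a JSON sidecar; thermal stacks are
float32 multi-page TIFFs already calibrated to °C.
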