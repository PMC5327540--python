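# eyeshine

Modelling toolkit for optic-nerve-transmitted (ONT) eyeshine in small
benthic fishes: spectral transmission efficiency, underwater irradiance
attenuation, emission-beam geometry, length-weighted circular statistics
and torsion fitting of optic-nerve pleat angles, morphometric ratios, and
a receptor-noise just-noticeable-difference (JND) model of eyeshine
conspicuousness. A seeded synthetic-data module generates inputs with the
statistical structure every stage assumes, so the whole pipeline runs with
no external data.

## Modules

| Module | Purpose |
| --- | --- |
| `eyeshine.spectral` | `SpectralCurve` container; photon conversion, transmittance, band-integrated transmission efficiency, attenuation coefficients K(λ), depth propagation |
| `eyeshine.beam` | law-of-cosines beam width from triangle sides, Snell refraction correction at a flat tank wall |
| `eyeshine.circular` | axial (±180°) range minimisation, length-weighted circular mean/SD, mean unwrapping, torsion regression with significance zeroing, group summaries |
| `eyeshine.morphometry` | head diameter/CSA, relative percentages, nerve-depth estimation, mean ± SD summaries |
| `eyeshine.visual` | A1 pigment templates, ocular-media filtering, quantum catches, chromatic/achromatic receptor-noise contrasts at depth |
| `eyeshine.synth` | seeded generators for spectra, depth profiles, nerve sections, morphometry |
| `eyeshine.io` / `eyeshine.cli` | CSV formats, pipeline runner, command-line interface |

## CLI

```sh
eyeshine simulate --kind spectra --seed 0 --out scratch/spec
eyeshine spectra --dws scratch/spec/dws.csv --ont scratch/spec/ont.csv --pet scratch/spec/pet.csv
eyeshine beam --chord 0.35 --left 2.0 --right 2.1 --n-water 1.333
eyeshine simulate --kind sections --seed 1 --out scratch/sec
eyeshine torsion scratch/sec/sections.csv --alpha 0.05
eyeshine simulate --kind morphometry --seed 2 --out scratch/morph
eyeshine morpho scratch/morph/morphometry.csv
eyeshine run --seed 3 --out scratch/full --depth 5 --depth 20
```

`run` executes every stage on synthetic inputs (or measured CSVs listed in
a YAML config passed via `--config`) and writes result CSVs plus a
`run_log.json` recording the seed and all defaulted parameters.

Spectral CSVs have the header `wavelength_nm,value` with an optional
`<name>.csv.meta` sidecar (`quantity = ...`, `label = ...`). Section CSVs
use `individual,side,distance_mm,layer_index,angle_deg,length_um`.

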