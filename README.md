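# magnegel

Magnetophoretic particle-tracing simulation and fiber-orientation
micrograph analysis for magnetically aligned collagen hydrogels.

The package models a pair of facing N42 NdFeB cuboid magnets with a
closed-form exterior field, traces 250 nm magnetic nanoparticles (MNPs)
through the gradient-squared-field force with Stokes drag, and
re-implements two micrograph quantification procedures: Fourier-spectrum
directionality histograms (2° bins over 0–180°, Gaussian fit, anisotropy
call) and a thresholded run-length gap count along a half-height
intensity transect. Seeded synthetic-micrograph generators with ground
truth make the whole pipeline testable without raw imaging data.

## Modules

| module | what it does |
| --- | --- |
| `magnegel.magnetics` | analytic cuboid-magnet field, two-block device, remanence calibration to a target midpoint flux density |
| `magnegel.magnetophoresis` | overdamped Euler particle tracing in a reflective well; net-motion angle statistics (field axis = 90°) |
| `magnegel.orientation` | FFT directionality histogram, Gaussian+baseline fit, single-isolated-peak anisotropy classification, Otsu binarization |
| `magnegel.segmentation` | transect extraction, <25%-of-max run-length gap counting (≥15 µm), artifact exclusion, replicate averaging |
| `magnegel.synthetic` | seeded generators: aligned/isotropic fibers, MNP strings, gap-band gel images, elongated-cell actin scenes, noise |
| `magnegel.pipeline` | YAML-configured end-to-end experiments, JSON report validated against a bundled schema |

## CLI

```sh
# trace MNPs between the calibrated magnets
magnegel simulate --seed 1 --n-particles 2000 --out sim

# generate a synthetic scene with ground truth
magnegel synth --kind aligned_fibers --seed 3 --out scene.tif --truth truth.json

# directionality histogram + Gaussian fit (averaged over images)
magnegel directionality scene.tif --out hist.csv --fit fit.json

# gap counting on gel micrographs
magnegel segments gel.tif --pixel-size-um 1.61 --out gaps.json

# field map CSV over the sample region
magnegel export-fieldmap --n 21 --out fieldmap.csv

# full experiment (device + simulation + dose-series groups)
magnegel run --config experiment.yaml
```

A ready-made experiment config is bundled at
`src/magnegel/configs/default_experiment.yaml`.

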