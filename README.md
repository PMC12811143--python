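# cardiomorph

Quantitative morphometry of cardiac compartment boundaries from imaging and
histology, with synthetic phantom generators so the full pipeline is testable
without external data. The package covers four analysis families:

- **Lineage linear profiles** (`cardiomorph.profiles`): rolling-ball
  background subtraction, slab maximum projections, midline-anchored profile
  sampling and normalization, ensemble aggregation with pointwise Welch
  testing, intensity-weighted boundary position/spread statistics (m, s)
  with Welch-t / F comparisons, and chamber-wise signal-area fractions.
- **Orientation analysis** (`cardiomorph.orientation`): structure-tensor
  orientation/coherency fields, gradient-energy-weighted axial
  directionality histograms, alignment to the dominant direction, pooled
  angle-bin scores, two-sample Watson U² (permutation / exhaustive /
  asymptotic) and Wilcoxon rank-sum tests.
- **Serial-section morphometry** (`cardiomorph.morphometry`): label-stack
  metrics at known pixel size and 5 µm slice thickness — IVS fill,
  attached-trabeculation fraction, apical compact-layer thickness, VSD
  detection by LV/RV lumen contact, closing-path defect areas
  (Σ chord × slice thickness), membranous/muscular subtype assignment, and
  WGA/DAPI cell morphometry (ellipse shape, nuclei density).
- **Genetic interaction GLM** (`cardiomorph.interaction`): bias-reduced
  (Jeffreys-prior/Firth) binomial logistic regression with allele-dose main
  effects and interaction, finite under complete separation, plus an
  independent grid-search oracle. Bundled incidence tables live in
  `cardiomorph.datasets`.

`cardiomorph.synthetic` generates every input class with stored ground
truth: two-reporter boundary volumes, oriented textures, heart-like serial
label stacks with septal holes of known geometry, ellipse cell masks, and
binomial incidence tables from an allele-dose log-odds model. All
generators are pure functions of spec + seed.

## CLI

```sh
cardiomorph simulate boundary --seed 1 --out sim/        # phantoms + truth
cardiomorph simulate sections --config heart.json --out sim/
cardiomorph profiles sim/boundary_volume.tif --channel band --out prof/
cardiomorph orient texture.csv --bins 2 --pool 0:5,90:5
cardiomorph morpho sim/sections --metrics fill,trab,thickness
cardiomorph vsd sim/sections --slice-thickness 5
cardiomorph glm counts.csv --out glm/
cardiomorph run config.json                              # staged pipeline
```

Pipeline configs are JSON (`stages`, `seed`, `out`, `params`); unknown keys
are rejected and every run writes a provenance record (config hash, seed,
versions). Volumes are multi-page TIFF with a JSON calibration sidecar;
label stacks are per-slice indexed PNG plus a legend JSON; tables are CSV.

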