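# adiposcreen

A desk-scale, fully synthetic re-implementation of a high-content
adipogenesis screening pipeline. The package covers six stages:

| Module | What it does |
| --- | --- |
| `adiposcreen.synthetic_plate` | 96-well plate layouts (serial 1:2 dilutions, randomized positions, controls), dose-dependent ground-truth cell populations, and rendered two-channel (nuclei / lipid) TIFF fields |
| `adiposcreen.imaging` | Nuclei segmentation (smooth → Otsu → watershed declump → size gate), seeded cell delineation, lipid-droplet detection, droplet→cell assignment, and the four per-image endpoints (nuclei count, droplet count, total droplet area, total droplet intensity) |
| `adiposcreen.single_cell` | Adipocyte classification (≥1 assigned droplet), mature-adipocyte flagging (lipid area ≥ 1000 px), reference-normalized droplet intensity, per-well population summaries |
| `adiposcreen.plate_stats` | Control pooling (Welch test), LOD = mean + 3·SD, >20% nuclei-loss cytotoxicity gating (HNC), 4PL dose-response fitting, EC10/EC20 interpolation, ≥2-endpoint activity calling, dose-unit conversion |
| `adiposcreen.reporter` | Tabular reporter-gene plates: per-nucleus signal normalization, the same cytotoxicity rule, percent-of-reference-maximum activity |
| `adiposcreen.chem_triage` | Nontarget-MS feature tables: >10× blank filtering, MS2 / identification-score tallies, summary CSV, cross-referencing identified compounds against a curated MDC list |

Everything is testable without any real data: the synthetic module plants
known truth (cell positions, droplet sizes, effect sizes, cytotoxic
doses) and every downstream stage is verified against it.

## CLI

```bash
adiposcreen simulate     --config plate.yaml --out raw/ --seed 1
adiposcreen segment      --images raw/ --out seg/
adiposcreen quantify     --objects seg/ --layout raw/plate_layout.yaml --out quant/
adiposcreen doseresponse --endpoints seg/endpoints.csv --layout raw/plate_layout.yaml --out calls/
adiposcreen reporter     --wells wells.csv --out reporter/
adiposcreen triage       --features features.csv --out table1.csv
```

A minimal `plate.yaml` for `simulate`:

```yaml
samples: [S1, S2]
top_dose: 3.0          # mg plastic per well
n_concentrations: 5    # 1:2 serial dilution
replicates: 4
cells_per_field: 30
effect_model: {ec50: 1.0, hill: 1.5, base_frac: 0.05, max_frac: 0.6}
imaging: {field_shape: [512, 512], fields_per_well: 9}
```

## Conventions

Pixel coordinates are 0-based `(row, col)`; areas are pixel counts;
intensities are arbitrary units. All simulation randomness flows from a
single integer seed via `numpy.random.SeedSequence`, so re-runs are
bit-identical.
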