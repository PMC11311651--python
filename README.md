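# chipinvasion

Quantification of cancer-cell invasion in a multi-channel
organ-on-a-chip assay. Chip channels are separated by a row of 16
cylindrical posts (150 μm diameter, 200 μm gaps), which defines 17
inter-post-threshold (IPT) windows. Invasiveness is scored per chip per
day with two metrics:

* **IPT crossings** — for each of the 17 windows, whether any cell has a
  footprint pixel past the post outer edge (75 μm beyond the post-center
  line for the default chip), giving a count out of 17;
* **maximum invasion distance** — how far the furthest cell pixel lies
  past the post-center line, in μm (clamped at 0).

Because no microscopy data is deposited with the assay design, the
package includes a first-class synthetic-experiment simulator: agents
perform a biased random walk toward the upper channel (drift inhibited
as `1 / (1 + dose/IC50)` in the drug arms), are rendered as Gaussian
blobs with noise, and carry exact ground-truth scores for closed-loop
validation of the imaging pipeline.

## Modules

| module | contents |
| --- | --- |
| `chipinvasion.geometry` | `ChipGeometry` / `Calibration`, `build_geometry`, IPT windows, px↔μm mapping |
| `chipinvasion.imaging` | TIFF reading, threshold/connected-component segmentation, label positivity rate |
| `chipinvasion.scoring` | crossing vector, IPT count, max invasion distance, fold summaries |
| `chipinvasion.stats` | one-way ANOVA, Tukey HSD, dose–response summary, star annotations |
| `chipinvasion.simulate` | agent walk, blob rendering, ground-truth detections, full experiment designs |
| `chipinvasion.cli` / `config` | `simulate` / `score` / `stats` subcommands, YAML config, provenance headers |

## CLI

```sh
# simulate the default 3-arm design (writes TIFFs + ground truth + table)
chipinvasion simulate --out runs/demo --seed 7

# segment and score every frame (JSON sidecars carry calibration)
chipinvasion score --images runs/demo --out runs/demo/scores.csv

# ANOVA + Tukey + dose-response report over the scores
chipinvasion stats --scores runs/demo/scores.csv --out runs/demo/report.txt
```

All three accept `--config config.yaml` with sections `seed`,
`geometry`, `calibration`, `segmentation`, `simulation`, `stats`; every
output embeds the package version, config digest, and seed.

## Conventions

* Physical frame: origin at the left end of the post row on the
  post-center line, +y toward the upper (invaded) channel; all lengths μm.
* IPT windows are half-open `[lo, hi)` intervals whose interior
  boundaries sit at post-center x-coordinates; windows 0 and 16 are
  closed by the edges of the post row's active window.
* Crossing is judged on any footprint pixel past the post *outer edge*;
  distance is measured from the post *center* line. The two reference
  lines differ by the post radius and are kept distinct in the geometry.
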