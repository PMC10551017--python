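# neurograft

Quantitative analysis of how implanted (3D-printed) cortical tissue
integrates into host brain tissue, for labs running ex vivo implantation
experiments on organotypic explants. The package covers the two standard
readouts of integration:

* **Functional integration** from spontaneous calcium imaging: per-ROI
  fluorescence traces are normalised as ΔF/F₀ (F₀ = mean of the first 10
  frames), smoothed with a six-frame running mean over frames t−2…t+3,
  background-corrected by zeroing values below *median + δ* (δ ∈
  [0.02, 0.05]), and min–max rescaled to [0, 1]. All-pairs Pearson
  correlations are computed on the processed traces; an unordered ROI pair
  with **r > 0.1** is called *correlated*, and the fraction of correlated
  pairs is reported within the host, within the implant, and across the
  host–implant interface. A hierarchically ordered similarity matrix and a
  spatial correlation network (blue-to-purple edge gradient for
  low-to-high r) visualise the structure.
* **Structural integration** from fluorescence images with an annotated
  implant boundary: process-outgrowth distance (farthest supra-threshold
  labelled signal beyond the boundary, read off a mean intensity profile
  taken normal to the boundary), migrated-neuron counts (labelled,
  nucleus-colocalised somata 200–400 µm beyond the boundary, reported per
  0.1 mm²), and labelled-area coverage of a region (percent supra-threshold
  pixels).

Because raw microscopy data of such experiments are rarely deposited, a
synthetic-data module generates calcium recordings with planted correlated
communities and morphology scenes with planted outgrowth, cells and
coverage, so every stage can be verified against known ground truth.

## Worked example

```python
import neurograft as ng
from neurograft.pipeline import full_calcium, full_morphology

# one planted community spanning the host-implant divide
cfg = ng.SimConfig(
    n_host=20, n_implant=12, n_frames=300,
    communities=[((0, 1, 2, 3, 20, 21), 0.08)],
    seed=7,
)
raw, truth = ng.simulate_traces(cfg)
result = full_calcium(raw)
print(result.report.summary())

image, scene = ng.simulate_morphology_image(
    1400, 600, 2.0, 400, 300.0, 5, seed=7, implant_fill_fraction=0.8)
report, profile = full_morphology(
    image, profile_box_um=(300, 1400, *scene.outgrowth_stripe_um))
print(report.summary())
```

prints

```
Correlated-pair fractions (Pearson r > 0.1)
         host-host:   40 /  190 pairs =  21.05%
      host-implant:   57 /  240 pairs =  23.75%
   implant-implant:   17 /   66 pairs =  25.76%
Process outgrowth: 299.0 um
Migrated neurons in 200-400 um band: 5 (4.2 per 0.1 mm^2, band area 0.120 mm^2)
Labelled-area coverage: 80.0%
```

The pair-fraction table counts, per compartment class, how many of the
possible ROI pairs exceed the r > 0.1 threshold: host–implant pairs above
the chance level indicate functional coupling across the interface (here
driven by the planted community plus chance correlations of spontaneous
events). The morphometry block recovers the planted scene: 300 µm of
process outgrowth (to within one 2 µm pixel), all 5 planted migrated
neurons in the 200–400 µm band, and the 80% labelled fill of the implant
slab.

The same pipelines are available from the shell:

```sh
neurograft simulate-traces --out sim --communities "0,1,2,20,21@0.08" --seed 7
neurograft full-calcium --input sim/traces.csv --out run
neurograft simulate-image --out img --seed 7
neurograft full-morphology --input img/scene.tif --out morpho \
    --profile-box 300,1200,210,390
```

Each command writes plain CSV/GraphML/TIFF artefacts plus a JSON manifest
(parameters, seed, package version, input checksums); identical seeds give
byte-identical outputs.

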