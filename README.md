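# dualreporter

Quantitative analysis of transcriptional **multi-tasking** in *Bacillus
subtilis* colony biofilms — do individual cells express more than one gene
at a time, and where in the colony does that happen?

The package is built for groups using **dual fluorescent transcriptional
reporters**: strains carrying two promoter fusions (YPet and mTurquoise2)
at neutral chromosomal loci, so two genes' expression can be read out
per cell or per pixel simultaneously. It implements three measurement
pipelines plus a synthetic-data module that generates every input type
with known ground truth, so the whole stack is testable without any
microscope or cytometer:

1. **Colony radial profiling** (`dualreporter.colony`). The colony
   footprint is segmented from the brightfield channel via its
   Laplacian-of-Gaussian response; each pixel's distance to the mask
   centroid *c* is normalized by the mean centroid-to-boundary distance
   *R̄*, giving a percent-of-radius coordinate *p = 100·d/R̄* (colony edge
   ≈ 100%). Fluorescence is averaged in 1% bins of *p* out to 120%,
   capturing background just beyond the edge, and optionally normalized
   per channel.

2. **Flow-cytometry co-expression** (`dualreporter.flow`). Per-channel
   detection gates are the empirical 99.9th percentile of a
   non-fluorescent control; each event is classified into one of four
   quadrants (neither / mTurq-only / YPet-only / both) by strict
   comparison against both gates. For a gene pair measured in both color
   orientations, the co-expression entry is
   max over orientations of 100·n_both/n. Per-gene totals use the YPet
   channel only. Samples under 24,000 events are flagged by QC.

3. **Voxel-wise Pearson correlation** (`dualreporter.voxel`). Two-channel
   confocal stacks are tiled into cubic voxels (10 px ≈ 0.80 µm per side
   at 0.08 µm/px); per voxel, the sample Pearson coefficient
   *r = cov(I₁,I₂)/(σ₁σ₂)* over its pixels is placed at the voxel
   centroid. Voxels without fluorescence or with a constant channel are
   excluded with a recorded reason.

`dualreporter.panel` enumerates the experimental design (all unordered
pairs of the active gene panel in both fluorophore orientations), and
`dualreporter.pipeline` / the `dualreporter` CLI orchestrate everything
from a single YAML config.

## Worked example

`examples/` holds one narrative script per capability. For instance:

```sh
python examples/radial_profile.py
```

```
segmented colony: 45273 px (truth 45273 px), mean radius 120.2 px
YPet profile peaks at 50% of radius (ring generated at 50%)
mTurq profile peaks at 95% of radius (edge-peaked channel, expected near 100%)
profile covers 1-120% in 120 bins; normalization constants {'YPet': 10472.4, 'mTurq': 9818.2}
```

The generator placed a ring of YPet expression at 50% of the colony
radius; the pipeline's masking recovers the footprint exactly and the
binned profile peaks at the generated position. Similarly,
`examples/flow_coexpression.py` recovers known mixture fractions through
control-based gating, and `examples/voxel_correlation.py` recovers
±0.7 correlation regions and excludes the no-fluorescence strip:

```
mean r, correlated region (x-voxels 0-3):  +0.70  (truth +0.70)
mean r, anti-correlated region (x-voxels 4-7): -0.70  (truth -0.70)
```

A full orchestrated run on self-generated demo data:

```sh
python examples/full_pipeline.py          # or: dualreporter run --config cfg.yaml
```

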