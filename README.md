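# clickmap3d

Atlas-registered 3D proliferation mapping for cleared-tissue light-sheet
microscopy.

Whole-brain maps of proliferating (S-phase) cells are built by click-labelling
EdU-positive nuclei, imaging the cleared brain in 3D, and asking, for every
brain region, *how many labelled nuclei does it contain per unit volume?*
`clickmap3d` implements the computational half of that workflow as a tested,
reusable library:

1. **Detection** — a random-forest pixel classifier separates nuclear signal
   from noise; connected components of fewer than **3 adjacent voxels** are
   discarded as noise (the three-voxel rule); components consistent with
   several touching nuclei are split; each nucleus yields one
   intensity-weighted centroid in physical μm.  Imaging at 3.65 μm voxels is
   sufficient: the package's own benchmark shows per-nucleus counts survive
   the resolution reduction from 0.334 μm.
2. **Normalization** — raw sample-space coordinates are mapped to a reference
   label atlas through an affine transform (stored forward, *used inversely*)
   plus a nonlinear deformation field (applied directly, sampled
   trilinearly).  Only the affine is estimated here; deformation fields come
   from an external registration tool or the synthetic generator.
3. **Atlas annotation** — three custom relabelings: a one-voxel
   subventricular-zone (SVZ) layer on the ventricular wall of the
   caudoputamen (custom ID 5), a consensus marker mask (voxels positive in
   ≥ 4 of 7 registered brains), and hemisphere splitting (left IDs =
   base + 1,000,000,000).
4. **Quantification** — per-region counts and densities
   (count / region volume, nuclei·mm⁻³), voxel-collision diagnostics at
   10/25/50 μm grids, strict <5 μm nearest-neighbour colocalization between
   channels (e.g. EdU vs Ki-67), hemisphere-paired comparisons, heatmap
   volumes, and the pulse-chase migration estimate
   (speed × chase time, e.g. 17.98 μm/h × 24 h = 431.52 μm).
5. **Synthetic data** — a first-class generator (toy symmetric atlases,
   region-dependent nucleus densities with SVZ enrichment, clusters of 1–4
   touching nuclei, Poisson-Gaussian camera noise, single-voxel speckles,
   surface-rim artifacts, known affine + smooth warp) so every stage is
   testable without any acquisition.

## Worked example

```python
import numpy as np
from clickmap3d import synthgen, detection, normalization, quantification

# 1. simulate: toy atlas + clustered nuclei + rendered EdU stack
atlas = synthgen.build_toy_atlas(spacing_um=10.0, shape=(48, 48, 48),
                                 n_regions=6, seed=100)
scene = synthgen.sample_nuclei(
    atlas, region_densities={21: 10_000.0, 31: 1_800.0},
    cluster_mix={1: 0.5, 2: 0.3, 3: 0.2}, seed=1)
params = synthgen.RenderParams(spacing_um=3.65)
edu = synthgen.render_channels(scene, params, channels=("edu",), seed=2)["edu"]

# 2. detect: background subtraction -> classification -> three-voxel rule + splitting
work = detection.subtract_background(edu, sigma_um=15.0)
mask = detection.classify_voxels(detection.threshold_classifier(24.0), work)
nuclei = detection.detect_nuclei(mask, intensity=work, min_voxels=3)
print(f"true nuclei: {len(scene.nuclei)}, detected: {len(nuclei)}")

# 3. normalize (identity chain here) and quantify per region
points = normalization.apply_chain_to_points(nuclei, scene.true_transform)
stats = quantification.count_per_region(points, atlas, level="leaf")
print(stats.table[["region_id", "name", "count", "volume_mm3",
                   "density_per_mm3"]].to_string(index=False))
```

prints

```
true nuclei: 113, detected: 113
 region_id                   name  count  volume_mm3  density_per_mm3
        11         ventricle leaf      5    0.000936      5341.880342
        21 caudoputamen-like leaf     83    0.008872      9355.275023
        31          region-3 leaf     24    0.014364      1670.843776
        41          region-4 leaf      1    0.015572        64.217827
        51          region-5 leaf      0    0.003824         0.000000
        61          region-6 leaf      0    0.004032         0.000000
```

All 113 simulated nuclei are recovered.  The caudoputamen-like shell (the
region wrapping the ventricle, where the generator concentrates nuclei the
way neurogenic tissue does) comes back with a density near the configured
10,000 mm⁻³; the handful of counts in neighbouring regions are cluster
members that straddle region boundaries, which is why densities, not raw
counts, are the comparable quantity.

A command-line interface mirrors the library:

```sh
clickmap3d simulate --out sim/ --seed 3
clickmap3d detect --in sim/edu.nrrd --out nuclei.csv
clickmap3d normalize --points nuclei.csv --affine sim/affine.txt --out atlas_pts.csv
clickmap3d quantify --points atlas_pts.csv --atlas sim/atlas.nrrd \
    --ontology sim/ontology.json --out stats.csv
clickmap3d benchmark --out report/
```

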