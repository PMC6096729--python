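# nucshuttle

Quantification of fluorescently tagged protein distribution in single
neurons from multi-channel 3D confocal stacks and 4D time-lapses — built for
studying nucleo-cytoplasmic shuttling and injury-induced redistribution of
aggregation-prone proteins such as TDP-43 in vivo.

The motivating biology: TDP-43, the hallmark mislocalising protein of
ALS/FTLD, normally sits predominantly in the neuronal nucleus (in dynamic
sub-micron granules) and redistributes to the cytoplasm — and occasionally
into the axon — when the neuron degenerates. Measuring that redistribution
in a living spinal cord requires voxel-level bookkeeping over a 3D cell
volume through time. This package provides those measurements plus a
synthetic-neuron microscopy simulator that supplies ground truth for every
one of them.

## What it measures

Let `g(v)` be the grey value of voxel `v`, treated as proportional to local
fluorophore concentration. Over the soma volume `S`, split by a nuclear
marker channel into nucleus `N` and cytoplasm `C = S \ N`:

    nuclear fraction  f = Σ_{v∈N} g(v) / ( Σ_{v∈N} g(v) + Σ_{v∈C} g(v) )

- **`compartment`** — that partition: per-channel Otsu (or fixed)
  thresholds, soma = largest connected component, nucleus = marker mask ∩
  soma; exact additivity of the two sums; per-frame time courses.
- **`granules`** — 3D connected-component volumetry of nuclear
  accumulations (volume = voxel count × voxel volume, 6/18/26-connectivity,
  deterministic scan-order labels).
- **`axon`** — per-segment mean intensity along a supplied neurite polyline
  (SWC/CSV), whole-path mean, background comparison (mean of two 8-µm
  off-cell lines, detection at > background + 2 SD), and spike detection in
  axonal time series.
- **`bleach`** — radial attenuation `1 − post/pre` around a z-parallel UV
  column, binned by in-plane distance.
- **`preprocess`** — line-based background estimation, in-plane mean
  filter, Richardson–Lucy deconvolution (reflective boundaries; off by
  default in measurement pipelines).
- **`stats`** — group summaries (mean ± SEM), one-way ANOVA with post hoc
  Tukey HSD.
- **`phantom`** — the synthetic neuron: ellipsoidal soma/nucleus, axon
  tube, seeded granules; Gaussian-PSF optics with Poisson + read noise; a
  stereotyped degeneration sequence (swelling to a sphere,
  nucleus→cytoplasm redistribution, pyknosis/karyorrhexis, fragment
  release, late axonal influx spike, dissolution); a UV bleach column with
  a survival profile anchored at 50% attenuation at a configurable radius.

## Worked example

```python
import nucshuttle as ns
from nucshuttle import compartment, preprocess, granules

scene = ns.build_scene(target_nuclear_fraction=0.782, seed=7,
                       granule_radii=[0.5, 0.45, 0.4, 0.35, 0.3, 0.3, 0.25, 0.25])
voxel = (0.4, 0.2, 0.2)                       # (dz, dy, dx) µm
shape = ns.grid_for_scene(scene, voxel)
stack = ns.render(scene, ns.OpticsParams(), shape, voxel, seed=7)

masks = compartment.compute_masks(stack)      # Otsu on marker channels
bg = preprocess.estimate_background_lines(stack, seed=7)
res = compartment.partition(stack, "reporter", masks, background=bg)
print(f"nuclear fraction: {res.nuclear_fraction:.3f} "
      f"(truth {scene.nuclear_fraction_truth})")

gs = granules.detect_objects(stack, "reporter", mask=masks.nuclear_mask,
                             threshold="fold:1.8", min_voxels=2)
print(f"granules detected: {len(gs)} (truth {len(scene.granules)}), "
      f"volumes {gs.volumes_um3.min():.3f}-{gs.volumes_um3.max():.3f} um3")
```

prints

```
nuclear fraction: 0.753 (truth 0.782)
granules detected: 5 (truth 8), volumes 0.048-0.480 um3
```

The recovered fraction sits within the expected ±0.05 of the ground truth:
the residual gap is PSF boundary spill between the bright nucleus and the
cytoplasm, the same bias any summed-intensity partition of a real confocal
stack carries. Of eight granules, the five that are large and well
separated relative to the PSF are recovered (two close pairs merge; the
smallest is blurred below threshold) — sub-resolution volumetry is
PSF-limited, see `docs/methods.md`.

There is also a CLI mirroring the modules:

```bash
nucshuttle run --config src/nucshuttle/data/demo.yaml --out demo_out
nucshuttle partition --stack demo_out/phantom.ome.tif --out partition.csv
nucshuttle stats --in measurements.csv --alpha 0.05
```

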