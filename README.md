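# fpmkit

Object-based analysis of excitation-resolved **fluorescence polarization
microscopy (FPM)** stacks.

In excitation-resolved FPM an image is acquired four times while the
excitation polarization rotates through ω = 0°, 45°, 90°, 135°
(anticlockwise from the +x axis). Because absorption scales with
cos²(ω − φ) of the angle between the field and each fluorophore's
transition dipole, the per-pixel intensity follows a sinusoid
`I_ω = a + b·cos 2(ω − α)` whose amplitude and phase encode the in-plane
**order** and mean **orientation** of the labeled molecules. From the
four images, pixelwise:

    S0 = (I0 + I45 + I90 + I135) / 2
    S1 = I0 − I90
    S2 = I45 − I135

    order   p = sqrt(S1² + S2²) / S0
    azimuth α = atan2(S2, S1) / 2        (axial, period 180°)

The interesting biology usually lives in *objects* — adhesion puncta,
cytoskeletal filaments — not whole images. fpmkit segments the S0 image
(built-in `puncta` and `filaments` schemes), extracts per-object
morphology, intensity and polarization features, and — its core
algorithm — computes each object's **midline** from the interior edges
of the Voronoi diagram of its boundary, so azimuths can be re-expressed
relative to the structure itself (`α_midline = (α_image − tangent) mod
180`; 90° means perpendicular to the structure). Axial quantities use
doubled-angle circular statistics: the axial mean, resultant length R̄,
and circular standard deviation `s0 = ½·sqrt(−2 ln R̄)`.

A forward-model scene generator (puncta fields, S-shaped ribbons,
filament fields, with Poisson/Gaussian noise and known per-pixel ground
truth) makes the whole pipeline testable by parameter recovery without
microscopy data.

## Worked example

```python
import numpy as np
import fpmkit as fk

# simulate a Poisson-noise field of 30 puncta with order 0.8
scene = fk.make_puncta_field(n=30, order=0.8, noise=fk.NoiseModel("poisson"), seed=1)
stack = fk.render_stack(scene)

maps = fk.compute_pixel_maps(stack)           # S0, order p, azimuth alpha
seg = fk.segment_puncta(maps.S0)              # Otsu-based puncta scheme
objects = fk.extract_features(seg, maps, stack)

print(f"objects found: {len(objects)} (planted: {len(scene.objects)})")
p = [o.mean_order for o in objects]
sb = [o.local_sb for o in objects]
print(f"median object order p = {np.median(p):.3f}")
print(f"median local S/B      = {np.median(sb):.2f}")

fk.kmeans_cluster(objects, ["local_sb"], k=2, seed=0)
for c in (1, 2):
    sel = [o for o in objects if o.cluster_id == c]
    print(f"cluster {c}: n={len(sel)}, mean p = {np.mean([o.mean_order for o in sel]):.3f}")
```

prints

```
objects found: 30 (planted: 30)
median object order p = 0.644
median local S/B      = 5.34
cluster 1: n=14, mean p = 0.633
cluster 2: n=16, mean p = 0.649
```

All 30 planted puncta are recovered. The measured order (0.644) sits
below the planted 0.8 because the scene's uniform background dilutes
the modulation — exactly `A·p/(A + 2B) = 0.654` for this amplitude and
background — and the local signal-to-background ratio (S/B ≈ 5.3)
quantifies that dilution per object. Cluster 1 is, by convention, the
low-S/B population; its slightly lower mean order is the expected
noise-on-order effect.

The same workflow runs from the shell:

```sh
fpmkit simulate --kind puncta --n 30 --seed 1 --out scene.ome.tif
fpmkit process scene.ome.tif --scheme puncta --out-dir out/
fpmkit cluster out/objects.csv --features local_sb --out out/clustered.csv
```

`fpmkit --help` lists all subcommands (`process`, `segment`, `midline`,
`cluster`, `export`, `render`, `simulate`).

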