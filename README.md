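# asmbrain

Automated quantification of regional cerebral blood flow (rCBF) from brain
perfusion SPECT, built around a 3D statistical shape model and the
active-shape algorithm.

Perfusion SPECT (e.g. ⁹⁹ᵐTc-HMPAO) gives relative, not absolute, flow, and in
clinical practice is mostly read visually. `asmbrain` implements a fully
automated quantification pipeline for such volumes, intended for researchers
and physicists working on nuclear-medicine brain imaging:

1. **Rotation** — the tilt of the brain in the sagittal view is estimated by
   PCA of the above-threshold voxel cloud and removed.
2. **Delineation** — a point-distribution model of the brain surface (546
   corresponding landmarks, mean shape x̄ plus the top K = 5 PCA modes P of
   landmark covariance; new surfaces are x̄ + P·b under a similarity
   transform) is fitted to the volume by the active-shape loop: a 1D boundary
   search along each landmark's surface normal alternates with a constrained
   model projection (|b_k| ≤ 3√λ_k) until the surface stops moving.
3. **Normalization** — voxel counts are scaled so a reference statistic
   equals 100 %: the cerebellar cortex mean, the cerebellar maximum (mean of
   the hottest voxel and its 26 neighbours), or the whole-cortex mean.
4. **Cortical projection** — 3010 sample points interpolated from the 546
   landmarks each take the maximal count along their inward normal down to
   9 % of the brain length (≈15 mm); sample points are pooled into 13 lobar
   regions (cerebellum, frontal, temporal, parietal, occipital, with
   dx/sin/median subdivisions), and each left-right pair gets an asymmetry
   index 100·(CBF_sin − CBF_dx)/((CBF_sin + CBF_dx)/2).
5. **Cortical index** — the percentage of brain voxels at or above 45 % of
   the reference, a proxy for preserved cortical tissue; the fraction of
   sample points *below* 45 % is reported as a delineation-quality metric.

Because no public rCBF-SPECT data accompany the method, the package ships a
first-class synthetic-data module: analytic brain phantoms (cortical shell +
white matter + ventricle + cerebellum, Gaussian PSF blur, Poisson counting
noise) with exact ground-truth surfaces, lobe masks and landmark sets, used
both to train the shape model and to validate every pipeline stage.

## Worked example

```python
import numpy as np
from asmbrain import (PhantomSpec, analyze_volume, generate_brain_phantom,
                      train_default_model)

# statistical shape model + symmetric lobe atlas from 29 synthetic surfaces
model, atlas = train_default_model(n_training=29, n_modes=5, seed=1)

# one noisy examination (10 mm PSF, Poisson counts)
volume, truth = generate_brain_phantom(PhantomSpec(seed=42))
result = analyze_volume(volume, model, atlas)

print(f"converged: {result.fit.converged} after {result.fit.iterations} iterations")
print(f"estimated tilt: {result.rotation.angle_deg:.1f} deg")
rep = result.report.methods["cerebellum_mean"]
print(f"reference (cerebellar cortex mean): {rep.reference_raw:.1f} counts")
for region in ("frontal_dx", "frontal_sin", "temporal_dx",
               "parietal_dx", "occipital", "cerebellum"):
    print(f"{region:12s} {rep.region_means[region]:6.1f} %")
print(f"frontal asymmetry index: {rep.asymmetry['frontal']:+.2f} %")
print(f"cortical index: {rep.cortical_index:.1f} %")
print(f"sample points <45% of reference: {rep.low_value_fraction:.2f} %")
```

prints

```
converged: True after 88 iterations
estimated tilt: 12.2 deg
reference (cerebellar cortex mean): 68.7 counts
frontal_dx    103.6 %
frontal_sin   104.9 %
temporal_dx    83.3 %
parietal_dx   100.3 %
occipital     107.9 %
cerebellum    100.0 %
frontal asymmetry index: +1.22 %
cortical index: 96.7 %
sample points <45% of reference: 0.00 %
```

Region values are percentages of the cerebellar reference (100 % by
construction, hence `cerebellum 100.0`). On this phantom the regional spread
reflects blur and geometry, not perfusion differences — the uptake is uniform
across the cortex — so the asymmetry indices are small (the ≈1 % frontal
asymmetry is Poisson noise) and no sample point falls below the 45 % quality
threshold. The cortical index is high
because the synthetic ventricle is small.

`build_normal_database` aggregates such reports over a group of normal
examinations (per-point and per-region mean ± SD for each of the three
normalizations) and `zscore_patient` standardizes a new patient against it.

A command line mirrors the library: `asmbrain train`, `asmbrain simulate`,
`asmbrain fit`, `asmbrain quantify`, `asmbrain normals build/compare`.

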