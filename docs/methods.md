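# Methods

## The model

Brain surfaces are represented by 546 corresponding landmarks arranged as 14
closed rings of 39 points in sagittal planes — the layout that arises when
surface outlines are traced slice by slice in the sagittal view, where one
closed curve encloses the whole brain. Training surfaces are brought into a
common frame by generalized Procrustes analysis with full similarity
transforms (translation + rotation + isotropic scale), and the residual
variability is summarized by PCA of the flattened landmark vectors: sample
covariance with an n−1 denominator, modes signed so each one's
largest-magnitude component is positive. Five modes are retained by default;
a configuration flag (`with_scaling=False`) switches to rigid alignment if
overall size should instead appear as a mode.

Two details of the Procrustes step deserve a note. With per-shape scale
fitting, the plain "superimpose everything onto the average" map has no fixed
point — every pass shrinks the ensemble by a constant factor (regression
dilution), so the mean's centroid size is pinned to its initial value during
iteration. Consequently, re-running the alignment on an already-aligned set
reproduces it only up to one common similarity; the frame records the
convention. Convergence is declared when the mean moves less than 1e-6 mm per
point (at most 100 iterations).

## Synthetic data

The phantom emulates what a reconstructed HMPAO brain SPECT volume looks
like, not how it is acquired: an analytic cerebral ellipsoid fused with a
posterior-inferior cerebellar ellipsoid, a cortical shell of 10 mm radial
thickness at relative uptake 100, white matter at 40, a cold ventricle, 10 mm
FWHM Gaussian PSF blur (the resolution class of a modern dual-head camera),
then Poisson noise on scaled counts (blur before noise, emission statistics).
`counts_scale = 1.0` puts the blurred shell at SNR ≈ 9, a realistic count
level; 0 disables noise. All geometry is star-shaped about the cerebral
cross-section centre in every sagittal slice, so the exact outer surface, the
lobe masks and ring-structured landmark sets are available in closed form,
and a volume can equally be voxelized from an arbitrary ring-structured
landmark surface (used for parameter-recovery experiments and inside the
fitter, below).

Training surfaces are sampled from six mirror-symmetric degrees of freedom —
three semi-axis scale factors (SD 5 %), a superior-inferior bend and an
anterior-posterior slant (SD 4 mm each), and a cerebellar size factor
(SD 8 %) — chosen so that at least five meaningful PCA modes survive the
similarity alignment, matching the retained-mode count. Lobe boundaries are
fractional cuts of the cerebral frame (frontal y ≥ 0.34·a_y, occipital
y ≤ −0.60·a_y, parietal z ≥ 0.15·a_z, medial |x| ≤ 0.22·a_x, cerebellar =
inside the cerebellar ellipsoid), a geometric stand-in for an MRI-derived
atlas. What the phantom does **not** emulate: scatter, attenuation artefacts,
reconstruction texture, gyral anatomy, asymmetric normal perfusion, and
inter-subject variability beyond the six shape DOFs. Passing tests therefore
demonstrate the pipeline's internal consistency and its behaviour under
blur, noise and shape variation — not clinical accuracy on patient data.

## Boundary search

The classic steepest-gradient boundary rule is biased for a blurred shell:
the interior step (cortex → white matter) adds a positive gradient tail that
displaces the outer gradient maximum 0.4–1.6 mm outward, most strongly near
the sagittal poles. The default edge detector therefore fits, along each
outward normal, the 1D template of a blurred shell

    I(ρ) = A·Φ((ρ₀−ρ)/σ) − D·Φ((ρ₀−w−ρ)/σ)

(Φ the normal CDF, σ from the camera FWHM, shell width w over a small grid,
amplitudes A ≥ D ≥ 0 solved linearly) and proposes the best-fitting edge
position ρ₀, refined to sub-sample precision by a parabola through the
residual. A proposal is accepted only if the fitted boundary fall A and the
profile's dynamic range exceed 20 % of the robust maximum and the template's
boundary value lies in the typical interval (15–70 % of the robust maximum);
otherwise the landmark keeps its position with confidence 0, and unmoved
points enter the model projection with weight 0.1 instead of 1.

A residual ~1 mm outward bias survives at the polar caps, where the thin cap
geometry breaks the 1D profile model (a genuine 3D blur effect). The fitter
therefore finishes with a *bias-calibrated* phase: the current surface is
voxelized and blurred with the nominal imaging model, the same detector is
run on this noiseless replica, and its offset there — pure systematic error —
is subtracted from the proposals on the real volume. This assumes the nominal
shell/PSF model describes the data; on the phantoms it does exactly, on real
data it would hold approximately. Convergence thresholds: 0.1 mm mean
movement for the standard loop (50 iterations max), 0.003 mm for the
calibrated refinement (60 max) — the mode-coefficient estimate keeps
improving well below the voxel scale, so the refinement is run much tighter.

## Quantification choices

* **Sampling mesh.** The 3010 sample points are the 546 landmarks plus a
  uniform selection of midpoint-subdivision vertices of the landmark
  triangulation. The triangulation is symmetric under the topological
  left-right mirror (diagonals flip between the two halves; the self-mirrored
  middle band is split four ways through centre vertices), and the selection
  adds vertices in mirror pairs, skipping exact-midline vertices — so paired
  regions are sampled identically and a left-right-flipped volume yields
  exactly swapped regional values. Lobe labels are inherited from the nearest
  landmark; normals are area-weighted and point inward.
* **Brain length** for the 9 % projection depth is the anterior-posterior
  extent of the fitted surface (166.7 mm → 15.0 mm). Rays are sampled every
  1 mm with trilinear interpolation; on ties the sample nearest the surface
  wins.
* **Cerebellar cortex mean** (reference i) is the mean of the cortical
  projection values over cerebellar-labelled sample points, consistent with
  how every other cortical value is sampled. **Cerebellar maximum**
  (reference ii) is realized as the maximal 3×3×3 block mean over the
  cerebellar voxel territory (brain voxels whose nearest sample point is
  cerebellar) — identical to "hottest voxel averaged with its 26 neighbours"
  when the maximum is unique, and well-defined under ties.
* **Thresholds.** The cortical index counts voxels **at or above** 45 % of
  the reference of the active normalization; the quality metric counts
  sample points **strictly below** 45 %. Both use whichever normalization the
  report row belongs to.
* **Asymmetry.** 100·(CBF_sin − CBF_dx)/((CBF_sin + CBF_dx)/2): antisymmetric
  under side swap and scale-free; (110, 90) → 20.0.
* **Orientation.** The brain-tissue mask uses 30 % of the 99.5th-percentile
  intensity; the principal-axis angle is folded into (−90°, 90°]; the offset
  angle defaults to 0 and a manual override replaces the estimate. Note the
  default phantom reads ≈12° even when generated untilted — the cerebellar
  bump genuinely tilts the principal axis of the voxel cloud; the estimate is
  exactly equivariant, which is what the pipeline relies on.

## Degenerate inputs and errors

Empty masks raise segmentation errors; collinear landmark sets and
over-requested mode counts raise rank errors; empty atlas regions raise atlas
errors; non-positive references raise data errors. Non-convergence of the
fit is reported in the result (`converged=False`), never raised. Landmarks
that see no uptake in any single-lobe phantom raise an error listing their
indices; a machine-readable override map (landmark id → region) replaces the
visual atlas adjustment step.

## Problem sizes

Tests and the acceptance script run at the production grid (128³ voxels,
2 mm spacing) with 29 training surfaces, 546 landmarks and 3010 sample
points; a full train-fit-quantify cycle takes a few tens of seconds on one
CPU. The Poisson-statistics check uses 200 replicates of a 32³ phantom, and
PCA oracle checks use landmark counts up to 50 against dense
eigendecompositions.

## Known limitations

* The lobe geometry is a coarse analytic stand-in; regional values on real
  scans would need an anatomically derived atlas.
* The bias-calibrated refinement inherits the nominal shell/PSF model; a
  mismatched camera resolution degrades it gracefully toward the uncorrected
  fit, but this has only been characterized on phantoms.
* Mode-coefficient recovery is validated for surfaces drawn from the model's
  own span; out-of-model anatomy (e.g. focal defects crossing the surface) is
  only handled through the clamp |b_k| ≤ 3√λ_k.
* Absolute flow (ml/100 g/min) is out of scope; all outputs are relative to
  the chosen reference.
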