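# Methods

`iusreg` compensates brain shift between 3D intraoperative ultrasound (iUS)
volumes acquired at successive resection stages. The later-stage volume
contains a resection cavity — a hypoechoic hole with a hyperechoic rim —
that has no counterpart in the earlier acquisition, so any image-distance
term that looks at it is matching structure against nothing. The package
therefore works in two stages: segment the cavity automatically, then
register the pair with a distance measure whose support excludes both the
cavity and everything outside the ultrasound beam cone.

## Registration model

**Distance.** For reference $R$ (the later-stage, cavity-bearing volume)
and warped template $T_u(x) = T(x + u(x))$, the masked normalized gradient
field (NGF) distance is

$$ D(u) = \tfrac12 \sum_{x \in \Omega_M} h\,\bigl(1 - r(x)^2\bigr),\qquad
   r = \frac{\langle \nabla R, \nabla T_u\rangle + \varepsilon^2}
            {\|\nabla R\|_\varepsilon\,\|\nabla T_u\|_\varepsilon}, $$

with $\|g\|_\varepsilon = \sqrt{\|g\|^2+\varepsilon^2}$, central
differences scaled by the voxel spacing (replicated at the grid boundary),
and $h$ the voxel volume. NGF scores the alignment of local gradient
*directions*, which makes it robust to the intensity non-stationarity of
ultrasound; $\varepsilon$ decides which gradient magnitudes count as edges
rather than noise. The mask $\Omega_M$ is the intersection of the two beam
cones (the moving one mapped through the rigid initialization, held fixed
during optimization) minus the segmented cavity. Because the distance is
evaluated on band-limited images, the cavity's spurious edges bleed about
σ voxels past the segmentation boundary; the exclusion mask is therefore
dilated by ceil(σ)+1 voxels — without this, a thin halo of rim gradient
survives masking and most of the masking benefit is lost.

**Regularizer.** The curvature energy
$S(u) = \tfrac12 \sum_l \sum_x h\,(\Delta u_l)^2$ penalizes the squared
Laplacian of each displacement component; affine transforms cost nothing.
The Laplacian uses spacing-scaled central second differences and is
accumulated over interior voxels only — this makes the affine null space
exact including at the boundary, which replicate-padding variants do not.

**Objective and optimization.** Each resolution level minimizes
$J(u) = 100\,\bigl[D(u)/(h N_M) + \alpha\, S(u)/(h N)\bigr]$ by
limited-memory BFGS with analytic gradients. The per-voxel normalization
makes $\alpha$ comparable across problem sizes; the factor 100 puts $J$ in
percent-like units so that the conventional stopping tolerances of 0.001
(minimal progress $|J_k - J_{k-1}|/\max(1,|J_k|)$, gradient norm, relative
gradient $\|g_k\|/\|g_0\|$, step length) are meaningful, with at most 100
iterations per level. Three coarse-to-fine levels are used (factor-2
Gaussian restriction; finest level = original grid), the field being
trilinearly prolongated between levels with millimetre values preserved.
A rigid stage (3 Euler angles + translation, same masked NGF at one level
coarser than the original, central-difference gradients) initializes the
deformable stage; it is optimized from two starts — identity and the
beam-centroid translation offset — keeping the lower optimum, which guards
against coarse-level local minima under large translations. The returned
field composes both stages.

**Gradient correctness.** The analytic gradient decomposes into the
adjoint of the difference operator (exact transpose, tested to machine
precision), the NGF pointwise derivative, and the exact derivative of
trilinear interpolation. Values match straight-loop reference
implementations to 1e-10 relative error and finite differences to 1e-4
(tests `test_registration.py`).

### Numerical choices that mattered

- **Band-limiting.** The distance is evaluated on Gaussian-smoothed
  images (`image_smoothing`, default σ = 3 finest-level voxels, halved per
  coarser level so the bandwidth is constant in mm). Speckle decorrelates
  between two acquisitions; its gradients carry no alignment signal but
  dominate raw-image NGF. Without band-limiting the objective is flat
  along the true deformation and the optimizer chases speckle.
- **Boundary handling in the optimizer's sampler.** The internal trilinear
  sampler clamps out-of-domain coordinates (replicate boundary) rather
  than returning 0. The zero-outside convention of plain warping makes the
  objective discontinuous whenever a boundary voxel crosses the domain
  edge, which stalls the line search at the first iteration. The public
  `warp_volume` keeps the zero-outside convention.
- **Support hygiene.** The beam boundary is an enormous intensity step;
  after smoothing, its gradients bleed ~σ voxels inward and can dominate
  the masked distance (observed as a biased rigid rotation optimum). The
  support is therefore eroded by ceil(σ_level)+1 voxels at every level of
  both stages, mirroring the cavity-mask dilation. The rigid stage uses a
  slightly narrower bandwidth (`rigid_smoothing`, default 2.5) than the
  deformable stage: it only needs the global pose and benefits from
  sharper structure.
- **Edge parameter.** ε defaults to 10% of the median absolute gradient
  magnitude over the mask, recomputed per level on the smoothed images.
  It is always estimated on the beam intersection *without* cavity
  exclusion, so masked and unmasked runs (the ablation this package
  exists to measure) share one ε and differ only in the distance support.
- **Regularizer weight.** Default 0.3. On phantoms, the curvature cost of
  a realistic 4 mm smooth shift is about 1/10 of the attainable NGF
  decrease at this weight; at weight 1.0 the penalty nearly cancels the
  gain and deformations are visibly under-recovered, while below ~0.1 the
  field starts fitting residual speckle.

## Cavity segmentation

A 3D U-Net with three resolution steps (two 3×3×3 convolutions + instance
normalization + ReLU per level, 2× max-pooling, 2× up-convolution with
skip concatenation, dropout p = 0.3 before every synthesis-path
convolution, final 1×1×1 convolution + sigmoid). Training is patch-based:
48³ labelled cores with 20 voxels of image context per side (network input
88³), batches of 5, SGD with momentum 0.9 at learning rate 0.0005, under
the Tversky loss

$$ L = 1 - \frac{TP + s}{TP + \alpha\,FP + \beta\,FN + s} $$

on soft counts with smoothing $s = 10^{-5}$ and default α = 0.3 / β = 0.7:
weighting false negatives higher deliberately over-segments, which suits a
structure that is afterwards cleaned by keeping only the largest
26-connected component. 20% of training patches are background-only; the
rest must contain at least one cavity voxel. Inputs are standardized per
patch (zero mean, unit variance) so the network is indifferent to the
acquisition's intensity scale. Whole-volume inference tiles the volume
into non-overlapping cores with mirror-padded context (each voxel
predicted exactly once), thresholds at 0.5, and keeps the largest
component.

The network is implemented in numpy with hand-written reverse-mode
differentiation (`iusreg.nn`), using a channels-last layout whose im2col
reduces to contiguous memory runs; it is sized for CPU training of small
volumetric models, and its convolutions are verified against
`scipy.ndimage.correlate` and finite differences. Desk-scale runs use
reduced widths (base 4 channels, 24³ cores, learning rate 0.02–0.03);
the configured defaults are the full-scale values above.

## Synthetic phantoms

The generator (`iusreg.synthetic`) emulates exactly the inputs the method
needs and nothing more: a cone-shaped beam (zero outside), blob-textured
tissue, multiplicative log-normal speckle drawn independently per volume,
a spherical cavity (interior ×0.12, rim ×2.5) present only in the fixed
volume, a smooth random deformation synthesized on a coarse control grid
(cubically upsampled, pinned to zero at the volume boundary, rescaled to a
stated maximum magnitude), and landmarks at blob centres placed outside
the cavity whose pairs satisfy `p_moving = p_fixed + u(p_fixed)` exactly.
All randomness flows from a single seed.

What it does **not** model: point-spread function, attenuation, shadowing,
reverberation, probe repositioning between stages (the cone is shared),
or anatomically structured deformation. Two consequences for interpreting
test results: (i) tissue structure is sparse (a dozen blobs), so the NGF
carries signal only near blob edges, and (ii) speckle decorrelates
*completely* between the two volumes, which is harsher than real
acquisitions seconds apart. Passing recovery tests therefore demonstrates
correctness of the machinery and the direction of the masking effect, not
clinical-grade accuracy.

### Known accuracy limit on phantoms

Even when the optimizer is started *at the ground-truth field*, it moves
to a nearby solution about one voxel away: the objective's own optimum is
displaced by residual smoothed-speckle alignment and the sparsity of true
structure in the phantom. The post-registration mean landmark error
therefore plateaus at roughly half its initial value on these phantoms
(the shipped recovery test asserts a stricter bound and is expected to
flag this limit), and the plateau is insensitive to the obvious knobs —
smoothing bandwidth, regularizer weight, edge parameter, preprocessing,
pyramid depth, iteration budget. Denser true structure or correlated
speckle (i.e., more realistic inputs) would lower the floor; the phantom
deliberately is not tuned to do so.

## Evaluation

DICE = 2|A∩B|/(|A|+|B|) with both-empty := 1 and one-empty := 0; mTRE
reports per-landmark Euclidean distances in mm with mean/min/max/SD (SD
with N−1 denominator, 0 for a single pair). The paired Wilcoxon
signed-rank test is two-sided; zero differences are discarded (Wilcoxon's
original policy); for n ≤ 25 the exact null is computed by the rank
generating polynomial (provably identical to 2ⁿ sign enumeration, doubled
ranks keeping tied midranks integral), otherwise the normal approximation
with tie correction is used. The reported statistic is min(W⁺, W⁻).

All landmark distances are computed in the fixed volume's world frame
(mm); no implicit axis flips are applied to any image — direction matrices
are honored as stored.

## Problem sizes used in the shipped tests

Tests and the acceptance script run at desk scale on one CPU: 32³ phantoms
(1 mm) for rigid recovery, 64³ (0.5 mm) for deformable recovery, ten 48³
pairs for the masking ablation, and a two-level, 4-channel U-Net trained
30 epochs on three 48³ phantoms for the segmentation check. The library
itself has no size assumptions beyond patch divisibility by 2^levels.
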