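# Methods

This note records the models behind each pipeline stage, the defaults
and their units, the numerical choices that were genuinely open, and
what the synthetic phantoms do and do not establish about real data.

## 1. LCN phantoms

A phantom is a 3D scalar field on an anisotropic voxel grid, array
order (z, y, x) with spacing in µm. Lacunae are solid ellipsoids with
semi-axes drawn uniformly from `lacuna_axes_range` (default
1.8–2.8 µm); canaliculi are straight cylinders (default radius
0.3 µm, length 2–4 µm) rooted just inside the lacunar surface and
directed outward with random jitter. All geometry is defined in
physical space and then sampled by voxel-centre membership, so the
coarse z step is honoured rather than approximated.

Separability constraints make the ground truth unambiguous:

- lacuna centres are separated by at least the sum of their largest
  semi-axes plus `min_separation` (default 2.5 µm, about three
  opening-ball diameters);
- tubes of one lacuna are pairwise separated by ≥ 50° so two
  attachments never merge into one blob;
- tubes keep `tube_clearance` (1.2 µm) from every other lacuna and
  from other lacunae's tubes, so no blob bridges two lacunae unless a
  test constructs one deliberately;
- tubes lie entirely inside the field: a tube clipped by the stack
  boundary to a voxel or two is not a countable attachment, so the
  generator does not create such tubes (border-crossing lacunae may
  still carry clipped tubes when `allow_border=True`).

If a requested tube cannot be placed within bounded retries it is
skipped and the ground-truth count reflects what was actually placed;
ground truth is always *descriptive* of the rendered volume. A
lacuna's `touches_border` flag is true iff its rasterization has a
voxel on an array face — the same observable the segmentation's edge
rule uses.

Image formation: background and foreground intensities (defaults
50/200, arbitrary units), then an optional Gaussian PSF (σ in µm,
converted per axis to voxels), then additive Gaussian sensor noise.
Ground truth describes the pre-blur, pre-noise objects.

The default field (48×160×160 voxels at 0.48/0.24/0.24 µm ≈
23×38×38 µm) is a deliberately small tile: it preserves grid
anisotropy and object scale while a full phantom segments in about a
second, and 20 lacunae in that volume give exact, seed-stable truth.
The consequence is a lacunar density far above real cortical bone
(~10⁵–10⁶/mm³ vs ~2–9×10⁴/mm³); all recovery statements are
ratios/counts and are unaffected, but absolute densities from
phantoms should never be read as physiological.

## 2. LCN segmentation and morphometry

Chain: local threshold → opening → label → boundary recovery → volume
filter + edge removal → per-lacuna morphometry → scan metrics.

- **Local threshold.** Foreground iff intensity > local mean ×
  (1 + offset), local mean over a window specified in µm (default
  10 µm) and converted to an odd per-axis voxel count. The offset
  default 0.2 is a fraction of the local mean. Bright-on-dark
  contrast is a contract; inverted data must be inverted by the
  caller. For noisy stacks `denoise_sigma` (µm) Gaussian-smooths the
  intensities first; ~the PSF width is a good value. The exact local
  statistic used by any given commercial/laboratory implementation is
  generally unspecified; mean-based with multiplicative offset is the
  simplest member of that family and is exposed in full.
- **Opening.** A ball of `opening_radius` µm (default 1.0; 0.8 for
  the phantom scale) digitized per axis. It must exceed the
  canaliculus radius and stay below the smallest lacunar semi-axis;
  for the continuum shape to survive opening, the lacuna's smallest
  surface curvature radius (b²_min/a_max for an ellipsoid) should
  also exceed it.
- **Boundary recovery.** Opening a *digitized* convex body shaves a
  partial one-voxel surface shell even when the continuum body is
  open with respect to the ball. Each labeled body is therefore grown
  `boundary_recovery_voxels` (default 1) back into the thresholded
  image, claiming only voxels the threshold marked as object and
  never bridging the background gap between bodies. Without this step
  volumes are biased low by 3–9% at the phantom grid and the shaved
  fragments register as spurious canaliculi.
- **Filters.** Components outside [min, max] µm³ are dropped (noise
  and vascular canals); defaults 50–2000 µm³ for real lacunae, set
  explicitly when segmenting phantoms. Components whose *pre-recovery*
  body touches any of the six faces are dropped — the recovery ring or
  an attached tube touching a face must not change border status.
- **Surface area.** Marching-cubes isosurface at level 0.5 on a
  padded crop, scaled by the voxel spacing. Regions under 8 voxels
  use exposed voxel-face area instead, where a sub-voxel isosurface
  collapses toward an octahedron and badly underestimates.
- **Canaliculi.** Candidate voxels are the pre-opening binary minus
  all lacuna bodies; their connected components are computed once
  globally. A lacuna's count is the number of distinct components
  intersecting the lacuna dilated by `dilation_radius_voxels`
  (default 1, isotropic in index space). Components smaller than
  `min_canaliculus_voxels` (default 2) are ignored as speckle. A
  component touching two lacunae counts once for each — the count is
  per-lacuna, not a global edge count.
- **Metrics.** Lac.N = retained count / imaged volume (per mm³);
  Cn.N = mean over lacunae of count/surface-area (per µm²). Cn.N is
  sometimes typeset with volumetric units in the literature; the
  per-surface-area definition is the one computed here. An empty scan
  reports density 0 and NaN for per-lacuna means — never silent
  zeros.
- **Acellular area.** Maximum-intensity projection along z, global
  threshold (fixed or Otsu); the acellular fraction is the percentage
  of considered pixels below threshold. An optional exclusion mask
  replaces manual exclusion of cement/resting lines, removed from
  numerator and denominator alike. On sparse phantoms most of the
  projection is unstained, so this figure is large by construction.

Validated behaviour on phantoms: on clean phantoms the interior
lacuna count is exact, volumes are within ~2.5% of the voxel-count
oracle, and canaliculus counts are exact across hundreds of lacunae;
at 10%-of-contrast noise with a 0.3 µm PSF, density errors stay
within one or two lacunae in twenty and Cn/Lac within a few percent.
Under blur the threshold halo inflates individual lacunar *volumes*
substantially (a resolution effect familiar from real confocal data);
densities and counts are robust, so volume comparisons are only
meaningful between identically acquired stacks.

## 3. Raman composition

Spectra are (wavenumber, intensity) pairs on a strictly increasing
grid. Band areas are trapezoidal integrals over fixed windows —
phosphate 950–970, carbonate 1050–1070, amide I 1660–1690 cm⁻¹ —
after removing a linear baseline through the two window endpoints.
Each baseline anchor is the mean intensity over `anchor_halfwidth`
(default 6 cm⁻¹) just outside the window: anchoring on single noisy
samples tilts the whole baseline and is the dominant error for the
small carbonate band. Mineral/matrix = phosphate/amide areas;
carbonate/phosphate = carbonate/phosphate areas; crystallinity =
1/FWHM of the phosphate band, with the half-maximum crossings found
by linear interpolation in a search window `fwhm_search_factor` ×
wider than the band window (widen it for bands broader than
σ ≈ 5 cm⁻¹). PMMA background is removed by least-squares scaling of a
measured reference over a PMMA-dominant window (default
790–830 cm⁻¹, where bone scatters little).

All three parameters are ratios of areas or reciprocal widths, hence
exactly invariant under global intensity scaling; phosphate
normalization is provided for presentation but cannot change any
parameter.

Synthetic spectra place Gaussian bands *inside* these windows with
widths (σ ≈ 2.5–5 cm⁻¹) such that each window captures ≥ 99.9% of its
band, keeping the closed-form areas (A·σ·√2π) valid oracles for
windowed integrals. The synthetic carbonate band sits at 1060 cm⁻¹:
the nominal ~1070 cm⁻¹ position is the *edge* of the standard
window, and a band centred on a window edge cannot be integrated
there with an endpoint baseline. Real ν₁PO₄ bands are broader
(FWHM ≈ 15–20 cm⁻¹) than the synthetic default, so phantom
crystallinity values are higher than typical bone; recovery accuracy,
not absolute value, is what the synthetic route establishes.

Noise: window integration has an irreducible area-noise floor
σ_area ≈ noise·√(width·step). For the carbonate band (smallest area)
this floor alone is ~4% of the area per 1% of phosphate-amplitude
noise, so accurate carbonate/phosphate recovery by pure window
integration requires sub-percent noise; the validation suite uses
0.5%. Multiple spectra per bone are handled by computing parameters
per spectrum and averaging parameters per bone (not averaging
spectra), so one aberrant spectrum cannot distort a band shape;
`average_per_bone` implements this, and averaging spectra first is
deliberately not the default.

## 4. Cortical geometry and porosity

The idealized annulus treats T.Ar and M.Ar as areas of concentric
circles: r_p = √(T.Ar/π), r_e = √(M.Ar/π), Ct.Th = r_p − r_e, J₀ =
(π/2)(r_p⁴ − r_e⁴), RCA = B.Ar/T.Ar. These are exact algebraic
identities (round-trip tested to 1e-12) intended as interpretable
summaries; measured thickness, moments and densities in input tables
are passed through untouched.

Porosity on a binary mask: (1) despeckle — bone components smaller
than `despeckle_min_voxels` (default 27 = a 3³ cube; the value used
by commercial tomography software is not published, so it is
config-exposed) are removed; (2) the envelope is formed by 3D
morphological closing (radius 2 voxels, mask padded so the closing
cannot erode the object at array faces) followed by 2D hole filling
of every slice along the axis — slice filling is what closes the
marrow canal, which is open at the volume ends; (3) cavities =
envelope minus bone; the largest connected cavity is the marrow canal
and is excluded; (4) porosity = 100 × remaining cavity voxels /
(envelope voxels excluding marrow). A cavity contiguous with the
marrow counts as marrow — the rule is stated rather than inferred,
and a phantom test documents it. On annulus phantoms the recovered
porosity equals the planted value exactly.

## 5. Cohort statistics

Repeated measurements are averaged hierarchically: repeats within a
scan → scan mean; scan means → animal value, unweighted. Pooling raw
repeats across scans weights scans by repeat count and is
deliberately not offered; a test demonstrates the two disagree with
unequal repeats. All inference runs on animal values.

The three-way ANOVA is a fixed-effects full factorial (age × sex ×
genotype) with sum-to-zero contrasts. Each term's sum of squares is
marginal (Type III): the residual-SS increase from dropping that
term's columns from the full model. On balanced designs this equals
the classical cell-means decomposition (verified against an
independent brute-force oracle to 1e-8 and against statsmodels'
Type III tables); under imbalance it remains well-defined. Empty
design cells abort with the offending cells listed; silently
refitting a smaller model would change the hypotheses being tested.
Degenerate inputs are explicit: an all-constant response reports
F = 0, p = 1 for every term.

Tukey HSD uses the studentized-range distribution on animal-level
cell means, with the standard error from a supplied residual mean
square (classical post hoc usage) or the pooled within-group variance
by default. `tukey_max_q` exposes the maximum pairwise q through the
same internals so that calibration simulations can compare it to a
single critical value — "any adjusted p < α" and "max q exceeds the
α critical value" are the same event, and the studentized-range tail
function is expensive enough (~30 ms per evaluation) that per-pair
p-values inside a 2000-replicate simulation would dominate runtime.

Calibration measured by simulation: the family-wise error of the
Tukey family over age × genotype cells under a global null lands at
≈ 4–5% at nominal 5%, and a planted genotype multiplier of 0.74 with
lognormal residual sd 0.15 and n = 10 animals per cell is detected
with power ≈ 1.

The cohort generator draws each scan value as baseline ×
level-multipliers × exp(N(0, σ)); lognormal residuals keep area-like
traits positive and make planted effects exact ratios of cell means.
The recorded "true cell mean" is the deterministic (σ = 0) product;
arithmetic means carry the usual exp(σ²/2) lognormal offset, which
cancels in all ratio comparisons.

## 6. What the synthetic route does and does not show

Passing phantom recovery proves the *implementation*: segmentation,
counting, integration, algebra and inference do what they claim under
known geometry, known optics and known noise. It does not prove
*biological* validity on real stacks: real lacunae are not perfect
ellipsoids, canaliculi curve and branch, staining is inhomogeneous,
backgrounds drift, and real Raman bands overlap and sit on
fluorescence. Those effects are exactly the ones the exposed
configuration (windows, offsets, radii, filters) exists to absorb,
and parameter choices for real data must be validated against real
reference measurements. Problem sizes throughout (phantom fields,
replicate counts) are chosen so the full validation suite runs in
about a minute on one CPU; all statistical checks are
seed-deterministic.
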