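# bonemorph

Quantitative phenotyping of aging cortical bone, driven end to end by
synthetic data with exact ground truth.

Aging-bone studies characterize the same bone at three scales: the
osteocyte **lacunar-canalicular network** (LCN) imaged by confocal
microscopy, **matrix composition** measured by Raman
microspectroscopy, and **cross-sectional geometry** from micro-CT
tables — then compare genotype/sex/age groups with factorial
statistics. `bonemorph` implements that entire analysis chain as a
reusable, tested Python package, plus generators that fabricate every
input kind (image stacks, spectra, binary masks, cohort tables) with
known truth, so the whole pipeline is exercisable and validatable
without any microscope.

## What it computes

**LCN morphometry** (`bonemorph.lcn`) — from a 3D fluorescence stack
with anisotropic voxels: adaptive local thresholding (physical-space
window), morphological opening to strip canaliculi, volume filtering
and edge removal, then per-lacuna volume (Lac.V, µm³),
isosurface-mesh surface area (µm²), and canaliculi per lacuna
(Cn/Lac) by counting blobs of the pre-opening binary that overlap the
dilated lacuna. Scan-level outputs: lacunar density Lac.N (#/mm³),
mean Lac.V, mean Cn/Lac, canalicular density Cn.N (attachments per
µm² of lacunar surface), and the acellular area fraction of the
maximum-intensity projection.

**Raman composition** (`bonemorph.raman`) — band-area parameters with
PMMA background subtraction and phosphate normalization:

- mineral/matrix = area(ν₁PO₄, 950–970 cm⁻¹) / area(amide I, 1660–1690 cm⁻¹)
- carbonate/phosphate = area(CO₃²⁻, 1050–1070 cm⁻¹) / area(ν₁PO₄)
- crystallinity = 1 / FWHM of the ~960 cm⁻¹ phosphate band

**Cortical geometry** (`bonemorph.geometry`) — the idealized annulus
model of the mid-diaphysis: r_p = √(T.Ar/π), r_e = √(M.Ar/π),
Ct.Th = r_p − r_e, J₀ = (π/2)(r_p⁴ − r_e⁴), RCA = B.Ar/T.Ar; plus 3D
cortical porosity on binary masks (despeckle → shrink-wrap envelope →
marrow isolation → pore fraction).

**Group statistics** (`bonemorph.stats`) — the hierarchical procedure
used for repeated in-scan measurements: repeats → scan means → animal
mean (the animal is the experimental unit), three-way fixed-effects
ANOVA (age × sex × genotype, Type III, sum-to-zero coding) and Tukey
HSD post hoc comparisons via the studentized-range distribution.

**Synthetic data** (`bonemorph.synthetic`) — ellipsoidal lacunae with
tube canaliculi rasterized in physical space onto the anisotropic
grid (optional PSF blur and sensor noise); Gaussian-band spectra over
smooth backgrounds with closed-form true areas; voxelized cortical
annuli with planted pores; factorial cohort tables with multiplicative
effects and lognormal residuals. Everything is deterministic given a
seed, and every generator returns the ground truth alongside the data.

## Worked example

Quantify a noisy LCN phantom and recover its planted truth:

```python
from bonemorph import (LCNPhantomParams, SegmentationConfig,
                       generate_lcn_stack, quantify_stack,
                       radii_from_areas, derived_annulus)

params = LCNPhantomParams(n_lacunae=20, noise_sd=15.0, psf_sigma=0.3, seed=42)
stack, truth = generate_lcn_stack(params)

cfg = SegmentationConfig(min_lacuna_volume=10.0, max_lacuna_volume=500.0,
                         opening_radius=0.8, denoise_sigma=0.3)
metrics, records, labels = quantify_stack(stack, cfg)

print(f"lacunae found : {metrics.n_lacunae} (truth: {truth.n_interior})")
print(f"Lac.N         : {metrics.lac_density:,.0f} /mm^3 (truth: {truth.lac_density:,.0f})")
print(f"Cn/Lac        : {metrics.mean_canaliculi_per_lacuna:.2f} "
      f"(truth: {truth.mean_canaliculi_per_lacuna:.2f})")

r_p, r_e = radii_from_areas(2.0, 0.9)   # T.Ar, M.Ar in mm^2
ct, j0 = derived_annulus(r_p, r_e)
print(f"r_p={r_p:.3f} mm  r_e={r_e:.3f} mm  Ct.Th={ct:.3f} mm  J0={j0:.3f} mm^4")
```

prints

```
lacunae found : 20 (truth: 20)
Lac.N         : 588,688 /mm^3 (truth: 588,688)
Cn/Lac        : 5.00 (truth: 5.00)
r_p=0.798 mm  r_e=0.535 mm  Ct.Th=0.263 mm  J0=0.508 mm^4
```

Despite 10% noise and a 0.3 µm PSF, all 20 interior lacunae and all
canaliculus attachments are recovered; the annulus line converts a
2.0 mm² total and 0.9 mm² marrow area into the idealized radii,
cortical thickness, and polar moment of inertia. (Phantom fields are
small, so their lacunar densities are intentionally higher than real
cortical bone; the recovery arithmetic is scale-free.)

The same stages are scriptable from a shell:

```sh
bonemorph synth lcn --seed 1 --out phantom/
bonemorph lcn quantify --stack phantom/phantom.tif --config seg.json --out results/
bonemorph synth cohort --seed 2 --out cohort/
bonemorph stats run --table cohort/cohort.csv --trait T_Ar --out stats/
```

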