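"""Synthetic-data generators with exact ground truth.

Every input the pipeline consumes can be fabricated here with known
truth: 3D lacunar-canalicular phantoms (ellipsoidal lacunae with
tube-like canaliculi), Raman spectra built from Gaussian bands over a
smooth background, voxelized cortical annuli with embedded pores, and
factorial cohort tables with planted age x sex x genotype effects.

All geometry is defined in physical space (micrometres) and then
sampled onto the anisotropic voxel grid, so the phantoms honour the
confocal convention of a z step several times coarser than the
in-plane pixel size.  Generators are deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import ImageStack, UM3_PER_MM3

__all__ = [
    "LCNPhantomParams",
    "LacunaTruth",
    "LCNGroundTruth",
    "PlacementError",
    "generate_lcn_stack",
    "GaussianBand",
    "SpectrumParams",
    "TrueRatios",
    "generate_raman_spectrum",
    "TraitSpec",
    "CohortParams",
    "generate_cohort_table",
    "AnnulusParams",
    "generate_annulus_mask",
]


class PlacementError(RuntimeError):
    """Raised when objects cannot be placed after bounded retries."""


# ---------------------------------------------------------------------------
# LCN phantom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LCNPhantomParams:
    """Parameters of a lacunar-canalicular phantom.

    The default field is a scaled-down tile of a confocal acquisition:
    the anisotropy of the voxel grid (z step coarser than in-plane) is
    preserved while the field of view is kept small enough that a full
    phantom segments in seconds.  Lacunae are ellipsoids with semi-axes
    drawn uniformly from ``lacuna_axes_range``; canaliculi are straight
    cylinders of radius ``canaliculus_radius`` emanating outward from
    the lacunar surface with jittered directions.

    ``canaliculi_per_lacuna`` is either a fixed integer or the mean of
    a Poisson draw when ``canaliculi_poisson`` is True (capped at
    ``max_canaliculi`` so that tubes remain geometrically separable).
    """

    stack_shape: tuple[int, int, int] = (48, 160, 160)
    voxel_spacing: tuple[float, float, float] = (0.48, 0.24, 0.24)
    n_lacunae: int = 20
    lacuna_axes_range: tuple[float, float] = (1.8, 2.8)
    canaliculi_per_lacuna: float = 5
    canaliculi_poisson: bool = False
    max_canaliculi: int = 9
    canaliculus_radius: float = 0.3
    canaliculus_length_range: tuple[float, float] = (2.0, 4.0)
    background_intensity: float = 50.0
    foreground_intensity: float = 200.0
    noise_sd: float = 0.0
    psf_sigma: float = 0.0
    min_separation: float = 2.5
    tube_clearance: float = 1.2
    min_tube_angle_deg: float = 50.0
    border_margin: float = 0.5
    allow_border: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_lacunae < 0:
            raise ValueError("n_lacunae must be >= 0")
        lo, hi = self.lacuna_axes_range
        if not (0 < lo <= hi):
            raise ValueError("lacuna_axes_range must be positive and ordered")
        if self.canaliculus_radius <= 0:
            raise ValueError("canaliculus_radius must be > 0")
        if self.foreground_intensity <= self.background_intensity:
            raise ValueError("foreground intensity must exceed background")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")


@dataclass(frozen=True)
class LacunaTruth:
    """Ground truth for one phantom lacuna (pre-blur, pre-noise)."""

    center: tuple[float, float, float]     # um, (z, y, x)
    semi_axes: tuple[float, float, float]  # um, (z, y, x)
    volume: float                          # analytic (4/3) pi a b c, um^3
    voxel_volume: float                    # rasterized voxel count x voxel volume, um^3
    canaliculi_count: int
    touches_border: bool


@dataclass(frozen=True)
class LCNGroundTruth:
    """Scan-level phantom truth."""

    lacunae: tuple[LacunaTruth, ...]
    lac_density: float        # interior lacunae per mm^3
    mean_lac_volume: float    # mean analytic volume of interior lacunae, um^3
    physical_volume: float    # um^3

    @property
    def n_interior(self) -> int:
        return sum(not lac.touches_border for lac in self.lacunae)

    @property
    def mean_canaliculi_per_lacuna(self) -> float:
        interior = [l.canaliculi_count for l in self.lacunae if not l.touches_border]
        return float(np.mean(interior)) if interior else float("nan")


def _ellipsoid_voxels(shape, spacing, center, semi_axes):
    """Return (slices, bool patch) of voxels whose centres fall inside the
    ellipsoid.  Voxel centre of index i along an axis sits at i*spacing."""
    sp = np.asarray(spacing, float)
    c = np.asarray(center, float)
    ax = np.asarray(semi_axes, float)
    lo = np.maximum(np.floor((c - ax) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((c + ax) / sp).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return tuple(slice(0, 0) for _ in range(3)), np.zeros((0, 0, 0), bool)
    grids = np.ix_(*[(np.arange(lo[d], hi[d]) * sp[d] - c[d]) / ax[d] for d in range(3)])
    patch = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2 <= 1.0
    return tuple(slice(lo[d], hi[d]) for d in range(3)), patch


def _tube_voxels(shape, spacing, p0, p1, radius):
    """Voxels within ``radius`` of the segment p0-p1 (physical coords)."""
    sp = np.asarray(spacing, float)
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    lo = np.maximum(np.floor((np.minimum(p0, p1) - radius) / sp).astype(int), 0)
    hi = np.minimum(np.ceil((np.maximum(p0, p1) + radius) / sp).astype(int) + 1, shape)
    if np.any(hi <= lo):
        return tuple(slice(0, 0) for _ in range(3)), np.zeros((0, 0, 0), bool)
    zz, yy, xx = np.meshgrid(
        *[np.arange(lo[d], hi[d]) * sp[d] for d in range(3)], indexing="ij"
    )
    pts = np.stack([zz, yy, xx], axis=-1)
    d = p1 - p0
    denom = float(d @ d)
    t = np.clip(((pts - p0) @ d) / denom, 0.0, 1.0) if denom > 0 else 0.0
    nearest = p0 + t[..., None] * d if denom > 0 else np.broadcast_to(p0, pts.shape)
    dist2 = np.sum((pts - nearest) ** 2, axis=-1)
    patch = dist2 <= radius**2
    return tuple(slice(lo[d], hi[d]) for d in range(3)), patch


def _segment_point_distance(p0, p1, q):
    d = p1 - p0
    denom = float(d @ d)
    if denom == 0:
        return float(np.linalg.norm(q - p0))
    t = float(np.clip((q - p0) @ d / denom, 0.0, 1.0))
    return float(np.linalg.norm(q - (p0 + t * d)))


def _segment_segment_distance(p0, p1, q0, q1):
    """Minimum distance between two 3D segments (clamped closest points)."""
    u = p1 - p0
    v = q1 - q0
    w = p0 - q0
    a, b, c = float(u @ u), float(u @ v), float(v @ v)
    d, e = float(u @ w), float(v @ w)
    denom = a * c - b * b
    if denom > 1e-12:
        s = np.clip((b * e - c * d) / denom, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-12 else 0.0
    t = float(np.clip(t, 0.0, 1.0))
    # re-clamp s for the clamped t
    s = float(np.clip((b * t - d) / a, 0.0, 1.0)) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p0 + s * u) - (q0 + t * v)))


def generate_lcn_stack(
    params: LCNPhantomParams,
    lacunae: list[tuple[tuple[float, float, float], tuple[float, float, float]]] | None = None,
) -> tuple[ImageStack, LCNGroundTruth]:
    """Render a lacunar-canalicular phantom and its exact ground truth.

    Parameters
    ----------
    params
        Phantom parameters; the RNG is seeded from ``params.seed``.
    lacunae
        Optional explicit list of ``(center, semi_axes)`` in um, in
        ``(z, y, x)`` order, bypassing random placement (used for
        constructed test geometries).  Centres may lie anywhere,
        including outside the field.

    Returns
    -------
    (stack, truth)
        The rendered stack (float32, blurred and noised according to
        ``params``) and the ground truth describing every object
        before blur and noise.

    Raises
    ------
    PlacementError
        If ``n_lacunae`` cannot be placed with the requested minimum
        separation within a bounded number of retries.
    """
    from scipy import ndimage

    rng = np.random.default_rng(params.seed)
    shape = tuple(params.stack_shape)
    sp = np.asarray(params.voxel_spacing, float)
    extent = sp * np.asarray(shape)

    specs: list[tuple[np.ndarray, np.ndarray]] = []
    if lacunae is not None:
        specs = [(np.asarray(c, float), np.asarray(a, float)) for c, a in lacunae]
    else:
        lo, hi = params.lacuna_axes_range
        tries = 0
        max_tries = max(200 * params.n_lacunae, 1000)
        while len(specs) < params.n_lacunae:
            if tries >= max_tries:
                raise PlacementError(
                    f"placed only {len(specs)}/{params.n_lacunae} lacunae after "
                    f"{max_tries} tries; stack too small for requested density"
                )
            tries += 1
            axes = rng.uniform(lo, hi, size=3)
            if params.allow_border:
                center = rng.uniform(0, extent)
            else:
                margin = axes + params.border_margin
                if np.any(extent - 2 * margin <= 0):
                    raise PlacementError("stack smaller than one lacuna plus margin")
                center = rng.uniform(margin, extent - margin)
            ok = True
            for c2, a2 in specs:
                min_d = float(axes.max() + a2.max() + params.min_separation)
                if np.linalg.norm(center - c2) < min_d:
                    ok = False
                    break
            if ok:
                specs.append((center, axes))

    objects = np.zeros(shape, bool)
    lac_truth: list[LacunaTruth] = []
    lac_masks: list[tuple[tuple, np.ndarray]] = []

    for center, axes in specs:
        sl, patch = _ellipsoid_voxels(shape, sp, center, axes)
        objects[sl] |= patch
        lac_masks.append((sl, patch))
        # border flag from the rasterization itself: does any lacuna voxel
        # sit on an array face (consistent with what segmentation sees)
        touches = False
        for d in range(3):
            if patch.size and sl[d].start == 0 and np.take(patch, 0, axis=d).any():
                touches = True
            if patch.size and sl[d].stop == shape[d] and np.take(patch, -1, axis=d).any():
                touches = True
        # an ellipsoid entirely outside the field also "touches" nothing it
        # can be counted in; flag it as border so it is never expected
        if not patch.any():
            touches = True
        lac_truth.append(
            LacunaTruth(
                center=tuple(center),
                semi_axes=tuple(axes),
                volume=4.0 / 3.0 * math.pi * float(np.prod(axes)),
                voxel_volume=float(patch.sum()) * float(np.prod(sp)),
                canaliculi_count=0,
                touches_border=touches,
            )
        )

    # canaliculi: straight tubes normal-ish to the surface, kept clear of
    # other lacunae and of each other so attachment counts are unambiguous
    counts = [0] * len(specs)
    all_tubes: list[tuple[int, np.ndarray, np.ndarray]] = []
    tube_gap = 2 * params.canaliculus_radius + params.tube_clearance
    for i, (center, axes) in enumerate(specs):
        if params.canaliculi_poisson:
            n_want = int(rng.poisson(params.canaliculi_per_lacuna))
        else:
            n_want = int(round(params.canaliculi_per_lacuna))
        n_want = min(n_want, params.max_canaliculi)
        if n_want == 0:
            continue
        cos_max = math.cos(math.radians(params.min_tube_angle_deg))
        placed_dirs: list[np.ndarray] = []
        for _ in range(n_want):
            for _ in range(60):
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                # keep tubes angularly separated so attachments stay distinct
                if any(float(v @ u) >= cos_max for u in placed_dirs):
                    continue
                length = rng.uniform(*params.canaliculus_length_range)
                # surface exit point of the ray along v
                t_surf = 1.0 / math.sqrt(float(np.sum((v / axes) ** 2)))
                p0 = center + v * (t_surf * 0.8)   # rooted just inside the surface
                p1 = center + v * (t_surf + length)
                # a clipped tube is not a countable attachment: keep the
                # whole tube (plus its radius) inside the field
                pad = params.canaliculus_radius + sp
                if not params.allow_border and (
                    np.any(p1 < pad) or np.any(p1 > extent - pad)
                ):
                    continue
                clear = True
                for j, (c2, a2) in enumerate(specs):
                    if j == i:
                        continue
                    d = _segment_point_distance(p0, p1, c2)
                    if d < float(a2.max()) + params.tube_clearance:
                        clear = False
                        break
                if clear:
                    for owner, q0, q1 in all_tubes:
                        if owner == i:
                            continue  # same-lacuna tubes are separated by angle
                        if _segment_segment_distance(p0, p1, q0, q1) < tube_gap:
                            clear = False
                            break
                if clear:
                    sl, patch = _tube_voxels(shape, sp, p0, p1, params.canaliculus_radius)
                    objects[sl] |= patch
                    counts[i] += 1
                    placed_dirs.append(v)
                    all_tubes.append((i, p0, p1))
                    break

    lac_truth = [replace(t, canaliculi_count=c) for t, c in zip(lac_truth, counts)]

    image = np.full(shape, params.background_intensity, np.float32)
    image[objects] = params.foreground_intensity
    if params.psf_sigma > 0:
        image = ndimage.gaussian_filter(image, sigma=params.psf_sigma / sp)
    if params.noise_sd > 0:
        image = image + rng.normal(0.0, params.noise_sd, size=shape).astype(np.float32)

    phys_vol = float(np.prod(extent))
    interior = [t for t in lac_truth if not t.touches_border]
    truth = LCNGroundTruth(
        lacunae=tuple(lac_truth),
        lac_density=len(interior) / phys_vol * UM3_PER_MM3,
        mean_lac_volume=float(np.mean([t.volume for t in interior])) if interior else float("nan"),
        physical_volume=phys_vol,
    )
    return ImageStack(image.astype(np.float32), tuple(sp)), truth


# ---------------------------------------------------------------------------
# Raman spectra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GaussianBand:
    """One Gaussian band: ``amplitude * exp(-(x - center)^2 / (2 sigma^2))``."""

    center: float     # cm^-1
    amplitude: float
    sigma: float      # cm^-1

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("band sigma must be > 0")

    @property
    def area(self) -> float:
        """Closed-form integral A * sigma * sqrt(2 pi)."""
        return self.amplitude * self.sigma * math.sqrt(2.0 * math.pi)

    @property
    def fwhm(self) -> float:
        """Closed-form 2 * sigma * sqrt(2 ln 2)."""
        return 2.0 * self.sigma * math.sqrt(2.0 * math.log(2.0))


@dataclass(frozen=True)
class SpectrumParams:
    """Synthetic bone Raman spectrum: three canonical bands plus a smooth
    background polynomial and white noise.

    The background polynomial is evaluated in the scaled coordinate
    ``u = (x - mid) / (span / 2)`` (u in [-1, 1] across the grid) so
    that coefficients of order ~1 produce backgrounds comparable to the
    band amplitudes.

    Band positions sit inside the standard integration windows
    (950-970, 1050-1070, 1660-1690 cm^-1) and the default widths are
    narrow enough that each window captures essentially the whole band;
    this keeps the closed-form band areas valid oracles for
    window-integrated estimates.  The carbonate band is deliberately
    centred at 1060 rather than at its nominal ~1070 cm^-1 position:
    1070 is the *edge* of the standard integration window, and a band
    centred on a window edge cannot be integrated there with an
    endpoint baseline.
    """

    phosphate: GaussianBand = GaussianBand(960.0, 10.0, 3.0)
    carbonate: GaussianBand = GaussianBand(1060.0, 1.5, 3.0)
    amide_i: GaussianBand = GaussianBand(1675.0, 2.5, 4.5)
    extra_bands: tuple[GaussianBand, ...] = ()
    background_coeffs: tuple[float, ...] = (0.0,)
    noise_sd: float = 0.0
    grid_start: float = 50.0
    grid_stop: float = 3300.0
    grid_step: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_step <= 0 or self.grid_stop <= self.grid_start:
            raise ValueError("invalid wavenumber grid")
        for b in (self.phosphate, self.carbonate, self.amide_i, *self.extra_bands):
            if not (self.grid_start <= b.center <= self.grid_stop):
                raise ValueError(f"band center {b.center} outside grid")


@dataclass(frozen=True)
class TrueRatios:
    """Analytic band areas and the compositional parameters they imply."""

    area_phosphate: float
    area_carbonate: float
    area_amide_i: float
    fwhm_phosphate: float
    mineral_matrix: float
    carbonate_phosphate: float
    crystallinity: float


def generate_raman_spectrum(params: SpectrumParams):
    """Synthesize a spectrum; returns ``(RamanSpectrum, TrueRatios)``."""
    from .raman import RamanSpectrum

    rng = np.random.default_rng(params.seed)
    x = np.arange(params.grid_start, params.grid_stop + params.grid_step / 2, params.grid_step)
    y = np.zeros_like(x, dtype=float)
    for b in (params.phosphate, params.carbonate, params.amide_i, *params.extra_bands):
        y += b.amplitude * np.exp(-((x - b.center) ** 2) / (2.0 * b.sigma**2))
    if any(c != 0 for c in params.background_coeffs):
        mid = 0.5 * (params.grid_start + params.grid_stop)
        half = 0.5 * (params.grid_stop - params.grid_start)
        u = (x - mid) / half
        y += np.polynomial.polynomial.polyval(u, params.background_coeffs)
    if params.noise_sd > 0:
        y = y + rng.normal(0.0, params.noise_sd, size=x.shape)

    a_p, a_c, a_a = params.phosphate.area, params.carbonate.area, params.amide_i.area
    fwhm = params.phosphate.fwhm
    truth = TrueRatios(
        area_phosphate=a_p,
        area_carbonate=a_c,
        area_amide_i=a_a,
        fwhm_phosphate=fwhm,
        mineral_matrix=a_p / a_a if a_a > 0 else float("nan"),
        carbonate_phosphate=a_c / a_p if a_p > 0 else float("nan"),
        crystallinity=1.0 / fwhm,
    )
    return RamanSpectrum(wavenumbers=x, intensities=y), truth


# ---------------------------------------------------------------------------
# Factorial cohort tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TraitSpec:
    """Generative model for one measured trait.

    Each scan value is ``baseline * prod(effect multipliers for the
    animal's factor levels) * exp(N(0, residual_sd))``, i.e. lognormal
    multiplicative residuals, keeping area-like traits positive.
    ``effects`` maps ``(factor, level)`` to a multiplier, e.g.
    ``{("genotype", "iGHRKO"): 0.74}``.
    """

    baseline: float
    effects: dict = field(default_factory=dict)
    residual_sd: float = 0.1

    def cell_mean(self, age, sex, genotype) -> float:
        m = self.baseline
        for (factor, level), mult in self.effects.items():
            if {"age": age, "sex": sex, "genotype": genotype}[factor] == level:
                m *= mult
        return m


def _default_traits() -> dict:
    # mouse femur mid-diaphysis scale: T.Ar ~ 2 mm^2, with the knockout
    # reducing total area by ~26 percent
    return {
        "T_Ar": TraitSpec(2.0, {("genotype", "iGHRKO"): 0.74}, 0.1),
    }


@dataclass(frozen=True)
class CohortParams:
    """Factorial study design: age x sex x genotype with repeated scans."""

    ages: tuple = (12, 22, 30)
    sexes: tuple = ("M", "F")
    genotypes: tuple = ("control", "iGHRKO")
    n_per_cell: int = 5
    scans_per_animal: int = 4
    traits: dict = field(default_factory=_default_traits)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_cell < 2:
            raise ValueError("need n >= 2 animals per cell for ANOVA")
        if self.scans_per_animal < 1:
            raise ValueError("scans_per_animal must be >= 1")
        for name, ts in self.traits.items():
            if ts.baseline <= 0:
                raise ValueError(f"trait {name}: baseline must be > 0")
            if any(m <= 0 for m in ts.effects.values()):
                raise ValueError(f"trait {name}: multipliers must be > 0")


def generate_cohort_table(params: CohortParams) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns ``(table, truth)``.

    ``table`` has one row per scan per animal with columns
    ``animal, age, sex, genotype, scan`` plus one column per trait.
    ``truth`` holds the deterministic (sd = 0) cell mean for every
    trait and factor cell.
    """
    rng = np.random.default_rng(params.seed)
    rows = []
    animal_id = 0
    for age in params.ages:
        for sex in params.sexes:
            for genotype in params.genotypes:
                for _ in range(params.n_per_cell):
                    animal_id += 1
                    for scan in range(params.scans_per_animal):
                        row = {
                            "animal": f"A{animal_id:04d}",
                            "age": age,
                            "sex": sex,
                            "genotype": genotype,
                            "scan": scan,
                        }
                        for name, ts in params.traits.items():
                            mean = ts.cell_mean(age, sex, genotype)
                            row[name] = mean * math.exp(
                                rng.normal(0.0, ts.residual_sd)
                            ) if ts.residual_sd > 0 else mean
                        rows.append(row)
    table = pd.DataFrame(rows)

    truth_rows = []
    for age in params.ages:
        for sex in params.sexes:
            for genotype in params.genotypes:
                for name, ts in params.traits.items():
                    truth_rows.append(
                        {
                            "age": age,
                            "sex": sex,
                            "genotype": genotype,
                            "trait": name,
                            "cell_mean": ts.cell_mean(age, sex, genotype),
                        }
                    )
    return table, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# Cortical annulus masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnulusParams:
    """Voxelized hollow cylinder (cortical shell) with optional pores.

    All lengths in mm.  Pores are spheres embedded strictly inside the
    cortex; a pore that would overlap the marrow cavity or the outside
    is resampled (random placement) or rejected with an error (explicit
    placement), because marrow is not a pore.
    """

    r_periosteal: float = 0.6
    r_endosteal: float = 0.3
    height: float = 0.3
    voxel_size: float = 0.01
    n_pores: int = 0
    pore_radius_range: tuple[float, float] = (0.02, 0.04)
    pore_margin: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.r_periosteal > self.r_endosteal >= 0):
            raise ValueError("need r_periosteal > r_endosteal >= 0")
        if self.voxel_size <= 0 or self.height <= 0:
            raise ValueError("voxel_size and height must be > 0")


def generate_annulus_mask(
    params: AnnulusParams,
    pores: list[tuple[tuple[float, float, float], float]] | None = None,
) -> tuple[np.ndarray, dict]:
    """Build a binary cortical-shell mask and its true porosity.

    Parameters
    ----------
    params
        Geometry; RNG seeded from ``params.seed`` for random pores.
    pores
        Optional explicit pores as ``(center (z, y, x) mm, radius mm)``.
        An explicit pore not fully inside the cortex raises ValueError.

    Returns
    -------
    (mask, truth)
        ``mask`` is uint8 with 1 = bone; ``truth`` has keys
        ``porosity_pct`` (pore voxels / cortical-envelope voxels x 100),
        ``pore_voxels``, ``envelope_voxels``, ``n_pores``.
    """
    vs = params.voxel_size
    nz = max(int(round(params.height / vs)), 1)
    nxy = int(math.ceil(2 * params.r_periosteal / vs)) + 3
    cyx = (nxy - 1) / 2.0 * vs
    yy, xx = np.meshgrid(np.arange(nxy) * vs - cyx, np.arange(nxy) * vs - cyx, indexing="ij")
    rr = np.sqrt(yy**2 + xx**2)
    annulus2d = (rr <= params.r_periosteal) & (rr >= params.r_endosteal)
    mask = np.broadcast_to(annulus2d, (nz, nxy, nxy)).copy()
    envelope = mask.copy()          # the cortical envelope: shell incl. pores
    shape = mask.shape
    sp = (vs, vs, vs)

    rng = np.random.default_rng(params.seed)
    pore_mask = np.zeros(shape, bool)

    def carve(center, radius, explicit):
        c = np.asarray(center, float)
        ryx = math.hypot(c[1] - cyx, c[2] - cyx)
        inside = (
            params.r_endosteal + radius + params.pore_margin <= ryx
            <= params.r_periosteal - radius - params.pore_margin
            and radius <= c[0] <= params.height - radius
        )
        if not inside:
            if explicit:
                raise ValueError(
                    "pore at {} (r={}) is not strictly inside the cortex; "
                    "marrow and periosteal space are not pores".format(tuple(c), radius)
                )
            return False
        sl, patch = _ellipsoid_voxels(shape, sp, c, (radius,) * 3)
        pore_mask[sl] |= patch
        return True

    placed = 0
    if pores is not None:
        for center, radius in pores:
            carve(center, radius, explicit=True)
            placed += 1
    else:
        tries = 0
        while placed < params.n_pores and tries < 200 * max(params.n_pores, 1):
            tries += 1
            radius = rng.uniform(*params.pore_radius_range)
            theta = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(params.r_endosteal, params.r_periosteal)
            z = rng.uniform(0, params.height)
            center = (z, cyx + rad * math.sin(theta), cyx + rad * math.cos(theta))
            if carve(center, radius, explicit=False):
                placed += 1
        if placed < params.n_pores:
            raise PlacementError(
                f"placed only {placed}/{params.n_pores} pores in the cortex"
            )

    pore_mask &= envelope
    mask = envelope & ~pore_mask
    envelope_voxels = int(envelope.sum())
    pore_voxels = int(pore_mask.sum())
    truth = {
        "porosity_pct": 100.0 * pore_voxels / envelope_voxels,
        "pore_voxels": pore_voxels,
        "envelope_voxels": envelope_voxels,
        "n_pores": placed,
    }
    return mask.astype(np.uint8), truth
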