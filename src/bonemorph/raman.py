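"""Raman bone-composition parameters.

Three compositional indices are computed from a cortical-bone Raman
spectrum, each from integrated band areas:

* mineral/matrix ratio  = area(nu1 phosphate, 950-970 cm^-1)
                          / area(amide I, 1660-1690 cm^-1),
* carbonate/phosphate   = area(carbonate, 1050-1070 cm^-1)
                          / area(phosphate),
* crystallinity         = 1 / FWHM of the ~960 cm^-1 phosphate band,
                          FWHM from linear interpolation of the
                          half-maximum crossings.

Band areas are trapezoidal integrals over the configured window after
subtracting a linear baseline drawn between the window endpoints.
Because every parameter is a ratio of areas (or a peak width), all
three are invariant to global intensity scaling, and in particular to
whether the spectrum was previously normalized to the phosphate band.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "BandConfig",
    "CompositionMetrics",
    "BandError",
    "subtract_background",
    "normalize_to_phosphate",
    "band_area",
    "compute_ratios",
    "phosphate_fwhm",
    "crystallinity",
    "analyze_spectra",
    "average_per_bone",
]


class BandError(ValueError):
    """A band area or width could not be measured (named band in message)."""


@dataclass(frozen=True)
class RamanSpectrum:
    """Wavenumber grid (cm^-1, strictly increasing) plus intensities."""

    wavenumbers: np.ndarray
    intensities: np.ndarray
    background_subtracted: bool = False
    normalized: bool = False

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, float)
        y = np.asarray(self.intensities, float)
        if w.ndim != 1 or w.shape != y.shape:
            raise ValueError("wavenumbers and intensities must be equal-length 1D")
        if w.size < 2 or np.any(np.diff(w) <= 0):
            raise ValueError("wavenumber grid must be strictly increasing")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def scaled(self, factor: float) -> "RamanSpectrum":
        return replace(self, intensities=self.intensities * factor)


@dataclass(frozen=True)
class BandConfig:
    """Band windows (cm^-1) and baseline rule for the three indices."""

    phosphate_window: tuple[float, float] = (950.0, 970.0)
    carbonate_window: tuple[float, float] = (1050.0, 1070.0)
    amide_window: tuple[float, float] = (1660.0, 1690.0)
    baseline: str = "linear"           # "linear" endpoint baseline or "none"
    anchor_halfwidth: float = 6.0      # cm^-1 averaged outside each endpoint
    pmma_window: tuple[float, float] = (790.0, 830.0)
    fwhm_search_factor: float = 2.0    # half-max search extends the window

    def __post_init__(self) -> None:
        for name, (lo, hi) in (
            ("phosphate", self.phosphate_window),
            ("carbonate", self.carbonate_window),
            ("amide", self.amide_window),
        ):
            if lo >= hi:
                raise ValueError(f"{name} window must be increasing")
        windows = sorted(
            [self.phosphate_window, self.carbonate_window, self.amide_window]
        )
        for (_, hi), (lo, _) in zip(windows, windows[1:]):
            if lo < hi:
                raise ValueError("band windows must not overlap")
        if self.baseline not in ("linear", "none"):
            raise ValueError("baseline must be 'linear' or 'none'")


@dataclass(frozen=True)
class CompositionMetrics:
    mineral_matrix: float
    carbonate_phosphate: float
    crystallinity: float      # 1/cm^-1
    fwhm_phosphate: float     # cm^-1


def _window_slice(spectrum: RamanSpectrum, window, name="band"):
    w = spectrum.wavenumbers
    lo, hi = window
    if lo < w[0] or hi > w[-1]:
        raise BandError(
            f"{name} window {window} outside spectral range ({w[0]}, {w[-1]})"
        )
    return lo, hi


def _anchor_level(w, y, x0, halfwidth, side):
    """Baseline anchor at x0: mean intensity over a margin outside the
    window (noise-robust); falls back to the interpolated endpoint when
    the margin is empty or ``halfwidth`` is 0."""
    if halfwidth > 0:
        sel = (w >= x0 - halfwidth) & (w <= x0) if side == "left" else \
              (w >= x0) & (w <= x0 + halfwidth)
        if sel.any():
            return float(y[sel].mean())
    return float(np.interp(x0, w, y))


def band_area(
    spectrum: RamanSpectrum,
    window: tuple[float, float],
    baseline: str = "linear",
    name: str = "band",
    anchor_halfwidth: float = 6.0,
) -> float:
    """Trapezoidal band area over ``window`` after baseline subtraction.

    The window endpoints are placed exactly at the requested
    wavenumbers by linear interpolation of the spectrum.  The
    ``linear`` baseline is the straight segment joining the two
    endpoint levels, each level estimated as the mean intensity over a
    margin of ``anchor_halfwidth`` cm^-1 just outside the window (a
    single noisy sample would otherwise tilt the whole baseline);
    ``none`` integrates the raw curve.  A nonpositive area raises
    :class:`BandError` (it signals an unphysical or empty band, never
    a silent zero).
    """
    lo, hi = _window_slice(spectrum, window, name)
    w, y = spectrum.wavenumbers, spectrum.intensities
    inner = (w > lo) & (w < hi)
    xs = np.concatenate(([lo], w[inner], [hi]))
    ys = np.concatenate(([np.interp(lo, w, y)], y[inner], [np.interp(hi, w, y)]))
    if baseline == "linear":
        b_lo = _anchor_level(w, y, lo, anchor_halfwidth, "left")
        b_hi = _anchor_level(w, y, hi, anchor_halfwidth, "right")
        ys = ys - (b_lo + (b_hi - b_lo) * (xs - lo) / (hi - lo))
    area = float(np.trapezoid(ys, xs))
    if area <= 0:
        raise BandError(f"nonpositive {name} band area ({area:.4g}) in {window}")
    return area


def subtract_background(
    spectrum: RamanSpectrum,
    reference: RamanSpectrum,
    window: tuple[float, float] | None = None,
) -> RamanSpectrum:
    """Remove a scaled embedding-medium (PMMA) reference spectrum.

    The reference is resampled onto the spectrum grid by linear
    interpolation; the scale factor is the least-squares fit of the
    reference to the spectrum over ``window`` (default: the configured
    PMMA-dominant region around 800 cm^-1, where bone bands are
    absent).  A zero reference leaves the spectrum unchanged.
    """
    if window is None:
        window = BandConfig().pmma_window
    w = spectrum.wavenumbers
    if reference.wavenumbers[-1] < window[0] or reference.wavenumbers[0] > window[1]:
        raise ValueError("reference grid does not cover the scaling window")
    ref = np.interp(w, reference.wavenumbers, reference.intensities)
    sel = (w >= window[0]) & (w <= window[1])
    if not sel.any():
        raise ValueError(f"scaling window {window} contains no grid points")
    denom = float(ref[sel] @ ref[sel])
    scale = float(spectrum.intensities[sel] @ ref[sel]) / denom if denom > 0 else 0.0
    return replace(
        spectrum,
        intensities=spectrum.intensities - scale * ref,
        background_subtracted=True,
    )


def normalize_to_phosphate(spectrum: RamanSpectrum, cfg: BandConfig) -> RamanSpectrum:
    """Divide by the phosphate band area (the strongest mineral band).

    Raises :class:`BandError` for a nonpositive phosphate area.  All
    downstream ratios are mathematically unchanged by this step; it
    exists so spectra from different acquisitions plot on a common
    scale.
    """
    area = band_area(
        spectrum, cfg.phosphate_window, cfg.baseline, "phosphate",
        cfg.anchor_halfwidth,
    )
    return replace(spectrum, intensities=spectrum.intensities / area, normalized=True)


def phosphate_fwhm(spectrum: RamanSpectrum, cfg: BandConfig) -> float:
    """Full width at half maximum of the phosphate band, in cm^-1.

    The peak is located inside the phosphate window (a tie between
    non-adjacent equal maxima is ambiguous and raises); the half-height
    crossings are found by linear interpolation, searching an extended
    window ``fwhm_search_factor`` times wider than the band window.  A
    linear baseline across the extended window is removed first.
    """
    lo, hi = _window_slice(spectrum, cfg.phosphate_window, "phosphate")
    w, y = spectrum.wavenumbers, spectrum.intensities
    half_w = (hi - lo) / 2.0 * cfg.fwhm_search_factor
    mid = (lo + hi) / 2.0
    xlo, xhi = max(mid - half_w, w[0]), min(mid + half_w, w[-1])
    sel = (w >= xlo) & (w <= xhi)
    xs, ys = w[sel], y[sel]
    if cfg.baseline == "linear":
        ys = ys - (ys[0] + (ys[-1] - ys[0]) * (xs - xs[0]) / (xs[-1] - xs[0]))
    in_band = (xs >= lo) & (xs <= hi)
    band_vals = ys[in_band]
    peak_val = band_vals.max()
    peak_positions = np.flatnonzero(in_band)[np.flatnonzero(band_vals == peak_val)]
    if peak_positions.size > 1 and np.any(np.diff(peak_positions) > 1):
        raise BandError("ambiguous phosphate peak: two separated equal maxima")
    ip = int(peak_positions[0])
    half = peak_val / 2.0

    left = None
    for i in range(ip, 0, -1):
        if ys[i - 1] < half <= ys[i]:
            left = xs[i - 1] + (xs[i] - xs[i - 1]) * (half - ys[i - 1]) / (ys[i] - ys[i - 1])
            break
    right = None
    for i in range(ip, len(ys) - 1):
        if ys[i + 1] < half <= ys[i]:
            right = xs[i] + (xs[i + 1] - xs[i]) * (ys[i] - half) / (ys[i] - ys[i + 1])
            break
    if left is None or right is None:
        raise BandError("no half-maximum crossing within the phosphate search window")
    return float(right - left)


def crystallinity(spectrum: RamanSpectrum, cfg: BandConfig) -> float:
    """Mineral crystallinity, ``1 / FWHM`` of the phosphate band."""
    return 1.0 / phosphate_fwhm(spectrum, cfg)


def compute_ratios(spectrum: RamanSpectrum, cfg: BandConfig) -> CompositionMetrics:
    """All three compositional parameters for one spectrum."""
    a_p = band_area(spectrum, cfg.phosphate_window, cfg.baseline, "phosphate", cfg.anchor_halfwidth)
    a_c = band_area(spectrum, cfg.carbonate_window, cfg.baseline, "carbonate", cfg.anchor_halfwidth)
    a_a = band_area(spectrum, cfg.amide_window, cfg.baseline, "amide I", cfg.anchor_halfwidth)
    fwhm = phosphate_fwhm(spectrum, cfg)
    return CompositionMetrics(
        mineral_matrix=a_p / a_a,
        carbonate_phosphate=a_c / a_p,
        crystallinity=1.0 / fwhm,
        fwhm_phosphate=fwhm,
    )


def analyze_spectra(
    spectra: dict[str, RamanSpectrum],
    cfg: BandConfig | None = None,
) -> pd.DataFrame:
    """Per-spectrum parameter table; index = spectrum id."""
    cfg = cfg or BandConfig()
    rows = {}
    for name, spec in spectra.items():
        m = compute_ratios(spec, cfg)
        rows[name] = {
            "mineral_matrix": m.mineral_matrix,
            "carbonate_phosphate": m.carbonate_phosphate,
            "crystallinity": m.crystallinity,
            "fwhm_phosphate": m.fwhm_phosphate,
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def average_per_bone(params: pd.DataFrame, bone_of: dict[str, str]) -> pd.DataFrame:
    """Average per-spectrum parameters within each bone.

    Multiple spectra are acquired per section; parameters are computed
    per spectrum and their mean is reported per bone (averaging the
    parameters, not the spectra, so one aberrant spectrum cannot skew a
    band shape).
    """
    df = params.copy()
    df["bone"] = [bone_of[s] for s in df.index]
    return df.groupby("bone").mean(numeric_only=True)
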