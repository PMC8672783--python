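"""Idealized cortical cross-section geometry and 3D porosity.

A mid-diaphyseal cortex is summarized as a circular annulus: the
periosteal (outer) radius follows from the total cross-sectional area,
r_p = sqrt(T.Ar / pi), and the endosteal (inner) radius from the
marrow area, r_e = sqrt(M.Ar / pi).  From the two radii the idealized
cortical thickness (r_p - r_e) and polar moment of inertia
(pi/2)(r_p^4 - r_e^4) follow; relative cortical area is
RCA = B.Ar / T.Ar.  These are forward-model summaries of tomography
tables -- measured thickness, moments, and densities are passed
through, never recomputed.

Cortical porosity is measured on a binary 3D mask: despeckle, wrap the
envelope tightly around the object (morphological closing plus
per-slice hole filling), isolate the marrow cavity as the largest
internal cavity, and report the remaining cavity voxels as a
percentage of the cortical envelope excluding marrow.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "radii_from_areas",
    "derived_annulus",
    "rca",
    "derive_table",
    "cortical_porosity",
]


def radii_from_areas(t_ar, m_ar):
    """Idealized periosteal and endosteal radii from T.Ar and M.Ar.

    ``r = sqrt(A / pi)`` for each area; units follow the inputs
    (mm^2 -> mm).  Accepts scalars or arrays.  Requires
    ``T.Ar > M.Ar >= 0`` elementwise.
    """
    t = np.asarray(t_ar, float)
    m = np.asarray(m_ar, float)
    if np.any(m < 0):
        raise ValueError("marrow area must be >= 0")
    if np.any(m >= t):
        raise ValueError("marrow area must be smaller than total area")
    r_p = np.sqrt(t / np.pi)
    r_e = np.sqrt(m / np.pi)
    if np.isscalar(t_ar) and np.isscalar(m_ar):
        return float(r_p), float(r_e)
    return r_p, r_e


def derived_annulus(r_p, r_e):
    """Idealized cortical thickness and polar moment for an annulus.

    ``Ct.Th = r_p - r_e``; ``J0 = (pi/2)(r_p^4 - r_e^4)`` (mm, mm^4
    for radii in mm).  Requires ``r_p > r_e`` elementwise.
    """
    rp = np.asarray(r_p, float)
    re = np.asarray(r_e, float)
    if np.any(rp <= re):
        raise ValueError("periosteal radius must exceed endosteal radius")
    ct = rp - re
    j0 = np.pi / 2.0 * (rp**4 - re**4)
    if np.isscalar(r_p) and np.isscalar(r_e):
        return float(ct), float(j0)
    return ct, j0


def rca(b_ar, t_ar):
    """Relative cortical bone area, ``B.Ar / T.Ar``, in (0, 1]."""
    b = np.asarray(b_ar, float)
    t = np.asarray(t_ar, float)
    if np.any(t <= 0):
        raise ValueError("total area must be > 0")
    if np.any(b > t):
        raise ValueError("bone area cannot exceed total area")
    out = b / t
    return float(out) if np.isscalar(b_ar) else out


def derive_table(table: pd.DataFrame) -> pd.DataFrame:
    """Add derived geometry columns to an area table.

    Expects columns ``T_Ar``, ``M_Ar``, ``B_Ar`` (mm^2); adds
    ``r_periosteal``, ``r_endosteal``, ``Ct_Th_ideal``, ``J0_ideal``
    and ``RCA``.  All other columns (measured thickness, densities,
    trabecular indices, ...) pass through untouched.
    """
    for col in ("T_Ar", "M_Ar", "B_Ar"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    out = table.copy()
    r_p, r_e = radii_from_areas(out["T_Ar"].to_numpy(), out["M_Ar"].to_numpy())
    ct, j0 = derived_annulus(r_p, r_e)
    out["r_periosteal"] = r_p
    out["r_endosteal"] = r_e
    out["Ct_Th_ideal"] = ct
    out["J0_ideal"] = j0
    out["RCA"] = rca(out["B_Ar"].to_numpy(), out["T_Ar"].to_numpy())
    return out


def cortical_porosity(
    mask: np.ndarray,
    despeckle_min_voxels: int = 27,
    closing_radius: int = 2,
) -> float:
    """Percent porosity of a binary cortical mask (1 = bone).

    Pipeline: (1) despeckle -- drop bone components smaller than
    ``despeckle_min_voxels``; (2) shrink-wrap the envelope --
    morphological closing with a ``closing_radius``-voxel ball followed
    by 2D hole filling on every slice along axis 0, yielding the solid
    envelope of the object; (3) cavities are envelope voxels that are
    not bone; the largest connected cavity is taken to be the marrow
    canal and excluded; (4) porosity = 100 x remaining cavity voxels /
    (envelope voxels excluding marrow).

    A cavity contiguous with the marrow canal is counted as marrow,
    not as a pore.  Raises if the mask contains no object.
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 3:
        raise ValueError("mask must be 3D")
    if not mask.any():
        raise ValueError("no cortical shell detectable: mask is empty")

    labels, n = ndimage.label(mask)
    if despeckle_min_voxels > 1 and n > 1:
        sizes = np.bincount(labels.ravel())
        small = np.flatnonzero(sizes < despeckle_min_voxels)
        small = small[small > 0]
        if small.size:
            mask = mask & ~np.isin(labels, small)
    if not mask.any():
        raise ValueError("no cortical shell detectable after despeckling")

    if closing_radius > 0:
        # pad so the closing's erosion half cannot eat the object at the
        # array faces (an object touching a face would otherwise lose a
        # closing_radius-thick slab of its envelope)
        pad = closing_radius + 1
        closed = ndimage.binary_closing(
            np.pad(mask, pad), structure=ndimage.generate_binary_structure(3, 1),
            iterations=closing_radius,
        )[pad:-pad, pad:-pad, pad:-pad]
    else:
        closed = mask
    envelope = np.empty_like(closed)
    for z in range(closed.shape[0]):
        envelope[z] = ndimage.binary_fill_holes(closed[z])

    cavities = envelope & ~mask
    cav_labels, n_cav = ndimage.label(cavities)
    if n_cav == 0:
        return 0.0
    sizes = np.bincount(cav_labels.ravel())[1:]
    marrow = int(np.argmax(sizes)) + 1
    pore_voxels = int(cavities.sum() - sizes[marrow - 1])
    denom = int(envelope.sum() - sizes[marrow - 1])
    if denom <= 0:
        raise ValueError("degenerate envelope: no cortex outside the marrow cavity")
    return 100.0 * pore_voxels / denom
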