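"""Reading and writing the pipeline's on-disk formats.

Stacks travel as multi-page TIFF with the voxel spacing in the
ImageJ-style metadata plus a JSON side-car (``<stem>.spacing.json``)
so that no TIFF-metadata dialect is load-bearing.  Spectra are plain
two-column CSV (wavenumber, intensity); tables are CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .core import ImageStack
from .raman import RamanSpectrum

__all__ = [
    "read_stack",
    "write_stack",
    "read_spectrum",
    "write_spectrum",
    "read_table",
    "write_table",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".spacing.json")


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF plus a spacing side-car."""
    path = Path(path)
    dz, dy, dx = stack.spacing
    tifffile.imwrite(
        path,
        stack.data,
        resolution=(1.0 / dx, 1.0 / dy),
        metadata={"spacing": dz, "unit": "um", "axes": "ZYX"},
    )
    _sidecar(path).write_text(
        json.dumps({"spacing_um_zyx": list(stack.spacing)}) + "\n"
    )


def read_stack(path, spacing=None) -> ImageStack:
    """Read a multi-page TIFF; spacing from the side-car unless given.

    ``spacing`` overrides everything and is ``(z, y, x)`` in um.
    """
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if spacing is None:
        side = _sidecar(path)
        if not side.exists():
            raise FileNotFoundError(
                f"no voxel spacing given and no side-car {side.name}; "
                "pass spacing=(z, y, x) in um"
            )
        spacing = json.loads(side.read_text())["spacing_um_zyx"]
    return ImageStack(data, tuple(spacing))


def write_spectrum(spectrum: RamanSpectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": spectrum.wavenumbers, "intensity": spectrum.intensities}
    ).to_csv(path, index=False)


def read_spectrum(path) -> RamanSpectrum:
    """Two-column CSV (wavenumber, intensity), header optional."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns")
    first = df.columns[0]
    try:  # headerless file: the 'header' is actually the first data row
        float(first)
        df = pd.read_csv(path, header=None)
    except (TypeError, ValueError):
        pass
    w = df.iloc[:, 0].to_numpy(float)
    y = df.iloc[:, 1].to_numpy(float)
    return RamanSpectrum(wavenumbers=w, intensities=y)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_table(table: pd.DataFrame, path, index: bool = False) -> None:
    table.to_csv(path, index=index)
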