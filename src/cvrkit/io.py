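"""NIfTI and table I/O helpers."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import GeometryError
from .grids import Grid
from .response_models import BoldSeries

__all__ = ["save_volume", "load_volume", "load_probability_stack", "load_bold", "save_bold"]


def save_volume(data: np.ndarray, grid: Grid, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data).astype(dtype), grid.affine)
    img.to_filename(str(path))


def load_volume(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    grid = Grid(tuple(data.shape[:3]), img.affine)
    return data, grid


def load_probability_stack(gm_path, wm_path, csf_path) -> tuple[np.ndarray, Grid]:
    """Stack GM/WM/CSF probability volumes into an (X, Y, Z, 3) array."""
    vols, grids = zip(*(load_volume(p) for p in (gm_path, wm_path, csf_path)))
    for g in grids[1:]:
        if g.shape != grids[0].shape or not np.allclose(g.affine, grids[0].affine):
            raise GeometryError("tissue probability volumes must share one grid")
    return np.stack(vols, axis=-1), grids[0]


def load_bold(path, mask_path=None, tr: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise GeometryError("BOLD input must be a 4-D NIfTI")
    grid = Grid(tuple(data.shape[:3]), img.affine)
    if tr is None:
        tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
        tr = round(tr, 6)  # zooms are float32; keep the nominal TR
    if tr <= 0:
        raise GeometryError("repetition interval missing; pass it explicitly")
    if mask_path is not None:
        mask, mgrid = load_volume(mask_path)
        if mgrid.shape != grid.shape:
            raise GeometryError("mask grid does not match the BOLD grid")
        mask = mask > 0.5
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    return BoldSeries(data, tr, mask, grid)


def save_bold(series: BoldSeries, path) -> None:
    img = nib.Nifti1Image(series.data.astype(np.float32), series.grid.affine)
    zooms = tuple(series.grid.spacing) + (series.repetition_interval,)
    img.header.set_zooms(zooms)
    img.to_filename(str(path))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
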