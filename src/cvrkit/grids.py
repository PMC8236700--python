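"""Axis-aligned voxel-grid geometry shared by the resampling steps.

All spatial reasoning is done in world millimetres.  Grids are described
by a shape and a NIfTI-style affine; only axis-aligned affines (diagonal
3x3 part with positive spacings) are supported — rotated or sheared grids
raise :class:`GeometryError`, since the partial-volume footprint algebra
below is separable per axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError

__all__ = ["Grid", "overlap_matrix", "downsample_probabilities", "nn_resample", "parent_index_maps"]


@dataclass(frozen=True)
class Grid:
    """An axis-aligned 3-D voxel grid (shape + affine)."""

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        A = np.asarray(self.affine, dtype=float)
        if A.shape != (4, 4):
            raise GeometryError("affine must be 4x4")
        R = A[:3, :3]
        if not np.allclose(R, np.diag(np.diag(R))):
            raise GeometryError("only axis-aligned (diagonal) affines are supported")
        if np.any(np.diag(R) <= 0):
            raise GeometryError("voxel spacings must be positive")
        object.__setattr__(self, "affine", A)
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    @classmethod
    def from_spacing(cls, shape, spacing, origin=(0.0, 0.0, 0.0)) -> "Grid":
        """Grid whose voxel (0,0,0) has its *center* at ``origin + spacing/2``.

        With a shared ``origin`` the world box ``[origin, origin + shape*spacing]``
        is tiled exactly, which is how the phantom nests its 1 mm and
        low-resolution grids.
        """
        spacing = np.broadcast_to(np.asarray(spacing, dtype=float), 3).copy()
        A = np.eye(4)
        A[:3, :3] = np.diag(spacing)
        A[:3, 3] = np.asarray(origin, dtype=float) + spacing / 2.0
        return cls(tuple(shape), A)

    @property
    def spacing(self) -> np.ndarray:
        return np.diag(self.affine[:3, :3]).copy()

    @property
    def origin(self) -> np.ndarray:
        """World coordinate of the low corner (edge) of voxel (0,0,0)."""
        return self.affine[:3, 3] - self.spacing / 2.0

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + (np.arange(self.shape[axis]) + 0.5) * self.spacing[axis]

    def axis_edges(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis] + 1) * self.spacing[axis]

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


def overlap_matrix(dst_edges: np.ndarray, src_edges: np.ndarray) -> np.ndarray:
    """1-D interval-overlap lengths, shape (n_dst, n_src)."""
    lo = np.maximum(dst_edges[:-1, None], src_edges[None, :-1])
    hi = np.minimum(dst_edges[1:, None], src_edges[None, 1:])
    return np.clip(hi - lo, 0.0, None)


def downsample_probabilities(prob: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Overlap-volume-weighted mean of a high-res volume under each
    low-res voxel footprint.

    ``prob`` may carry trailing component axes (e.g. an (X,Y,Z,3) stack of
    tissue probabilities).  Low-res voxels whose footprint misses the
    source grid entirely come back as 0.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.shape[:3] != src.shape:
        raise GeometryError("probability volume does not match the source grid")
    Ws = [overlap_matrix(dst.axis_edges(ax), src.axis_edges(ax)) for ax in range(3)]
    cover = [W.sum(axis=1) for W in Ws]
    for W, c in zip(Ws, cover):
        if not np.any(c > 0):
            raise GeometryError("grids are disjoint in world space")
    num = np.einsum("ia,jb,kc,abc...->ijk...", Ws[0], Ws[1], Ws[2], prob, optimize=True)
    den = cover[0][:, None, None] * cover[1][None, :, None] * cover[2][None, None, :]
    if prob.ndim > 3:
        den = den.reshape(den.shape + (1,) * (prob.ndim - 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _nearest_index(dst_centers: np.ndarray, src_centers: np.ndarray,
                   src_spacing: float) -> np.ndarray:
    # Nearest source center; exact midpoints resolve to the lower index.
    u = (dst_centers - src_centers[0]) / src_spacing
    idx = np.ceil(u - 0.5 - 1e-12).astype(int)
    return np.clip(idx, 0, src_centers.size - 1)


def nn_resample(volume: np.ndarray, src: Grid, dst: Grid) -> np.ndarray:
    """Nearest-neighbor resampling of a (possibly multi-component) volume."""
    volume = np.asarray(volume)
    if volume.shape[:3] != src.shape:
        raise GeometryError("volume does not match the source grid")
    idx = [_nearest_index(dst.axis_centers(ax), src.axis_centers(ax), src.spacing[ax])
           for ax in range(3)]
    return volume[np.ix_(idx[0], idx[1], idx[2])]


def parent_index_maps(hi: Grid, lo: Grid) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-axis index of the low-res voxel whose *footprint* contains each
    high-res voxel center (clipped at the grid border)."""
    out = []
    for ax in range(3):
        u = (hi.axis_centers(ax) - lo.origin[ax]) / lo.spacing[ax]
        out.append(np.clip(np.floor(u).astype(int), 0, lo.shape[ax] - 1))
    return tuple(out)
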