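"""Partial volume correction (PVC) of low-resolution CVR metric maps.

A low-resolution metric value I0 mixes the contributions of gray matter,
white matter and CSF in proportion to the voxel's tissue composition:
``I0 = g0*Ig + w0*Iw + c0*Ic``.  Assuming each tissue's intensity is
constant over a small neighborhood, every voxel within a given radius
(default 9 mm, which with 3.5 mm isotropic voxels yields 81 voxels and
hence 81 equations) contributes one such equation, and the per-tissue
intensities are recovered by least-absolute-deviations (LAD) regression —
preferred over least squares for its robustness to outliers.  Solutions
for tissue classes absent from the central voxel are not assigned.  The
corrected map lives on the high-resolution (1 mm) anatomical grid: each
high-res voxel receives the solution of its own majority tissue class.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GeometryError
from .grids import Grid, downsample_probabilities, nn_resample, parent_index_maps

__all__ = [
    "NeighborhoodSpec",
    "PvcSolution",
    "PvcResult",
    "neighborhood_offsets",
    "downsample_fractions",
    "lad_solve",
    "solve_voxel_pvc",
    "apply_pvc",
    "nn_resample",
]

MIN_NEIGHBORS = 3  # an over-determined 3-unknown system needs >= 3 equations


@dataclass(frozen=True)
class NeighborhoodSpec:
    """Spherical neighborhood: radius in mm over a (possibly anisotropic) grid."""

    radius: float = 9.0
    voxel_size: tuple[float, float, float] = (3.5, 3.5, 3.5)

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise GeometryError("radius must be non-negative")
        if any(v <= 0 for v in self.voxel_size):
            raise GeometryError("voxel sizes must be positive")


def neighborhood_offsets(spec: NeighborhoodSpec) -> np.ndarray:
    """Integer lattice offsets within the sphere, center-to-center in mm.

    The boundary is inclusive and (0,0,0) is always a member.  For a 9 mm
    radius on a 3.5 mm isotropic grid this gives 81 offsets.
    """
    size = np.asarray(spec.voxel_size, dtype=float)
    nmax = np.floor(spec.radius / size + 1e-9).astype(int)
    ax = [np.arange(-n, n + 1) for n in nmax]
    I, J, K = np.meshgrid(*ax, indexing="ij")
    d2 = (I * size[0]) ** 2 + (J * size[1]) ** 2 + (K * size[2]) ** 2
    keep = d2 <= spec.radius**2 + 1e-9
    return np.column_stack([I[keep], J[keep], K[keep]])


def downsample_fractions(prob_maps: np.ndarray, highres_grid: Grid, lowres_grid: Grid) -> np.ndarray:
    """Tissue fractions (g, w, c) per low-res voxel.

    ``prob_maps`` is an (X, Y, Z, 3) stack of GM/WM/CSF probabilities on
    the high-resolution grid; each low-res voxel's fractions are the
    overlap-volume-weighted means of the probabilities under its footprint.
    """
    prob_maps = np.asarray(prob_maps, dtype=float)
    if prob_maps.ndim != 4 or prob_maps.shape[3] != 3:
        raise GeometryError("prob_maps must be an (X, Y, Z, 3) stack")
    if prob_maps.min() < -1e-9 or prob_maps.max() > 1 + 1e-9:
        raise GeometryError("probabilities must lie in [0, 1]")
    return downsample_probabilities(prob_maps, highres_grid, lowres_grid)


def lad_solve(A: np.ndarray, b: np.ndarray, eps: float = 1e-9,
              max_iter: int = 100, tol: float = 1e-13) -> np.ndarray:
    """Least-absolute-deviations fit via iteratively reweighted least squares.

    Minimizes ``sum |A x - b|`` with weights ``1 / max(|r|, eps)``.  Small
    dense systems only (the PVC design is at most a few hundred rows by 3
    columns).
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    for _ in range(max_iter):
        r = b - A @ x
        w = 1.0 / np.maximum(np.abs(r), eps)
        Aw = A * w[:, None]
        try:
            x_new = np.linalg.solve(A.T @ Aw, Aw.T @ b)
        except np.linalg.LinAlgError:
            x_new, *_ = np.linalg.lstsq(np.sqrt(w)[:, None] * A, np.sqrt(w) * b,
                                        rcond=None)
        if np.max(np.abs(x_new - x)) < tol:
            x = x_new
            break
        x = x_new
    return x


@dataclass
class PvcSolution:
    """Unmixed per-tissue intensities for one low-resolution voxel.

    Classes absent from the central voxel, or unresolvable ones, carry NaN.
    """

    i_g: float
    i_w: float
    i_c: float
    rank_ok: bool
    n_neighbors_used: int

    def as_array(self) -> np.ndarray:
        return np.array([self.i_g, self.i_w, self.i_c])


def solve_voxel_pvc(
    intensities: np.ndarray,
    fractions: np.ndarray,
    present_classes: np.ndarray,
) -> PvcSolution:
    """Solve one voxel's neighborhood mixing system for (Ig, Iw, Ic).

    Parameters
    ----------
    intensities:
        Metric values of the usable neighbors (masked ones already removed).
    fractions:
        Matching (n, 3) GM/WM/CSF fractions.
    present_classes:
        Booleans marking which classes have nonzero fraction in the central
        voxel; solutions for absent classes are not assigned.

    The system is solved by least-absolute-deviations over the classes that
    appear anywhere in the neighborhood.  ``rank_ok`` is False (and nothing
    is assigned) when there are fewer than three usable neighbors or the
    design is numerically rank-deficient.
    """
    intensities = np.asarray(intensities, dtype=float)
    A = np.asarray(fractions, dtype=float)
    present = np.asarray(present_classes, dtype=bool)
    out = np.full(3, np.nan)
    if A.ndim != 2 or A.shape[1] != 3 or intensities.shape != (A.shape[0],):
        raise GeometryError("fractions must be (n, 3) matching the intensities")
    n = intensities.size

    cols = np.flatnonzero(np.any(A > 0, axis=0))
    if n < MIN_NEIGHBORS or cols.size == 0:
        return PvcSolution(*out, rank_ok=False, n_neighbors_used=n)
    design = A[:, cols]
    rank = np.linalg.matrix_rank(design)
    if rank < cols.size:
        return PvcSolution(*out, rank_ok=False, n_neighbors_used=n)

    x = lad_solve(design, intensities)
    assigned = np.full(3, np.nan)
    assigned[cols] = x
    out[present] = assigned[present]
    return PvcSolution(*out, rank_ok=True, n_neighbors_used=n)


@dataclass
class PvcResult:
    """Output of :func:`apply_pvc`."""

    highres: np.ndarray            # corrected map on the high-res grid
    solutions: np.ndarray          # (X, Y, Z, 3) per-tissue solutions, low-res
    rank_ok: np.ndarray            # low-res boolean: system solved
    fallback: np.ndarray           # low-res boolean: uncorrected value used
    fallback_fraction: float


def apply_pvc(
    metric_map: np.ndarray,
    fractions: np.ndarray,
    mask: np.ndarray,
    lowres_grid: Grid,
    highres_probs: np.ndarray,
    highres_grid: Grid,
    spec: NeighborhoodSpec | None = None,
) -> PvcResult:
    """Partial-volume-correct a low-res metric map onto the high-res grid.

    For every in-mask low-res voxel the neighborhood system is solved by
    LAD (neighbors outside the mask are excluded).  Each high-res voxel
    then receives the solution of its own majority tissue class (argmax of
    the three probabilities, ties to the first class) from the low-res
    voxel whose footprint contains it, provided that class is present
    there; otherwise it falls back to the uncorrected value.  High-res
    voxels with no tissue at all stay NaN.
    """
    metric_map = np.asarray(metric_map, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    mask = np.asarray(mask, dtype=bool) & np.isfinite(metric_map)
    if spec is None:
        spec = NeighborhoodSpec(voxel_size=tuple(lowres_grid.spacing))
    if metric_map.shape != tuple(lowres_grid.shape):
        raise GeometryError("metric map does not match the low-res grid")
    if fractions.shape != metric_map.shape + (3,):
        raise GeometryError("fractions must be (X, Y, Z, 3) on the low-res grid")

    offsets = neighborhood_offsets(spec)
    shape = metric_map.shape
    solutions = np.full(shape + (3,), np.nan)
    rank_ok = np.zeros(shape, dtype=bool)
    fallback = np.zeros(shape, dtype=bool)

    centers = np.argwhere(mask)
    for vx in centers:
        pos = offsets + vx
        inside = np.all((pos >= 0) & (pos < shape), axis=1)
        pos = pos[inside]
        use = mask[pos[:, 0], pos[:, 1], pos[:, 2]]
        pos = pos[use]
        sol = solve_voxel_pvc(
            metric_map[pos[:, 0], pos[:, 1], pos[:, 2]],
            fractions[pos[:, 0], pos[:, 1], pos[:, 2]],
            fractions[tuple(vx)] > 0,
        )
        i, j, k = vx
        solutions[i, j, k] = sol.as_array()
        rank_ok[i, j, k] = sol.rank_ok
        if not sol.rank_ok:
            fallback[i, j, k] = True

    # Project onto the high-res grid by majority tissue class.
    ix, iy, iz = parent_index_maps(highres_grid, lowres_grid)
    parent = np.ix_(ix, iy, iz)
    probs = np.asarray(highres_probs, dtype=float)
    if probs.shape != tuple(highres_grid.shape) + (3,):
        raise GeometryError("highres_probs must be (X, Y, Z, 3) on the high-res grid")
    majority = np.argmax(probs, axis=3)
    has_tissue = probs.sum(axis=3) > 0
    parent_in_mask = mask[parent]

    sol_hi = np.take_along_axis(solutions[parent], majority[..., None], axis=3)[..., 0]
    uncorrected = metric_map[parent]
    out = np.where(np.isfinite(sol_hi), sol_hi, uncorrected)
    out[~(has_tissue & parent_in_mask)] = np.nan
    used_fallback = has_tissue & parent_in_mask & ~np.isfinite(sol_hi)

    n_mask = int(mask.sum())
    frac_fb = float(np.mean(used_fallback[has_tissue & parent_in_mask])) if n_mask else 0.0
    return PvcResult(out, solutions, rank_ok, fallback, frac_fb)
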