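"""Digital phantom with known per-tissue ground truth.

Generates a high-resolution layered head geometry — a central CSF
(ventricular) compartment, a white-matter ellipsoid core, a cortical
gray-matter ribbon of realistic (~2.5 mm) thickness, and a thin outer
CSF shell — split into four angular sectors that
stand in for vascular territories, plus a low-resolution 4-D BOLD series
simulated from the time-delay convolution model.  Because the cortical
ribbon is thinner than a low-resolution voxel, every low-res cortical
voxel genuinely mixes tissues, which is exactly the partial-volume
situation the correction is meant to undo.  All randomness (measurement
noise) flows through one seeded generator, so outputs are reproducible
bit for bit.

Default truth values sit at physiologically realistic magnitudes for a
+10 mmHg step: GM ssCVR ~0.30 %/mmHg with tau ~24 s, WM ~0.13 %/mmHg with
tau ~48 s, and a small positive fast CSF response (surface-vein signal
bleeding into CSF, so CSF is not assumed null).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import CvrkitError
from .grids import Grid
from .pvc import downsample_fractions
from .response_models import (
    DEFAULT_FINE_DT,
    DEFAULT_PRE_ADVANCE,
    BoldSeries,
    _RegressorBank,
    fit_standard,
)
from .stimulus import ProtocolSpec, StimulusTrace, build_step_protocol, resample_to_frames

__all__ = [
    "PhantomSpec",
    "PhantomGeometry",
    "PhantomData",
    "generate_geometry",
    "generate_bold",
    "simulate_convolution_cohort",
]

CLASS_NAMES = ("gm", "wm", "csf")


@dataclass(frozen=True)
class PhantomSpec:
    """Ground-truth parameters and acquisition settings of the phantom.

    Truth tau values should sit on the fitting grid (even seconds) and
    truth time delays on the delay grid (multiples of 0.2 s, counted on
    the post-advance convention) when exact-recovery tests are intended.
    """

    highres_shape: tuple[int, int, int] = (70, 70, 42)
    highres_voxel: float = 1.0            # mm
    lowres_voxel: float = 3.5             # mm
    sscvr: tuple[float, float, float] = (0.30, 0.13, 0.05)   # %/mmHg (GM, WM, CSF)
    tau: tuple[float, float, float] = (24.0, 48.0, 10.0)     # s
    td: tuple[float, float, float] = (2.2, 2.8, 1.6)         # s (post-advance grid)
    noise_sd: float = 1.0                 # % of baseline intensity per frame
    drift_slope: float = 0.002            # %/s linear drift
    baseline_intensity: float = 1000.0    # arbitrary scanner units
    protocol: ProtocolSpec = field(default_factory=ProtocolSpec)
    petco2_dt: float = 0.5                # s, sampling of the written trace
    n_frames: int = 150
    tr: float = 2.4                       # s
    gm_thickness: float = 2.5             # mm cortical ribbon
    csf_thickness: float = 2.0            # mm shell
    smooth_sigma: float = 1.0             # mm; 0 gives a blocky (pure-class) geometry
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise CvrkitError("noise_sd must be non-negative")
        if min(self.tau) <= 0 or self.tr <= 0 or self.n_frames < 10:
            raise CvrkitError("invalid phantom timing parameters")
        if self.n_frames * self.tr > self.protocol.total_duration + 1e-9:
            raise CvrkitError("protocol shorter than the BOLD acquisition")

    @property
    def lowres_shape(self) -> tuple[int, int, int]:
        mm = np.asarray(self.highres_shape) * self.highres_voxel
        return tuple(int(np.floor(m / self.lowres_voxel + 1e-9)) for m in mm)


@dataclass
class PhantomGeometry:
    """High-resolution tissue probabilities and territory labels."""

    probs: np.ndarray                     # (X, Y, Z, 3) GM/WM/CSF
    territories: np.ndarray               # int labels 1..4 (0 outside)
    highres_grid: Grid
    lowres_grid: Grid


def generate_geometry(spec: PhantomSpec) -> PhantomGeometry:
    """Build the layered ellipsoid geometry on the 1 mm grid.

    WM core, GM ribbon of ``gm_thickness`` (Euclidean distance from the
    core surface), CSF shell beyond it; class borders are smoothed with a
    Gaussian of ``smooth_sigma`` mm and renormalized so probabilities sum
    to at most 1, creating genuine partial-volume voxels.
    """
    shape = spec.highres_shape
    lo_shape = spec.lowres_shape
    if min(lo_shape) < 4:
        raise CvrkitError("phantom too small to contain four territories")
    vx = spec.highres_voxel
    grid_hi = Grid.from_spacing(shape, vx)
    grid_lo = Grid.from_spacing(lo_shape, spec.lowres_voxel)

    half = np.asarray(shape, dtype=float) * vx / 2.0
    margin = spec.gm_thickness + spec.csf_thickness + 3.0 * max(spec.smooth_sigma, vx)
    semi = half - margin
    if np.any(semi <= 2 * spec.lowres_voxel):
        raise CvrkitError("phantom shape too small for the requested shell thicknesses")

    coords = [(np.arange(n) + 0.5) * vx - h for n, h in zip(shape, half)]
    X, Y, Z = np.meshgrid(*coords, indexing="ij")
    u = np.sqrt((X / semi[0]) ** 2 + (Y / semi[1]) ** 2 + (Z / semi[2]) ** 2)
    core = u <= 1.0
    ventricle = u <= 0.35            # interior CSF, like deep ventricular CSF
    wm = core & ~ventricle
    dist = ndimage.distance_transform_edt(~core, sampling=vx)
    gm = (dist > 0) & (dist <= spec.gm_thickness)
    csf = ventricle | (
        (dist > spec.gm_thickness) & (dist <= spec.gm_thickness + spec.csf_thickness)
    )
    onehot = np.stack(
        [gm, wm, csf, ~(gm | wm | csf)], axis=-1
    ).astype(float)

    head = core | (dist <= spec.gm_thickness + spec.csf_thickness)
    if spec.smooth_sigma > 0:
        sigma_vox = spec.smooth_sigma / vx
        smoothed = np.stack(
            [ndimage.gaussian_filter(onehot[..., i], sigma=sigma_vox) for i in range(3)],
            axis=-1,
        )
        # Internal tissue borders are smooth, the head boundary crisp: inside
        # the head the three tissue probabilities renormalize to exactly 1
        # (as anatomical segmentations do), outside they are zero.
        total = smoothed.sum(axis=-1, keepdims=True)
        probs = smoothed / np.where(total > 0, total, 1.0)
        probs[~head] = 0.0
    else:
        probs = onehot[..., :3]
        probs[~head] = 0.0

    theta = np.arctan2(Y, X)
    sector = np.floor((theta + np.pi) / (np.pi / 2.0)).astype(int)
    territories = np.clip(sector, 0, 3) + 1
    territories[probs.sum(axis=-1) <= 0] = 0
    return PhantomGeometry(probs, territories, grid_hi, grid_lo)


@dataclass
class PhantomData:
    """Simulated acquisition plus everything needed to score a recovery."""

    series: BoldSeries
    petco2: StimulusTrace                 # protocol trace as it would be recorded
    petco2_frames: StimulusTrace          # resampled to the frame grid (aligned)
    fractions: np.ndarray                 # (X, Y, Z, 3) low-res tissue fractions
    geometry: PhantomGeometry
    truth: dict[str, np.ndarray]          # per-class (GM, WM, CSF) parameter truth
    truth_maps: dict[str, np.ndarray]     # low-res fraction-mixed metric maps

    def purity(self, class_index: int, tol: float = 1e-6) -> np.ndarray:
        """Low-res voxels composed (numerically) purely of one class."""
        return self.fractions[..., class_index] >= 1.0 - tol


def generate_bold(geometry: PhantomGeometry, spec: PhantomSpec) -> PhantomData:
    """Simulate the low-resolution 4-D BOLD series from the phantom truth.

    Each tissue class responds with its own ssCVR, tau and delay to the
    convolved step stimulus; a low-res voxel's response is the
    fraction-weighted mixture of the class responses (the forward model is
    linear in composition, so mixing at low resolution equals averaging
    the high-res responses under the voxel footprint).  A linear drift and
    seeded white Gaussian noise are added, and the percent-scale response
    is mean-centered per voxel so that the voxel's temporal mean equals
    the baseline intensity exactly, making percent normalization an exact
    inverse in the noiseless case.
    """
    protocol = build_step_protocol(spec.protocol, spec.petco2_dt)
    frames = resample_to_frames(protocol, spec.tr, spec.n_frames)
    t = frames.times
    bank = _RegressorBank(frames, DEFAULT_FINE_DT)

    responses = np.stack(
        [
            spec.sscvr[c] * bank.at_frames(spec.tau[c], t,
                                           net_shift=spec.td[c] - DEFAULT_PRE_ADVANCE)
            for c in range(3)
        ]
    )                                                     # (3, T), percent units
    drift = spec.drift_slope * t

    fractions = downsample_fractions(geometry.probs, geometry.highres_grid,
                                     geometry.lowres_grid)
    # The brain mask keeps only fully tissue-covered voxels: the tissue
    # mixing model presumes g + w + c = 1, which holds inside the head but
    # not for voxels straddling its surface.
    mask = fractions.sum(axis=-1) >= 1.0 - 1e-6

    x = np.einsum("xyzc,ct->xyzt", fractions, responses) + drift
    x -= x.mean(axis=3, keepdims=True)
    data = np.zeros(x.shape)
    data[mask] = spec.baseline_intensity * (1.0 + x[mask] / 100.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(x.shape)
        data[mask] += spec.baseline_intensity * (spec.noise_sd / 100.0) * noise[mask]

    series = BoldSeries(data, spec.tr, mask, geometry.lowres_grid)

    # Reference mCVR per class: the standard-model slope of the noiseless
    # pure-class series (mCVR is itself a model summary, not a phantom input).
    mcvr = np.empty(3)
    for c in range(3):
        xc = responses[c] + drift
        mcvr[c] = fit_standard(100.0 + xc - xc.mean(), frames).mcvr

    truth = {
        "sscvr": np.asarray(spec.sscvr, dtype=float),
        "tau": np.asarray(spec.tau, dtype=float),
        "td": np.asarray(spec.td, dtype=float),
        "mcvr": mcvr,
    }
    # Fraction-mixed maps; exact for the metric itself only when the class
    # dynamics agree (equal tau/td), which is how the unmixing tests use them.
    truth_maps = {
        name: np.einsum("xyzc,c->xyz", fractions, truth[name])
        for name in ("mcvr", "sscvr", "tau", "td")
    }
    for name in truth_maps:
        truth_maps[name][~mask] = np.nan
    return PhantomData(series, protocol, frames, fractions, geometry, truth, truth_maps)


def simulate_convolution_cohort(
    n_subjects: int = 50,
    n_voxels: int = 150,
    seed: int = 0,
    r_range: tuple[float, float] = (0.5, 0.8),
    sscvr: float = 0.3,
    tau_grid: np.ndarray | None = None,
    protocol: ProtocolSpec | None = None,
    n_frames: int = 150,
    tr: float = 2.4,
) -> tuple[StimulusTrace, list[BoldSeries]]:
    """Cohort of single-"slice" subjects generated from the convolution model.

    Each subject is a bag of voxels with tau drawn uniformly from the
    fitting grid and zero net delay; per-voxel white-noise amplitude is set
    so the voxel's expected Pearson correlation with its regressor is drawn
    uniformly from ``r_range`` (moderate, physiologic SNR).  Intended for
    model-comparison experiments (e.g. BIC of the standard vs convolution
    model across subjects).  Returns the frame-grid stimulus and one
    ``BoldSeries`` of shape (n_voxels, 1, 1, n_frames) per subject.
    """
    from .response_models import DEFAULT_TAU_GRID
    from .grids import Grid

    tau_grid = DEFAULT_TAU_GRID if tau_grid is None else np.asarray(tau_grid)
    protocol = protocol or ProtocolSpec()
    frames = resample_to_frames(build_step_protocol(protocol, 0.5), tr, n_frames)
    bank = _RegressorBank(frames, DEFAULT_FINE_DT)
    rng = np.random.default_rng(seed)
    baseline = 1000.0

    subjects = []
    for _ in range(n_subjects):
        taus = rng.choice(tau_grid, size=n_voxels)
        r_targets = rng.uniform(*r_range, size=n_voxels)
        data = np.empty((n_voxels, 1, 1, n_frames))
        for v in range(n_voxels):
            x = sscvr * bank.at_frames(taus[v], frames.times)
            sd = x.std() * np.sqrt(1.0 / r_targets[v] ** 2 - 1.0)
            x = x - x.mean() + rng.normal(0.0, sd, n_frames)
            data[v, 0, 0] = baseline * (1.0 + x / 100.0)
        grid = Grid.from_spacing((n_voxels, 1, 1), 3.5)
        subjects.append(BoldSeries(data, tr, np.ones((n_voxels, 1, 1), bool), grid))
    return frames, subjects
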