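"""Voxel-wise BOLD response models for a step CO2 stimulus.

Three nested descriptions of the BOLD response S(t) to the end-tidal CO2
waveform P(t) are fit per voxel, each with a linear drift term and a
constant baseline:

1. standard:     S(t) = mCVR * P(t)                  + alpha*t + b + eps
2. convolution:  S(t) = ssCVR * (P (*) h_tau)(t)     + alpha*t + b + eps
3. time delay:   S(t) = ssCVR * (P (*) h_tau)(t-TD') + alpha*t + b + eps

where ``h_tau(s) = exp(-s/tau)`` truncated at ``5*tau`` and normalized to
unit area, so a sustained step of amplitude A converges to A.  ``tau``
(the speed of the vasodilatory response) is grid-searched from 2 to 100 s
in 2 s steps; the time delay is grid-searched from 0 to 5 s in 0.2 s steps
after first advancing the convolved regressor 2 s so that it precedes the
BOLD signal everywhere.  mCVR and ssCVR are regression slopes in percent
BOLD signal change per mmHg CO2.  The two models are compared per voxel by
the Bayesian information criterion BIC = n*ln(SSE/n) + (p+1)*ln(n) with
p = 2 for the standard and p = 3 for the convolution model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import FitError, ProtocolError
from .grids import Grid
from .stimulus import StimulusTrace

__all__ = [
    "DEFAULT_TAU_GRID",
    "DEFAULT_TD_GRID",
    "DEFAULT_PRE_ADVANCE",
    "DEFAULT_FINE_DT",
    "BoldSeries",
    "ExponentialKernel",
    "FitConfig",
    "StandardFit",
    "ConvolutionFit",
    "DelayFit",
    "VolumeFit",
    "percent_normalize",
    "fit_standard",
    "convolve_exponential",
    "fit_convolution",
    "fit_time_delay",
    "compute_bic",
    "fit_volume",
]

DEFAULT_TAU_GRID = 2.0 * np.arange(1, 51)          # 2, 4, ..., 100 s
DEFAULT_TD_GRID = 0.2 * np.arange(0, 26)           # 0, 0.2, ..., 5.0 s
DEFAULT_PRE_ADVANCE = 2.0                          # s, applied before the TD search
DEFAULT_FINE_DT = 0.1                              # s, sub-frame working grid


@dataclass
class BoldSeries:
    """A 4-D BOLD acquisition: (x, y, z, t) plus timing and a brain mask."""

    data: np.ndarray
    repetition_interval: float
    brain_mask: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
        if self.data.ndim != 4:
            raise FitError("BOLD data must be 4-D (x, y, z, t)")
        if self.n_frames < 10:
            raise FitError("need at least 10 temporal frames")
        if self.repetition_interval <= 0:
            raise FitError("repetition interval must be positive")
        if self.brain_mask.shape != self.data.shape[:3]:
            raise FitError("brain mask shape must match the spatial shape")
        if tuple(self.grid.shape) != self.data.shape[:3]:
            raise FitError("grid shape must match the spatial shape")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    @property
    def frame_times(self) -> np.ndarray:
        return (np.arange(self.n_frames) + 0.5) * self.repetition_interval


@dataclass(frozen=True)
class ExponentialKernel:
    """Truncated exponential-decay kernel ``exp(-s/tau)`` on ``[0, 5*tau]``.

    Discrete weights are the exact integrals of the exponential over each
    sampling interval, so that convolving a sample-and-hold input equals
    the continuous convolution on the sampling grid; the weight sum (the
    normalization constant, ``tau * (1 - e^-5)`` in the continuous limit)
    divides the kernel for exact unit steady-state gain.
    """

    tau: float
    dt: float

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise FitError("tau must be positive")
        if self.dt <= 0:
            raise FitError("kernel sampling interval must be positive")

    @property
    def support(self) -> float:
        return 5.0 * self.tau

    @property
    def normalization_c(self) -> float:
        """Continuous-limit area of the truncated kernel."""
        return self.tau * (1.0 - np.exp(-5.0))

    def weights(self) -> np.ndarray:
        """Normalized lag weights ``w[0..K]`` with ``w[0] = 0``.

        ``w[k]`` carries the kernel mass on ``[(k-1)*dt, min(k*dt, 5*tau)]``.
        """
        n = int(np.ceil(self.support / self.dt - 1e-12))
        edges = np.minimum(np.arange(n + 1) * self.dt, self.support)
        mass = np.exp(-edges[:-1] / self.tau) - np.exp(-edges[1:] / self.tau)
        w = np.concatenate(([0.0], mass))
        return w / w.sum()


def percent_normalize(series: BoldSeries) -> tuple[BoldSeries, np.ndarray]:
    """Express each voxel's series as percent of its temporal mean.

    Returns the normalized series and the validity mask: voxels inside the
    brain mask whose temporal mean is non-positive are flagged invalid and
    excluded from fitting.
    """
    means = series.data.mean(axis=3)
    valid = series.brain_mask & (means > 0)
    out = np.full_like(series.data, np.nan)
    out[valid] = 100.0 * series.data[valid] / means[valid][:, None]
    normalized = BoldSeries(out, series.repetition_interval, valid, series.grid)
    return normalized, valid


def _ols(X: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """OLS of columns of Y on X. Returns (betas, residuals, sse)."""
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    return beta, resid, np.einsum("t...,t...->...", resid, resid)


def fit_standard(voxel_series: np.ndarray, petco2: StimulusTrace) -> "StandardFit":
    """Standard linear model: slope of BOLD on PETCO2 with drift + baseline."""
    y = np.asarray(voxel_series, dtype=float)
    if y.shape != petco2.values.shape:
        raise FitError("series and stimulus must share the frame grid")
    if np.ptp(petco2.values) == 0:
        raise FitError("constant PETCO2 regressor: standard fit degenerate")
    X = np.column_stack([petco2.values, petco2.times, np.ones_like(y)])
    beta, resid, sse = _ols(X, y)
    return StandardFit(mcvr=float(beta[0]), alpha=float(beta[1]),
                       baseline=float(beta[2]), residuals=resid, sse=float(sse))


@dataclass
class StandardFit:
    mcvr: float
    alpha: float
    baseline: float
    residuals: np.ndarray
    sse: float


def convolve_exponential(
    petco2: StimulusTrace, tau: float, fine_dt: float = DEFAULT_FINE_DT
) -> StimulusTrace:
    """Convolve a PETCO2 trace with the normalized exponential kernel.

    The trace is linearly upsampled to ``fine_dt`` (sub-frame resolution,
    needed because the delay grid is finer than a repetition interval),
    convolved causally, and returned on the fine grid.  Samples preceding
    the trace are padded with its first value, so a trace that starts at
    its resting baseline is treated as having been at baseline forever.
    """
    if tau <= 0:
        raise FitError("tau must be positive")
    kernel = ExponentialKernel(tau, fine_dt)
    t0, t1 = float(petco2.times[0]), float(petco2.times[-1])
    n_fine = int(np.floor((t1 - t0) / fine_dt + 1e-9)) + 1
    t_fine = t0 + np.arange(n_fine) * fine_dt
    x = petco2.at(t_fine)
    w = kernel.weights()
    pad = np.full(w.size - 1, x[0])
    y = np.convolve(np.concatenate([pad, x]), w)[w.size - 1 : w.size - 1 + n_fine]
    return StimulusTrace(t_fine, y, fine_dt)


class _RegressorBank:
    """Caches fine-grid convolutions and their frame-time samplings."""

    def __init__(self, petco2: StimulusTrace, fine_dt: float):
        self.petco2 = petco2
        self.fine_dt = fine_dt
        self._fine: dict[float, StimulusTrace] = {}

    def fine(self, tau: float) -> StimulusTrace:
        key = float(tau)
        if key not in self._fine:
            self._fine[key] = convolve_exponential(self.petco2, key, self.fine_dt)
        return self._fine[key]

    def at_frames(self, tau: float, times: np.ndarray, net_shift: float = 0.0) -> np.ndarray:
        """Convolved regressor delayed by ``net_shift`` s, sampled at frame times."""
        return self.fine(tau).at(times - net_shift)


@dataclass
class ConvolutionFit:
    tau: float
    sscvr: float
    alpha: float
    baseline: float
    residuals: np.ndarray
    sse: float
    pearson_r: float
    convolved_fine: StimulusTrace


@dataclass
class DelayFit:
    td: float
    td_net: float
    sscvr: float
    alpha: float
    baseline: float
    residuals: np.ndarray
    sse: float
    pearson_r: float


def _partial_r(sse: float, sse_null: float, slope: float) -> float:
    """Pearson correlation of the regressor with the series, drift partialled."""
    if sse_null <= 0:
        return np.nan
    r2 = max(0.0, (sse_null - sse) / sse_null)
    return float(np.sign(slope) * np.sqrt(min(1.0, r2)))


def fit_convolution(
    voxel_series: np.ndarray,
    petco2: StimulusTrace,
    tau_grid: np.ndarray = DEFAULT_TAU_GRID,
    fine_dt: float = DEFAULT_FINE_DT,
) -> ConvolutionFit:
    """Grid-search tau; ssCVR is the slope on the winning convolved regressor.

    The winner maximizes the Pearson correlation between the BOLD series
    and the convolved PETCO2 with the drift partialled out (equivalently,
    minimizes the regression SSE).  Exact ties go to the smallest tau.
    """
    y = np.asarray(voxel_series, dtype=float)
    bank = _RegressorBank(petco2, fine_dt)
    t = petco2.times
    ones = np.ones_like(y)
    _, _, sse_null = _ols(np.column_stack([t, ones]), y)
    best = None
    for tau in np.asarray(tau_grid, dtype=float):
        reg = bank.at_frames(tau, t)
        beta, resid, sse = _ols(np.column_stack([reg, t, ones]), y)
        if not np.isfinite(sse):
            continue
        if best is None or sse < best[0]:
            best = (float(sse), float(tau), beta, resid)
    if best is None:
        raise FitError("convolution fit failed at every tau candidate")
    sse, tau, beta, resid = best
    return ConvolutionFit(
        tau=tau, sscvr=float(beta[0]), alpha=float(beta[1]), baseline=float(beta[2]),
        residuals=resid, sse=sse, pearson_r=_partial_r(sse, float(sse_null), beta[0]),
        convolved_fine=bank.fine(tau),
    )


def fit_time_delay(
    voxel_series: np.ndarray,
    best_convolved: StimulusTrace,
    times: np.ndarray,
    td_grid: np.ndarray = DEFAULT_TD_GRID,
    pre_advance: float = DEFAULT_PRE_ADVANCE,
) -> DelayFit:
    """Grid-search the time delay of the winning convolved regressor.

    The regressor is first advanced ``pre_advance`` seconds so it precedes
    the BOLD signal everywhere, then delayed by each candidate TD; the TD
    maximizing the drift-partialled Pearson correlation wins (ties to the
    smallest TD) and ssCVR is re-estimated at the winning shift.  ``td_net
    = td - pre_advance`` is the net physiologic delay actually applied.
    """
    y = np.asarray(voxel_series, dtype=float)
    times = np.asarray(times, dtype=float)
    ones = np.ones_like(y)
    _, _, sse_null = _ols(np.column_stack([times, ones]), y)
    best = None
    for td in np.asarray(td_grid, dtype=float):
        reg = best_convolved.at(times - (td - pre_advance))
        beta, resid, sse = _ols(np.column_stack([reg, times, ones]), y)
        if not np.isfinite(sse):
            continue
        if best is None or sse < best[0]:
            best = (float(sse), float(td), beta, resid)
    if best is None:
        raise FitError("time-delay fit failed at every candidate")
    sse, td, beta, resid = best
    return DelayFit(
        td=td, td_net=td - pre_advance, sscvr=float(beta[0]), alpha=float(beta[1]),
        baseline=float(beta[2]), residuals=resid, sse=sse,
        pearson_r=_partial_r(sse, float(sse_null), beta[0]),
    )


def compute_bic(sse: float, n_frames: int, p: int) -> float:
    """BIC = n*ln(SSE/n) + (p+1)*ln(n); p counts the model parameters."""
    if n_frames <= 1:
        raise FitError("BIC needs more than one frame")
    if sse < 0:
        raise FitError("SSE must be non-negative")
    if sse == 0:
        warnings.warn("SSE is exactly zero (perfect fit); BIC is -inf", RuntimeWarning)
        return -np.inf
    n = float(n_frames)
    return float(n * np.log(sse / n) + (p + 1) * np.log(n))


@dataclass(frozen=True)
class FitConfig:
    """Grids and conventions of the voxel-wise fitting procedure."""

    tau_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TAU_GRID.copy())
    td_grid: np.ndarray = field(default_factory=lambda: DEFAULT_TD_GRID.copy())
    pre_advance: float = DEFAULT_PRE_ADVANCE
    fine_dt: float = DEFAULT_FINE_DT


@dataclass
class VolumeFit:
    """Per-voxel metric maps from :func:`fit_volume` (NaN outside the mask)."""

    maps: dict[str, np.ndarray]
    valid: np.ndarray
    grid: Grid
    config: FitConfig
    n_frames: int

    def __getitem__(self, key: str) -> np.ndarray:
        return self.maps[key]

    MAP_NAMES = ("mcvr", "sscvr", "tau", "td", "td_net", "alpha", "baseline",
                 "sse_standard", "sse_convolution", "bic_standard",
                 "bic_convolution", "pearson_r")


def _bic_array(sse: np.ndarray, n: int, p: int) -> np.ndarray:
    out = np.full(sse.shape, -np.inf)
    pos = sse > 0
    out[pos] = n * np.log(sse[pos] / n) + (p + 1) * np.log(n)
    if np.any(~pos):
        warnings.warn(
            f"{int(np.sum(~pos))} voxel(s) with SSE exactly zero; BIC set to -inf",
            RuntimeWarning,
        )
    return out


def fit_volume(
    series: BoldSeries, petco2: StimulusTrace, config: FitConfig | None = None
) -> VolumeFit:
    """Run the full per-voxel fitting cascade over a masked 4-D volume.

    Percent-normalizes the data, fits the standard and convolution models,
    searches the time delay, and computes both BICs.  Voxels outside the
    mask (or with degenerate data) carry NaN; per-voxel failures never
    abort the volume.  ``petco2`` must already be aligned and resampled to
    the frame grid.
    """
    config = config or FitConfig()
    if len(petco2) != series.n_frames:
        raise ProtocolError("stimulus must be resampled to the BOLD frame grid")
    if np.ptp(petco2.values) == 0:
        raise FitError("constant PETCO2 regressor: volume fit degenerate")

    normalized, valid = percent_normalize(series)
    maps = {name: np.full(series.data.shape[:3], np.nan)
            for name in VolumeFit.MAP_NAMES}
    n_vox = int(valid.sum())
    n = series.n_frames
    if n_vox == 0:
        return VolumeFit(maps, valid, series.grid, config, n)

    Y = normalized.data[valid].T                      # (T, V)
    t = petco2.times
    ones = np.ones(n)

    # Standard model.
    _, _, sse_null = _ols(np.column_stack([t, ones]), Y)
    beta_std, _, sse_std = _ols(np.column_stack([petco2.values, t, ones]), Y)

    # Convolution model: tau grid search (argmin SSE == argmax partial r).
    bank = _RegressorBank(petco2, config.fine_dt)
    tau_grid = np.asarray(config.tau_grid, dtype=float)
    slopes = np.empty((tau_grid.size, n_vox))
    sses = np.empty((tau_grid.size, n_vox))
    for i, tau in enumerate(tau_grid):
        beta, _, sse = _ols(np.column_stack([bank.at_frames(tau, t), t, ones]), Y)
        slopes[i], sses[i] = beta[0], sse
    k_tau = np.argmin(sses, axis=0)                   # first min -> smallest tau
    tau_win = tau_grid[k_tau]
    sse_conv = sses[k_tau, np.arange(n_vox)]

    # Time-delay search, grouped by winning tau so each regressor is built once.
    td_grid = np.asarray(config.td_grid, dtype=float)
    td_win = np.empty(n_vox)
    sscvr = np.empty(n_vox)
    alpha = np.empty(n_vox)
    baseline = np.empty(n_vox)
    sse_td = np.empty(n_vox)
    for tau in np.unique(tau_win):
        sel = np.flatnonzero(tau_win == tau)
        Yg = Y[:, sel]
        g_sse = np.empty((td_grid.size, sel.size))
        g_beta = np.empty((td_grid.size, 3, sel.size))
        for j, td in enumerate(td_grid):
            reg = bank.at_frames(tau, t, net_shift=td - config.pre_advance)
            beta, _, sse = _ols(np.column_stack([reg, t, ones]), Yg)
            g_beta[j], g_sse[j] = beta, sse
        k_td = np.argmin(g_sse, axis=0)               # first min -> smallest td
        cols = np.arange(sel.size)
        td_win[sel] = td_grid[k_td]
        sscvr[sel] = g_beta[k_td, 0, cols]
        alpha[sel] = g_beta[k_td, 1, cols]
        baseline[sel] = g_beta[k_td, 2, cols]
        sse_td[sel] = g_sse[k_td, cols]

    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.clip((sse_null - sse_td) / np.where(sse_null > 0, sse_null, np.nan), 0, 1)
    pearson = np.sign(sscvr) * np.sqrt(r2)

    values = {
        "mcvr": beta_std[0], "sscvr": sscvr, "tau": tau_win, "td": td_win,
        "td_net": td_win - config.pre_advance, "alpha": alpha, "baseline": baseline,
        "sse_standard": sse_std, "sse_convolution": sse_conv,
        "bic_standard": _bic_array(sse_std, n, p=2),
        "bic_convolution": _bic_array(sse_conv, n, p=3),
        "pearson_r": pearson,
    }
    for name, vec in values.items():
        maps[name][valid] = vec
    return VolumeFit(maps, valid, series.grid, config, n)
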