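"""End-tidal CO2 stimulus traces: protocol construction, resampling, alignment.

The vasodilatory stimulus is a targeted step change in the end-tidal
partial pressure of CO2 (PETCO2, mmHg).  The canonical protocol holds the
resting level, steps up by a fixed increment (typically +10 mmHg for
2 min), and returns to rest.  Before voxel-wise model fitting the measured
PETCO2 waveform is resampled onto the BOLD frame grid and time-shifted so
that its rapid transitions coincide with those of the brain-average BOLD
signal ("point of coincidence"), compensating for the lung-to-brain
transit and sampling-line delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, CoverageError, ProtocolError

__all__ = [
    "StimulusTrace",
    "ProtocolSpec",
    "build_step_protocol",
    "resample_to_frames",
    "align_to_bold",
    "read_petco2_tsv",
    "write_petco2_tsv",
]


@dataclass
class StimulusTrace:
    """A sampled PETCO2 waveform.

    Parameters
    ----------
    times:
        Sample times in seconds, strictly increasing.
    values:
        PETCO2 in mmHg, finite and positive.
    sampling_interval:
        Sampling interval in seconds when the grid is uniform, else None.
    """

    times: np.ndarray
    values: np.ndarray
    sampling_interval: float | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ProtocolError("times and values must be 1-D arrays of equal length")
        if self.times.size < 2:
            raise ProtocolError("a stimulus trace needs at least two samples")
        if not np.all(np.diff(self.times) > 0):
            raise ProtocolError("times must be strictly increasing")
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ProtocolError("PETCO2 values must be finite and positive")

    def __len__(self) -> int:
        return self.times.size

    @property
    def duration(self) -> float:
        """Covered duration in seconds, counting each sample's interval."""
        dt = self.sampling_interval
        if dt is None:
            dt = float(np.median(np.diff(self.times)))
        return float(self.times[-1] - self.times[0]) + dt

    def at(self, t: np.ndarray | float) -> np.ndarray:
        """Linear interpolation with edge-value extension."""
        return np.interp(t, self.times, self.values)


@dataclass(frozen=True)
class ProtocolSpec:
    """Step hypercapnia protocol: rest, step, return to rest.

    ``step_mmHg`` may be negative (hypocapnic step) in synthetic use.
    """

    baseline_mmHg: float = 40.0
    step_mmHg: float = 10.0
    baseline_duration: float = 120.0
    step_duration: float = 120.0
    recovery_duration: float = 120.0

    def __post_init__(self) -> None:
        for name in ("baseline_duration", "step_duration", "recovery_duration"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be positive")
        if self.baseline_mmHg <= 0 or not np.isfinite(self.step_mmHg):
            raise ProtocolError("baseline must be positive and step finite")

    @property
    def total_duration(self) -> float:
        return self.baseline_duration + self.step_duration + self.recovery_duration


def build_step_protocol(spec: ProtocolSpec, sampling_interval: float) -> StimulusTrace:
    """Sample the piecewise-constant step protocol on a uniform grid.

    Samples lie at ``k * sampling_interval`` for ``k = 0 .. n-1`` with
    ``n = round(total_duration / sampling_interval)``.  A sample takes the
    stepped value from the first sample at or after each boundary.
    """
    if sampling_interval <= 0:
        raise ProtocolError("sampling_interval must be positive")
    n = int(round(spec.total_duration / sampling_interval))
    if n < 2:
        raise ProtocolError("protocol too short for this sampling interval")
    times = np.arange(n) * sampling_interval
    t_up = spec.baseline_duration
    t_down = spec.baseline_duration + spec.step_duration
    # Guard against float grid jitter at the boundaries (e.g. 50*2.4).
    eps = 1e-9 * max(1.0, spec.total_duration)
    on = (times >= t_up - eps) & (times < t_down - eps)
    values = np.where(on, spec.baseline_mmHg + spec.step_mmHg, spec.baseline_mmHg)
    return StimulusTrace(times, values, sampling_interval)


def frame_times(n_frames: int, repetition_interval: float) -> np.ndarray:
    """Frame-center acquisition times ``(k + 1/2) * TR``, sharing the
    stimulus clock's origin."""
    return (np.arange(n_frames) + 0.5) * repetition_interval


def resample_to_frames(
    trace: StimulusTrace, repetition_interval: float, n_frames: int
) -> StimulusTrace:
    """Resample a trace onto BOLD frame-center times by linear interpolation.

    Every frame center must fall inside the sampled span (each sample is
    taken to cover one sampling interval), else :class:`CoverageError`.
    """
    if repetition_interval <= 0 or n_frames < 2:
        raise ProtocolError("need a positive repetition interval and >= 2 frames")
    t = frame_times(n_frames, repetition_interval)
    dt = trace.sampling_interval
    if dt is None:
        dt = float(np.median(np.diff(trace.times)))
    if t[0] < trace.times[0] - dt or t[-1] > trace.times[-1] + dt:
        raise CoverageError(
            f"trace spans [{trace.times[0]:.1f}, {trace.times[-1] + dt:.1f}] s "
            f"but acquisition frame centers span [{t[0]:.1f}, {t[-1]:.1f}] s"
        )
    return StimulusTrace(t, trace.at(t), repetition_interval)


def align_to_bold(
    trace: StimulusTrace,
    global_bold: np.ndarray,
    max_shift: float = 20.0,
    shift_step: float = 0.1,
) -> tuple[StimulusTrace, float]:
    """Shift the stimulus to the point of coincidence with the BOLD signal.

    Searches delays in ``[-max_shift, +max_shift]`` on a ``shift_step`` grid
    and returns the shifted trace maximizing the Pearson correlation with
    the brain-average BOLD series (sampled on the same frame grid).  A
    positive shift delays the stimulus.  Exact ties are broken toward the
    smallest absolute shift; shifted-out samples are filled by edge-value
    extension.

    Returns
    -------
    (aligned, shift):
        The shifted trace on the original frame grid and the applied shift
        in seconds.
    """
    global_bold = np.asarray(global_bold, dtype=float)
    if global_bold.shape != trace.values.shape:
        raise AlignmentError("global BOLD series must match the trace's frame grid")
    if max_shift <= 0 or shift_step <= 0:
        raise AlignmentError("max_shift and shift_step must be positive")
    if np.ptp(global_bold) == 0 or np.ptp(trace.values) == 0:
        raise AlignmentError("alignment undefined for zero-variance input")

    n_steps = int(np.floor(max_shift / shift_step + 1e-9))
    shifts = shift_step * np.arange(-n_steps, n_steps + 1)
    # Visit candidates in order of |shift| so the first strict maximum
    # realizes the smallest-|shift| tie-break.
    order = np.lexsort((shifts, np.abs(shifts)))

    y = global_bold - global_bold.mean()
    ynorm = np.linalg.norm(y)
    best_r, best_shift, best_vals = -np.inf, 0.0, trace.values
    for s in shifts[order]:
        shifted = trace.at(trace.times - s)
        x = shifted - shifted.mean()
        xnorm = np.linalg.norm(x)
        if xnorm == 0:
            continue
        r = float(x @ y) / (xnorm * ynorm)
        if r > best_r:
            best_r, best_shift, best_vals = r, float(s), shifted
    if not np.isfinite(best_r):
        raise AlignmentError("no valid shift candidate (shifted trace constant)")
    aligned = StimulusTrace(trace.times.copy(), best_vals, trace.sampling_interval)
    return aligned, best_shift


def read_petco2_tsv(path) -> StimulusTrace:
    """Read a two-column PETCO2 trace (``time_s``, ``petco2_mmHg``)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"time_s", "petco2_mmHg"} - set(df.columns)
    if missing:
        raise ProtocolError(f"PETCO2 TSV missing columns: {sorted(missing)}")
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    uniform = dt.size > 0 and np.allclose(dt, dt[0], rtol=0, atol=1e-6)
    return StimulusTrace(t, df["petco2_mmHg"].to_numpy(dtype=float),
                         float(dt[0]) if uniform else None)


def write_petco2_tsv(trace: StimulusTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "petco2_mmHg": trace.values}).to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )
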