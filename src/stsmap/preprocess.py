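"""EMG envelope extraction, sit-to-stand cycle segmentation and time normalization.

The analysis pipeline only considers the *upward* (sit-to-stand) phase of each
sit-stand-sit cycle: the return phase is largely gravity-driven and is
discarded.  Segmentation therefore works on the vertical center-of-mass
position and delimits, for every cycle, the band between 10% and 90% of the
subject's vertical excursion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sig


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class EnvelopeMatrix:
    """Nonnegative muscles x samples EMG envelope.

    Parameters
    ----------
    values : ndarray, shape (n_muscles, n_samples)
        Envelope amplitudes, elementwise >= 0.
    muscle_names : list of str
        One name per row.
    fs : float
        Sampling rate in Hz.
    """

    values: np.ndarray
    muscle_names: list[str]
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("envelope values must be a 2-D muscles x samples array")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be elementwise nonnegative")
        if len(self.muscle_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.muscle_names)} muscle names for "
                f"{self.values.shape[0]} envelope rows"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")

    @property
    def n_muscles(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class CycleSet:
    """Half-open sample intervals delimiting the upward phase of each cycle."""

    intervals: list[tuple[int, int]]
    source_fs: float
    phase: str = "upward"

    def __post_init__(self) -> None:
        self.intervals = [(int(a), int(b)) for a, b in self.intervals]
        prev_end = -1
        for a, b in self.intervals:
            if b <= a:
                raise ValueError(f"empty or inverted interval ({a}, {b})")
            if a < prev_end:
                raise ValueError("intervals must be sorted and non-overlapping")
            prev_end = b

    def __len__(self) -> int:
        return len(self.intervals)

    def durations(self) -> np.ndarray:
        """Interval durations in seconds."""
        return np.array([(b - a) / self.source_fs for a, b in self.intervals])


# --------------------------------------------------------------------------
# envelope
# --------------------------------------------------------------------------

def compute_envelope(
    raw: np.ndarray,
    fs: float,
    band: tuple[float, float] = (20.0, 450.0),
    lowpass: float = 5.0,
    order: int = 4,
    muscle_names: list[str] | None = None,
) -> EnvelopeMatrix:
    """Band-pass, full-wave rectify and low-pass raw EMG into an envelope.

    The recipe is zero-phase throughout (forward-backward filtering): an
    ``order``-th order Butterworth band-pass (default 20-450 Hz) removes DC
    and motion artifact, full-wave rectification follows, and an ``order``-th
    order Butterworth low-pass (default 5 Hz) yields the amplitude envelope.
    Zero-phase low-passing can undershoot below zero near sharp transients;
    the output is clipped at zero, which keeps the operator positively
    homogeneous.
    """
    raw = np.atleast_2d(np.asarray(raw, dtype=float))
    if not np.all(np.isfinite(raw)):
        raise ValueError("raw EMG contains non-finite samples")
    if band[1] >= fs / 2:
        raise ValueError(
            f"band-pass upper corner {band[1]} Hz requires fs > {2 * band[1]} Hz, got {fs}"
        )
    if fs <= 2 * band[0]:
        raise ValueError(f"fs={fs} too low for high-pass corner {band[0]} Hz")
    if raw.shape[1] < fs:
        raise ValueError("need at least 1 s of data to compute an envelope")

    sos_bp = sig.butter(order, band, btype="bandpass", fs=fs, output="sos")
    sos_lp = sig.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    bandpassed = sig.sosfiltfilt(sos_bp, raw, axis=1)
    env = sig.sosfiltfilt(sos_lp, np.abs(bandpassed), axis=1)
    env = np.maximum(env, 0.0)
    if muscle_names is None:
        muscle_names = [f"ch{i}" for i in range(raw.shape[0])]
    return EnvelopeMatrix(values=env, muscle_names=list(muscle_names), fs=fs)


# --------------------------------------------------------------------------
# cycle segmentation
# --------------------------------------------------------------------------

def segment_upward_cycles(
    vt_position: np.ndarray,
    fs: float,
    low_frac: float = 0.10,
    high_frac: float = 0.90,
    min_excursion: float = 1e-6,
) -> CycleSet:
    """Delimit the upward phase of every sit-to-stand cycle.

    Thresholds are placed at ``low_frac`` and ``high_frac`` of the vertical
    excursion above the seated (minimum) level.  Each interval starts at the
    last sample still at or below the seated threshold before the rise and
    ends at the first sample at or above the standing threshold, i.e. it
    covers the 10-90% band of the transition.

    Returns an empty :class:`CycleSet` (with a warning) when no excursion or
    no complete transition is found.
    """
    vt = np.asarray(vt_position, dtype=float)
    if vt.ndim != 1:
        raise ValueError("vt_position must be 1-D")
    if not np.all(np.isfinite(vt)):
        raise ValueError("vt_position contains non-finite values")

    lo_v, hi_v = vt.min(), vt.max()
    excursion = hi_v - lo_v
    if excursion < min_excursion:
        warnings.warn("no vertical excursion: returning empty cycle set", stacklevel=2)
        return CycleSet(intervals=[], source_fs=fs)

    low = lo_v + low_frac * excursion
    high = lo_v + high_frac * excursion
    mid = lo_v + 0.5 * excursion

    above_mid = vt >= mid
    rising = np.flatnonzero(~above_mid[:-1] & above_mid[1:]) + 1

    intervals: list[tuple[int, int]] = []
    for idx in rising:
        below_low = np.flatnonzero(vt[:idx] <= low)
        if below_low.size == 0:
            continue
        start = int(below_low[-1])
        above_high = np.flatnonzero(vt[idx:] >= high)
        if above_high.size == 0:
            continue
        end = int(idx + above_high[0]) + 1  # half-open: include first standing sample
        if intervals and start < intervals[-1][1]:
            continue  # same rise seen through a noisy mid-crossing
        if end - start < 3:
            continue
        intervals.append((start, end))

    if not intervals:
        warnings.warn("no complete sit-to-stand transition found", stacklevel=2)
    return CycleSet(intervals=intervals, source_fs=fs)


def select_random_cycles(cycles: CycleSet, target_duration: float, seed: int) -> CycleSet:
    """Randomly retain cycles until their total duration would exceed the target.

    Cycles are visited in a seeded random order without replacement and kept
    greedily while the running total stays within ``target_duration``; any
    cycle that would overflow the budget is skipped, so the retained subset is
    maximal under the budget.  If the full set already fits, it is returned
    unchanged.
    """
    if target_duration <= 0:
        raise ValueError("target_duration must be positive")
    durations = cycles.durations()
    if durations.sum() <= target_duration:
        return cycles

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cycles.intervals))
    kept: list[int] = []
    total = 0.0
    for i in order:
        if total + durations[i] <= target_duration:
            kept.append(i)
            total += durations[i]
    kept.sort()
    return CycleSet(
        intervals=[cycles.intervals[i] for i in kept],
        source_fs=cycles.source_fs,
        phase=cycles.phase,
    )


# --------------------------------------------------------------------------
# time normalization
# --------------------------------------------------------------------------

def time_normalize(signal: np.ndarray, n_points: int = 100) -> np.ndarray:
    """Linearly resample a channels x samples signal onto ``n_points`` samples.

    Both endpoints are preserved exactly; interior points are linear
    interpolations on an evenly spaced grid. A 1-D input returns 1-D output.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    arr = np.asarray(signal, dtype=float)
    squeeze = arr.ndim == 1
    arr = np.atleast_2d(arr)
    n = arr.shape[1]
    if n < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    x_old = np.linspace(0.0, 1.0, n)
    x_new = np.linspace(0.0, 1.0, n_points)
    out = np.empty((arr.shape[0], n_points))
    for i in range(arr.shape[0]):
        out[i] = np.interp(x_new, x_old, arr[i])
    return out[0] if squeeze else out
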