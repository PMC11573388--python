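"""Segmental center-of-mass estimation and position-velocity phase spaces.

The body CoM is a mass-fraction-weighted sum of segment CoMs, each located a
fixed fraction of the way from the proximal to the distal marker of its
segment.  The CoM trajectory is projected onto the sagittal plane (AP = x,
VT = y) relative to the center of the base of support, defined as the
time-mean midpoint between the two malleolus markers (feet are assumed
stationary).  Two position-velocity phase spaces are built from that
projection: cartesian (x, y, vx, vy) and polar (magnitude, angle and their
derivatives), where the angle is measured from the vertical axis with
anterior lean positive, ang = arctan(x / y).

Velocities are always differentiated at the original sampling rate, *before*
the 100-sample time normalization: resampling first would distort velocity
magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import CycleSet, time_normalize

#: order of the 8 phase-space variables everywhere in the package
VARIABLE_NAMES: tuple[str, ...] = ("x", "y", "vx", "vy", "mag", "ang", "vmag", "vang")

#: world-frame axis convention for marker tables: columns <marker>_{x,y,z}
#: x = antero-posterior (anterior positive), y = vertical (up), z = medio-lateral
AP_AXIS, VT_AXIS, ML_AXIS = 0, 1, 2


# --------------------------------------------------------------------------
# anthropometry
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SegmentDef:
    """One segment of the anthropometric model."""

    name: str
    mass_fraction: float      # fraction of total body mass
    com_fraction: float       # CoM position, fraction from proximal to distal marker
    proximal_marker: str
    distal_marker: str


@dataclass(frozen=True)
class AnthropometricTable:
    segments: tuple[SegmentDef, ...]

    def __post_init__(self) -> None:
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"segment mass fractions sum to {total}, expected 1")


#: Winter-style 3-segment sagittal model (both shanks+feet lumped, both
#: thighs lumped, head+arms+trunk).  Values are configuration defaults for a
#: reduced sagittal linkage, not a claim about any specific reference table.
DEFAULT_ANTHRO = AnthropometricTable(
    segments=(
        SegmentDef("shank_feet", 0.122, 0.45, "knee", "ankle"),
        SegmentDef("thighs", 0.200, 0.433, "hip", "knee"),
        SegmentDef("hat", 0.678, 0.626, "hip", "shoulder"),
    )
)


def marker_xyz(markers: pd.DataFrame, name: str) -> np.ndarray:
    """Extract an (n_samples, 3) trajectory for one named marker."""
    cols = [f"{name}_{ax}" for ax in ("x", "y", "z")]
    missing = [c for c in cols if c not in markers.columns]
    if missing:
        raise ValueError(f"missing marker '{name}' (columns {missing})")
    return markers[cols].to_numpy(dtype=float)


def estimate_com(
    markers: pd.DataFrame,
    anthro: AnthropometricTable = DEFAULT_ANTHRO,
    body_mass: float | None = None,
) -> np.ndarray:
    """Segmental CoM: mass-weighted sum of per-segment CoMs, shape (n, 3).

    ``body_mass`` is accepted for interface symmetry; the CoM *position*
    depends only on the mass fractions.
    """
    com = None
    for seg in anthro.segments:
        prox = marker_xyz(markers, seg.proximal_marker)
        dist = marker_xyz(markers, seg.distal_marker)
        seg_com = prox + seg.com_fraction * (dist - prox)
        contrib = seg.mass_fraction * seg_com
        com = contrib if com is None else com + contrib
    return com


def to_sagittal_relative(
    com3d: np.ndarray,
    malleolus_left: np.ndarray,
    malleolus_right: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Project the CoM onto the sagittal plane relative to the base of support.

    The origin is the time-mean midpoint of the two malleolus markers; the
    out-of-plane (medio-lateral) component is dropped.  Returns (x, y) =
    (AP, VT) series in meters.
    """
    midpoint = 0.5 * (np.asarray(malleolus_left) + np.asarray(malleolus_right))
    origin = midpoint.mean(axis=0)
    rel = np.asarray(com3d) - origin
    return rel[:, AP_AXIS].copy(), rel[:, VT_AXIS].copy()


# --------------------------------------------------------------------------
# polar coordinates and differentiation
# --------------------------------------------------------------------------

def polar_transform(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(x, y) -> (magnitude, angle-from-vertical), quadrant-safe.

    mag = sqrt(x^2 + y^2); ang = arctan2(x, y), so a purely vertical vector
    has angle 0 and anterior lean is positive.  At the origin the magnitude
    is 0 and the angle is undefined: it is returned as NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mag = np.hypot(x, y)
    ang = np.arctan2(x, y)
    ang = np.where(mag == 0.0, np.nan, ang)
    return mag, ang


def polar_inverse(mag: np.ndarray, ang: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Inverse of :func:`polar_transform`: x = mag sin(ang), y = mag cos(ang)."""
    mag = np.asarray(mag, dtype=float)
    ang = np.asarray(ang, dtype=float)
    return mag * np.sin(ang), mag * np.cos(ang)


def differentiate(series: np.ndarray, fs: float) -> np.ndarray:
    """Finite-difference velocity: central interior, one-sided at the ends.

    Exact for linear series (a ramp of slope k returns constant k).
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    return np.gradient(series, 1.0 / fs, axis=-1, edge_order=1)


# --------------------------------------------------------------------------
# phase trajectories
# --------------------------------------------------------------------------

@dataclass
class PhaseTrajectory:
    """100-sample time-normalized series of the 8 phase-space variables for one cycle."""

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    mag: np.ndarray
    ang: np.ndarray
    vmag: np.ndarray
    vang: np.ndarray
    fs_original: float

    def as_matrix(self) -> np.ndarray:
        """Stack the 8 variables into an (8, n_points) matrix in canonical order."""
        return np.vstack([getattr(self, name) for name in VARIABLE_NAMES])


def phase_variables(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    interval: tuple[int, int] | None = None,
) -> dict[str, np.ndarray]:
    """The 8 phase-space variables at the original sampling rate.

    If ``interval`` is given, the series are first sliced to that half-open
    sample range; derivatives are then taken on the slice so every cycle is
    self-contained.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if interval is not None:
        a, b = interval
        if a < 0 or b > x.shape[-1]:
            raise ValueError(f"interval ({a}, {b}) outside signal bounds")
        x, y = x[a:b], y[a:b]
    if x.shape[-1] < 3:
        raise ValueError("cycle shorter than 3 samples")
    mag, ang = polar_transform(x, y)
    return {
        "x": x,
        "y": y,
        "vx": differentiate(x, fs),
        "vy": differentiate(y, fs),
        "mag": mag,
        "ang": ang,
        "vmag": differentiate(mag, fs),
        "vang": differentiate(ang, fs),
    }


def build_phase_trajectory(
    x: np.ndarray,
    y: np.ndarray,
    fs: float,
    cycles: CycleSet,
    n_points: int = 100,
) -> list[PhaseTrajectory]:
    """Per-cycle phase trajectories, time-normalized to ``n_points`` samples.

    Velocities are differentiated at the original rate and then resampled.
    Positions are resampled and the polar pair recomputed from the resampled
    (x, y), so mag^2 = x^2 + y^2 holds exactly on the normalized grid.
    """
    out: list[PhaseTrajectory] = []
    for interval in cycles.intervals:
        v = phase_variables(x, y, fs, interval)
        xn = time_normalize(v["x"], n_points)
        yn = time_normalize(v["y"], n_points)
        magn, angn = polar_transform(xn, yn)
        out.append(
            PhaseTrajectory(
                x=xn,
                y=yn,
                vx=time_normalize(v["vx"], n_points),
                vy=time_normalize(v["vy"], n_points),
                mag=magn,
                ang=angn,
                vmag=time_normalize(v["vmag"], n_points),
                vang=time_normalize(v["vang"], n_points),
                fs_original=fs,
            )
        )
    return out


# --------------------------------------------------------------------------
# summary parameters
# --------------------------------------------------------------------------

@dataclass
class PhaseSpaceParameters:
    """Per-cycle extrema and across-cycle summaries of the 8 variables.

    ``per_cycle`` has one row per cycle and a (variable, stat) column
    MultiIndex with stats max/min/range; ``summary`` has one row per variable
    with across-cycle mean and sd of each stat plus ``range_variability``,
    the sd of the cycle-specific range.
    """

    per_cycle: pd.DataFrame
    summary: pd.DataFrame


def _sd(values: np.ndarray) -> float:
    # sample sd; a single cycle, or identical cycles, have exactly zero spread
    if len(values) < 2 or np.ptp(values) == 0:
        return 0.0
    return float(np.std(values, ddof=1))


def phase_space_parameters(trajs: list[PhaseTrajectory]) -> PhaseSpaceParameters:
    """Extrema, ranges and across-cycle variability of the phase-space variables."""
    if not trajs:
        raise ValueError("need at least one cycle")
    records = {}
    for var in VARIABLE_NAMES:
        series = np.vstack([getattr(t, var) for t in trajs])
        vmax = series.max(axis=1)
        vmin = series.min(axis=1)
        records[(var, "max")] = vmax
        records[(var, "min")] = vmin
        records[(var, "range")] = vmax - vmin
    per_cycle = pd.DataFrame(records)
    per_cycle.columns = pd.MultiIndex.from_tuples(per_cycle.columns, names=["variable", "stat"])

    rows = {}
    for var in VARIABLE_NAMES:
        rng = per_cycle[(var, "range")].to_numpy()
        rows[var] = {
            "max_mean": per_cycle[(var, "max")].mean(),
            "max_sd": _sd(per_cycle[(var, "max")].to_numpy()),
            "min_mean": per_cycle[(var, "min")].mean(),
            "min_sd": _sd(per_cycle[(var, "min")].to_numpy()),
            "range_mean": rng.mean(),
            "range_sd": _sd(rng),
            "range_variability": _sd(rng),
        }
    summary = pd.DataFrame.from_dict(rows, orient="index")
    return PhaseSpaceParameters(per_cycle=per_cycle, summary=summary)
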