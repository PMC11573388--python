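"""Synthetic sit-to-stand cohorts with known synergy structure.

The study data this pipeline targets (multi-channel surface EMG plus marker
kinematics from repeated sit-to-stand cycles) is not publicly deposited, so
every stage of the analysis is validated against cohorts generated here with
fully known ground truth:

* each subject has a true synergy count (3 or 4), true weight vectors W
  (unit-norm, well-separated columns) and true activation waveforms H
  (Gaussian bumps staggered across the upward phase);
* observed EMG envelopes are W.H plus rectified additive Gaussian noise;
* marker trajectories come from a sagittal 3-segment linkage (shank, thigh,
  head-arms-trunk) anchored at the ankles, whose rise speed is calibrated so
  the vertical CoM velocity peak matches a per-subject target — subjects with
  4 synergies draw their targets from a faster distribution, emulating the
  group-level kinematic effect the analysis is meant to detect;
* four-synergy subjects are built by splitting the middle activation bump
  into an earlier, narrower "extension" bump and a later, prolonged
  "flexion" bump, so the extra module lives in the central part of the cycle.

Everything is deterministic under a single cohort master seed; per-subject
seeds are derived by a fixed affine rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import com as com_mod
from .preprocess import EnvelopeMatrix

#: the 8 recorded muscles of the dominant leg, in channel order
MUSCLES: tuple[str, ...] = (
    "soleus",
    "gastrocnemius_medialis",
    "peroneus_longus",
    "tibialis_anterior",
    "vastus_lateralis",
    "rectus_femoris",
    "biceps_femoris",
    "gluteus_medius",
)

_MAX_W_ATTEMPTS = 500


# --------------------------------------------------------------------------
# containers / configuration
# --------------------------------------------------------------------------

@dataclass
class GroundTruthSubject:
    subject_id: str
    true_n_syn: int
    true_W: np.ndarray          # muscles x n_syn, unit-norm columns
    true_H: np.ndarray          # n_syn x samples_per_cycle (upward phase)
    n_cycles: int
    vt_velocity_peak: float     # m/s, target standing-phase vertical CoM velocity peak
    body_mass: float            # kg
    body_height: float          # m
    seed: int


@dataclass
class CohortConfig:
    """Generation parameters; defaults define the standard study conditions."""

    n3: int = 7                       # subjects with 3 synergies
    n4: int = 5                       # subjects with 4 synergies
    n_muscles: int = 8
    n_cycles: int = 5                 # sit-stand-sit repetitions per trial
    samples_per_cycle: int = 100      # ground-truth H grid over the upward phase
    emg_fs: float = 1000.0            # Hz
    marker_fs: float = 100.0          # Hz
    noise_sd: float = 0.05            # envelope noise sd, fraction of signal peak
    snr_db: float | None = None       # if set, overrides noise_sd to hit this SNR
    marker_noise_sd: float = 0.0      # m, white noise on marker coordinates
    vt_peak_mean_n3: float = 0.5      # m/s
    vt_peak_mean_n4: float = 0.7      # m/s
    vt_peak_sd: float = 0.05          # m/s, between-subject spread
    body_mass_mean: float = 79.0      # kg
    body_mass_sd: float = 11.0
    body_height_mean: float = 1.77    # m
    body_height_sd: float = 0.06
    baseline_level: float = 0.10      # tonic activation floor (fraction of bump peak)
    descent_gain: float = 0.6         # eccentric reactivation during the return phase
    w_jitter_sd: float = 0.05         # per-subject weight deviation from the group template

    def __post_init__(self) -> None:
        if self.n3 < 0 or self.n4 < 0 or self.n3 + self.n4 < 1:
            raise ValueError("cohort must contain at least one subject")
        if self.noise_sd < 0 or self.marker_noise_sd < 0:
            raise ValueError("noise levels must be nonnegative")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")
        if self.n_muscles < 4:
            raise ValueError("need at least 4 muscles to host 4 synergies")


@dataclass
class SyntheticCohort:
    subjects: list[GroundTruthSubject]
    observed_emg: dict[str, EnvelopeMatrix]
    marker_trials: dict[str, pd.DataFrame]
    config_echo: CohortConfig
    #: per subject: cycle/rise timing in seconds and samples (generator truth)
    trial_truth: dict[str, dict] = field(default_factory=dict)


def subject_seed(master_seed: int, index: int) -> int:
    """Fixed affine derivation of per-subject seeds from the cohort master seed."""
    return (master_seed * 100003 + 7919 * index) % (2**31)


# --------------------------------------------------------------------------
# ground-truth synergies
# --------------------------------------------------------------------------

def _bump_params(n_syn: int, split_second: bool) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian bump centers and widths (fractions of the upward phase)."""
    if split_second and n_syn == 4:
        # split of the middle module of the 3-synergy solution: an earlier,
        # narrower extension burst plus a later, prolonged flexion burst
        centers = np.array([0.15, 0.40, 0.62, 0.85])
        widths = np.array([0.15, 0.08, 0.18, 0.15])
    elif n_syn == 1:
        centers = np.array([0.5])
        widths = np.array([0.15])
    else:
        centers = np.linspace(0.15, 0.85, n_syn)
        widths = np.full(n_syn, 0.15)
    return centers, widths


def _pairwise_max_cosine(W: np.ndarray) -> float:
    Wn = W / np.linalg.norm(W, axis=0)
    G = Wn.T @ Wn
    n = G.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    return float(G[iu].max())


def make_ground_truth_synergies(
    n_syn: int,
    n_muscles: int,
    n_samples: int,
    seed: int,
    split_second: bool = False,
    max_cosine: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth weights and activations for one subject.

    Weights are sparse-ish nonnegative columns (gamma-distributed entries),
    normalized to unit Euclidean norm and resampled until every column pair
    has cosine similarity below ``max_cosine``.  Activations are Gaussian
    bumps with staggered centers spanning the cycle (width 15% of the cycle
    by default); ``split_second`` selects the 4-synergy split-bump layout.
    """
    if n_syn < 1:
        raise ValueError("n_syn must be >= 1")
    if n_muscles < n_syn:
        raise ValueError("need n_muscles >= n_syn")
    if n_samples < 10:
        raise ValueError("need n_samples >= 10")

    rng = np.random.default_rng(seed)
    W = rng.gamma(shape=0.8, scale=1.0, size=(n_muscles, n_syn)) + 1e-6
    for _ in range(_MAX_W_ATTEMPTS):
        Wn = W / np.linalg.norm(W, axis=0)
        if n_syn == 1 or _pairwise_max_cosine(Wn) < max_cosine:
            W = Wn
            break
        G = Wn.T @ Wn
        np.fill_diagonal(G, -np.inf)
        worst = int(np.argmax(G.max(axis=1)))
        W[:, worst] = rng.gamma(shape=0.8, scale=1.0, size=n_muscles) + 1e-6
    else:
        raise RuntimeError(
            f"could not draw {n_syn} weight columns with pairwise cosine "
            f"< {max_cosine} in {_MAX_W_ATTEMPTS} attempts"
        )

    centers, widths = _bump_params(n_syn, split_second)
    t = np.linspace(0.0, 1.0, n_samples)
    H = np.exp(-0.5 * ((t[None, :] - centers[:, None]) / widths[:, None]) ** 2)
    return W, H


def synthesize_envelopes(
    weights: np.ndarray,
    activations: np.ndarray,
    noise_sd: float,
    seed: int,
    fs: float = 1000.0,
    muscle_names: list[str] | None = None,
) -> EnvelopeMatrix:
    """Observed envelope = max(0, W.H + Gaussian noise).

    ``noise_sd`` is expressed as a fraction of each channel's clean peak
    value (envelope noise scales with a muscle's signal level; a silent
    channel records no noise either), so every muscle sees a comparable
    signal-to-noise ratio.  Rectification preserves nonnegativity.
    """
    W = np.asarray(weights, dtype=float)
    H = np.asarray(activations, dtype=float)
    if W.ndim != 2 or H.ndim != 2 or W.shape[1] != H.shape[0]:
        raise ValueError(f"non-conformable shapes {W.shape} and {H.shape}")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    clean = W @ H
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        row_peaks = clean.max(axis=1, keepdims=True)
        noise = rng.normal(0.0, 1.0, size=clean.shape) * (noise_sd * row_peaks)
        observed = np.maximum(clean + noise, 0.0)
    else:
        observed = clean
    if muscle_names is None:
        muscle_names = [f"m{i}" for i in range(W.shape[0])]
    return EnvelopeMatrix(values=observed, muscle_names=list(muscle_names), fs=fs)


def noise_sd_for_snr(weights: np.ndarray, activations: np.ndarray, snr_db: float) -> float:
    """Fraction-of-channel-peak noise sd giving the requested global envelope SNR.

    With per-channel noise sd = f * peak_m, the global noise power is
    f^2 * mean_m(peak_m^2); solving SNR = rms(signal)^2 / noise power for f.
    """
    clean = np.asarray(weights) @ np.asarray(activations)
    rms = float(np.sqrt(np.mean(clean**2)))
    peak_rms = float(np.sqrt(np.mean(clean.max(axis=1) ** 2)))
    return rms / peak_rms * 10 ** (-snr_db / 20.0)


# --------------------------------------------------------------------------
# sit-to-stand kinematics
# --------------------------------------------------------------------------

# cycle phase fractions: seated dwell, rise (upward phase), standing dwell, descent
_PHASE_FRACS = (0.15, 0.35, 0.20, 0.30)

# joint angles from the vertical (rad), sitting -> standing
_SHANK_SIT, _SHANK_STAND = 0.30, 0.03
_THIGH_SIT, _THIGH_STAND = -1.50, -0.03
_TRUNK_SIT, _TRUNK_STAND = 0.15, 0.00
_TRUNK_LEAN_AMP = 0.50  # forward-lean excursion during the transition (rad)

# segment lengths and ankle height as fractions of body height
_L_SHANK, _L_THIGH, _L_HAT, _ANKLE_H = 0.246, 0.245, 0.288, 0.040
_MALLEOLUS_HALF_WIDTH = 0.06  # m, lateral offset of each malleolus


def _smoothstep(u: np.ndarray) -> np.ndarray:
    return u * u * (3.0 - 2.0 * u)


def _cycle_phase(t_in_cycle: np.ndarray, cycle_T: float) -> tuple[np.ndarray, np.ndarray]:
    """Rise progression p(t) in [0, 1] and rise-phase coordinate u (NaN off-rise)."""
    f_sit, f_rise, f_stand, _ = _PHASE_FRACS
    tau = t_in_cycle / cycle_T
    p = np.zeros_like(tau)
    u = np.full_like(tau, np.nan)

    rising = (tau >= f_sit) & (tau < f_sit + f_rise)
    ur = (tau[rising] - f_sit) / f_rise
    p[rising] = _smoothstep(ur)
    u[rising] = ur

    standing = (tau >= f_sit + f_rise) & (tau < f_sit + f_rise + f_stand)
    p[standing] = 1.0

    desc = tau >= f_sit + f_rise + f_stand
    ud = (tau[desc] - (f_sit + f_rise + f_stand)) / _PHASE_FRACS[3]
    p[desc] = 1.0 - _smoothstep(ud)
    return p, u


def _linkage_markers(p: np.ndarray, height: float, motion_amplitude: float = 1.0) -> dict[str, np.ndarray]:
    """Sagittal marker positions (n, 3) for a rise progression series p."""
    a = motion_amplitude
    th1 = _SHANK_STAND + a * (_SHANK_SIT - _SHANK_STAND) * (1.0 - p)
    th2 = _THIGH_STAND + a * (_THIGH_SIT - _THIGH_STAND) * (1.0 - p)
    th3 = (
        _TRUNK_STAND
        + a * (_TRUNK_SIT - _TRUNK_STAND) * (1.0 - p)
        + a * _TRUNK_LEAN_AMP * np.sin(np.pi * p)
    )
    l1, l2, l3 = _L_SHANK * height, _L_THIGH * height, _L_HAT * height
    ankle_y = _ANKLE_H * height

    n = p.shape[0]
    zeros = np.zeros(n)
    ankle = np.column_stack([zeros, np.full(n, ankle_y), zeros])
    knee = ankle + np.column_stack([l1 * np.sin(th1), l1 * np.cos(th1), zeros])
    hip = knee + np.column_stack([l2 * np.sin(th2), l2 * np.cos(th2), zeros])
    shoulder = hip + np.column_stack([l3 * np.sin(th3), l3 * np.cos(th3), zeros])
    mall_l = ankle + np.array([0.0, 0.0, -_MALLEOLUS_HALF_WIDTH])
    mall_r = ankle + np.array([0.0, 0.0, _MALLEOLUS_HALF_WIDTH])
    return {
        "ankle": ankle,
        "knee": knee,
        "hip": hip,
        "shoulder": shoulder,
        "malleolus_left": mall_l,
        "malleolus_right": mall_r,
    }


def _calibrate_cycle_duration(
    subject_height: float,
    target_peak: float,
    anthro: com_mod.AnthropometricTable,
    motion_amplitude: float = 1.0,
) -> float:
    """Cycle duration (s) whose rise yields the target vertical CoM velocity peak.

    Time-scaling a fixed spatial path scales velocities inversely, so one
    finely sampled probe cycle at a nominal duration pins the scale factor.
    """
    T0 = 3.0
    fs_probe = 500.0
    t = np.arange(0.0, T0, 1.0 / fs_probe)
    p, _ = _cycle_phase(t, T0)
    frames = _linkage_markers(p, subject_height, motion_amplitude)
    markers = _markers_to_frame(frames)
    com3d = com_mod.estimate_com(markers, anthro)
    vy = np.gradient(com3d[:, com_mod.VT_AXIS], 1.0 / fs_probe)
    peak0 = float(vy.max())
    if target_peak <= 0:
        raise ValueError("vt_velocity_peak must be positive")
    return T0 * peak0 / target_peak


def _markers_to_frame(frames: dict[str, np.ndarray]) -> pd.DataFrame:
    data = {}
    for name, arr in frames.items():
        for k, ax in enumerate(("x", "y", "z")):
            data[f"{name}_{ax}"] = arr[:, k]
    return pd.DataFrame(data)


def generate_marker_trial(
    subject: GroundTruthSubject,
    n_cycles: int,
    fs: float = 100.0,
    seed: int = 0,
    marker_noise_sd: float = 0.0,
    anthro: com_mod.AnthropometricTable = com_mod.DEFAULT_ANTHRO,
    motion_amplitude: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Marker trajectories for ``n_cycles`` sit-stand-sit repetitions.

    Returns the marker table (columns ``<marker>_{x,y,z}`` in meters) and a
    timing dict with the calibrated cycle duration and per-cycle rise windows
    in seconds.  The malleoli stay at fixed ground positions; lateral
    coordinates are constant; the standing-phase vertical CoM velocity peak
    matches ``subject.vt_velocity_peak`` (exact up to time discretization).
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")

    if motion_amplitude == 0.0:
        cycle_T = 3.0  # degenerate static posture: nothing to calibrate
    else:
        cycle_T = _calibrate_cycle_duration(
            subject.body_height, subject.vt_velocity_peak, anthro, motion_amplitude
        )
    n = int(round(n_cycles * cycle_T * fs))
    t = np.arange(n) / fs
    p, _ = _cycle_phase(t % cycle_T, cycle_T)
    frames = _linkage_markers(p, subject.body_height, motion_amplitude)
    markers = _markers_to_frame(frames)

    if marker_noise_sd > 0:
        rng = np.random.default_rng(seed)
        markers = markers + rng.normal(0.0, marker_noise_sd, size=markers.shape)

    f_sit, f_rise = _PHASE_FRACS[0], _PHASE_FRACS[1]
    rises = [
        (c * cycle_T + f_sit * cycle_T, c * cycle_T + (f_sit + f_rise) * cycle_T)
        for c in range(n_cycles)
    ]
    timing = {"cycle_duration": cycle_T, "rise_windows_s": rises, "fs": fs}
    return markers, timing


# --------------------------------------------------------------------------
# cohort assembly
# --------------------------------------------------------------------------

def _activation_timecourse(
    true_H: np.ndarray,
    n_cycles: int,
    cycle_T: float,
    fs: float,
    baseline: float,
    descent_gain: float,
) -> np.ndarray:
    """Tile the upward-phase activations over a full multi-cycle trial."""
    n = int(round(n_cycles * cycle_T * fs))
    t = np.arange(n) / fs
    _, u = _cycle_phase(t % cycle_T, cycle_T)

    f_sit, f_rise, f_stand, f_desc = _PHASE_FRACS
    tau = (t % cycle_T) / cycle_T
    desc = tau >= (f_sit + f_rise + f_stand)
    ud = np.zeros_like(tau)
    ud[desc] = (tau[desc] - (f_sit + f_rise + f_stand)) / f_desc

    grid = np.linspace(0.0, 1.0, true_H.shape[1])
    A = np.full((true_H.shape[0], n), baseline)
    rising = np.isfinite(u)
    for k in range(true_H.shape[0]):
        A[k, rising] += np.interp(u[rising], grid, true_H[k])
        A[k, desc] += descent_gain * np.interp(1.0 - ud[desc], grid, true_H[k])
    return A


def _perturb_weights(template: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    W = np.maximum(template + rng.normal(0.0, sd, size=template.shape), 1e-6)
    return W / np.linalg.norm(W, axis=0)


def generate_cohort(config: CohortConfig, seed: int) -> SyntheticCohort:
    """Generate a full cohort; deterministic under a fixed master seed.

    The first ``n3`` subjects carry 3 synergies, the rest 4; 4-synergy
    subjects draw their vertical-velocity-peak targets from the faster
    distribution (``vt_peak_mean_n4``).  Subjects within a synergy-count
    group share one group-level ground-truth W/H template — the premise of
    group-average synergy analysis — with a small per-subject weight
    perturbation (``w_jitter_sd``).
    """
    subjects: list[GroundTruthSubject] = []
    observed: dict[str, EnvelopeMatrix] = {}
    trials: dict[str, pd.DataFrame] = {}
    truth: dict[str, dict] = {}

    templates = {
        3: make_ground_truth_synergies(
            3, config.n_muscles, config.samples_per_cycle, seed=subject_seed(seed, 10007)
        ),
        4: make_ground_truth_synergies(
            4, config.n_muscles, config.samples_per_cycle,
            seed=subject_seed(seed, 10009), split_second=True,
        ),
    }

    n_total = config.n3 + config.n4
    for i in range(n_total):
        n_syn = 3 if i < config.n3 else 4
        s_seed = subject_seed(seed, i)
        rng = np.random.default_rng(s_seed)
        peak_mean = config.vt_peak_mean_n3 if n_syn == 3 else config.vt_peak_mean_n4
        vt_peak = max(0.1, rng.normal(peak_mean, config.vt_peak_sd))
        mass = max(40.0, rng.normal(config.body_mass_mean, config.body_mass_sd))
        height = float(np.clip(rng.normal(config.body_height_mean, config.body_height_sd), 1.4, 2.1))

        W_tmpl, H_tmpl = templates[n_syn]
        W = _perturb_weights(W_tmpl, config.w_jitter_sd, rng)
        H = H_tmpl + config.baseline_level

        subj = GroundTruthSubject(
            subject_id=f"S{i + 1:02d}",
            true_n_syn=n_syn,
            true_W=W,
            true_H=H,
            n_cycles=config.n_cycles,
            vt_velocity_peak=float(vt_peak),
            body_mass=float(mass),
            body_height=height,
            seed=s_seed,
        )

        markers, timing = generate_marker_trial(
            subj,
            n_cycles=config.n_cycles,
            fs=config.marker_fs,
            seed=s_seed + 1,
            marker_noise_sd=config.marker_noise_sd,
        )
        A = _activation_timecourse(
            H - config.baseline_level,
            config.n_cycles,
            timing["cycle_duration"],
            config.emg_fs,
            config.baseline_level,
            config.descent_gain,
        )
        if config.snr_db is not None:
            sd = noise_sd_for_snr(W, A, config.snr_db)
        else:
            sd = config.noise_sd
        env = synthesize_envelopes(
            W, A, sd, seed=s_seed + 2, fs=config.emg_fs,
            muscle_names=list(MUSCLES[: config.n_muscles])
            if config.n_muscles <= len(MUSCLES)
            else [f"m{k}" for k in range(config.n_muscles)],
        )

        subjects.append(subj)
        observed[subj.subject_id] = env
        trials[subj.subject_id] = markers
        truth[subj.subject_id] = timing

    return SyntheticCohort(
        subjects=subjects,
        observed_emg=observed,
        marker_trials=trials,
        config_echo=config,
        trial_truth=truth,
    )


# --------------------------------------------------------------------------
# cohort I/O (plain-text directory tree)
# --------------------------------------------------------------------------

def write_cohort(cohort: SyntheticCohort, path: str | Path) -> None:
    """Write a cohort as per-subject emg.csv / markers.csv / truth.json + config.yaml."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    with open(root / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(cohort.config_echo), fh)
    for subj in cohort.subjects:
        d = root / subj.subject_id
        d.mkdir(exist_ok=True)
        env = cohort.observed_emg[subj.subject_id]
        pd.DataFrame(env.values.T, columns=env.muscle_names).to_csv(
            d / "emg.csv", index=False
        )
        cohort.marker_trials[subj.subject_id].to_csv(d / "markers.csv", index=False)
        timing = cohort.trial_truth.get(subj.subject_id, {})
        truth = {
            "subject_id": subj.subject_id,
            "true_n_syn": subj.true_n_syn,
            "true_W": subj.true_W.tolist(),
            "true_H": subj.true_H.tolist(),
            "n_cycles": subj.n_cycles,
            "vt_velocity_peak": subj.vt_velocity_peak,
            "body_mass": subj.body_mass,
            "body_height": subj.body_height,
            "seed": subj.seed,
            "emg_fs": env.fs,
            "timing": {
                "cycle_duration": timing.get("cycle_duration"),
                "rise_windows_s": timing.get("rise_windows_s"),
                "fs": timing.get("fs"),
            },
        }
        with open(d / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1)


def load_cohort(path: str | Path) -> SyntheticCohort:
    """Read back a cohort directory written by :func:`write_cohort`."""
    root = Path(path)
    with open(root / "config.yaml") as fh:
        config = CohortConfig(**yaml.safe_load(fh))
    subjects, observed, trials, truth_d = [], {}, {}, {}
    subj_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    for d in subj_dirs:
        with open(d / "truth.json") as fh:
            truth = json.load(fh)
        emg = pd.read_csv(d / "emg.csv")
        env = EnvelopeMatrix(
            values=emg.to_numpy().T,
            muscle_names=list(emg.columns),
            fs=truth["emg_fs"],
        )
        subj = GroundTruthSubject(
            subject_id=truth["subject_id"],
            true_n_syn=truth["true_n_syn"],
            true_W=np.asarray(truth["true_W"]),
            true_H=np.asarray(truth["true_H"]),
            n_cycles=truth["n_cycles"],
            vt_velocity_peak=truth["vt_velocity_peak"],
            body_mass=truth["body_mass"],
            body_height=truth["body_height"],
            seed=truth["seed"],
        )
        subjects.append(subj)
        observed[subj.subject_id] = env
        trials[subj.subject_id] = pd.read_csv(d / "markers.csv")
        timing = truth.get("timing") or {}
        if timing.get("rise_windows_s") is not None:
            timing["rise_windows_s"] = [tuple(w) for w in timing["rise_windows_s"]]
        truth_d[subj.subject_id] = timing
    return SyntheticCohort(
        subjects=subjects,
        observed_emg=observed,
        marker_trials=trials,
        config_echo=config,
        trial_truth=truth_d,
    )
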