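"""End-to-end study orchestration.

``run_study`` drives the whole analysis on a cohort directory or in-memory
cohort: envelope preparation, CoM phase spaces, per-subject NNMF with
model-order selection, partition of subjects by synergy count, group-average
synergy weights, fixed-W (and cross-) activation reconstruction, group-level
state-to-synergy mappings in all nine 2D spaces, and Kruskal-Wallis tests of
the phase-space parameters across synergy-count groups.  Everything is
seeded from a single master seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import stats as sstats

from . import com as com_mod
from . import mapping as map_mod
from . import preprocess as pre_mod
from . import synergy as syn_mod
from .synth import SyntheticCohort, load_cohort

#: phase-space summary statistics entering the group comparison
STAT_COLUMNS = ("max_mean", "min_mean", "range_mean", "range_variability")


# --------------------------------------------------------------------------
# statistics
# --------------------------------------------------------------------------

def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p across >= 2 groups."""
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if len(np.atleast_1d(g)) == 0:
            raise ValueError(f"group {i} has zero observations")
    res = sstats.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Analysis parameters for a full study run."""

    orders: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    n_restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-6
    n_points: int = 100                  # time-normalization grid
    target_duration: float = 10.0        # s of upward-phase time to retain per subject
    amplitude_normalize: bool = True     # per-muscle envelope max-normalization
    emg_is_envelope: bool = True         # synthetic cohorts store envelopes directly
    envelope_band: tuple[float, float] = (20.0, 450.0)
    envelope_lowpass: float = 5.0
    test_fraction: float = 0.2
    surface_n: int = 100
    alpha: float = 0.05
    group_orders: tuple[int, ...] = (3, 4)  # synergy counts entering the group stats


# --------------------------------------------------------------------------
# study result
# --------------------------------------------------------------------------

@dataclass
class StudyResult:
    """Aggregated outputs of one study run.

    Heavyweight objects (decompositions, maps, surfaces) are kept in memory
    for programmatic use; ``to_jsonable``/``to_json`` serialize the summary
    quantities (selected orders, VAFs, accuracies, statistics, seeds).
    """

    master_seed: int
    config: StudyConfig
    per_subject: dict[str, dict]
    groups: dict[int, list[str]]
    group_weights: dict[int, np.ndarray]
    reconstructions: dict[str, dict[int, dict]]
    mappings: dict[int, map_mod.GroupMappingResults]
    stats: dict[str, dict[str, dict[str, float]]]
    notes: list[str] = field(default_factory=list)

    def to_jsonable(self) -> dict:
        out = {
            "master_seed": self.master_seed,
            "config": asdict(self.config),
            "per_subject": {
                sid: {
                    "selected_n": rec["selected_n"],
                    "vaf": rec["vaf"],
                    "orders": rec["orders"],
                    "aic_values": list(map(float, rec["aic_values"])),
                    "n_cycles_selected": rec["n_cycles_selected"],
                    "seed": rec["seed"],
                    "phase_summary": rec["phase_summary"],
                }
                for sid, rec in self.per_subject.items()
            },
            "groups": {str(k): v for k, v in self.groups.items()},
            "group_weights": {str(k): w.tolist() for k, w in self.group_weights.items()},
            "reconstructions": {
                sid: {
                    str(n): {"vaf": r["vaf"], "own_group": r["own_group"]}
                    for n, r in by_n.items()
                }
                for sid, by_n in self.reconstructions.items()
            },
            "mappings": {
                str(n): {
                    "accuracies": res.accuracy_table(),
                    "pca_explained_fraction": res.pca_explained_fraction,
                }
                for n, res in self.mappings.items()
            },
            "stats": self.stats,
            "notes": self.notes,
        }
        return out

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_jsonable(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------

def _subject_analysis_seed(master_seed: int, index: int) -> int:
    return (master_seed * 9176 + 31 * index + 17) % (2**31)


def _emg_interval(interval: tuple[int, int], marker_fs: float, emg_fs: float, n_emg: int):
    a = int(round(interval[0] * emg_fs / marker_fs))
    b = int(round(interval[1] * emg_fs / marker_fs))
    return max(a, 0), min(b, n_emg)


def _prepare_envelope(env: pre_mod.EnvelopeMatrix, config: StudyConfig) -> np.ndarray:
    values = env.values
    if not config.emg_is_envelope:
        values = pre_mod.compute_envelope(
            values, env.fs, band=config.envelope_band,
            lowpass=config.envelope_lowpass, muscle_names=env.muscle_names,
        ).values
    if config.amplitude_normalize:
        peaks = values.max(axis=1, keepdims=True)
        values = values / np.where(peaks > 0, peaks, 1.0)
    return values


# --------------------------------------------------------------------------
# main entry point
# --------------------------------------------------------------------------

def run_study(
    cohort: SyntheticCohort | str | Path,
    config: StudyConfig | None = None,
    seed: int = 0,
) -> StudyResult:
    """Run the full analysis on a cohort; deterministic under ``seed``."""
    if not isinstance(cohort, SyntheticCohort):
        cohort = load_cohort(cohort)
    config = config or StudyConfig()

    per_subject: dict[str, dict] = {}
    V_by_subject: dict[str, np.ndarray] = {}
    cycle_cache: dict[str, dict] = {}
    notes: list[str] = []

    for i, subj in enumerate(cohort.subjects):
        sid = subj.subject_id
        s_seed = _subject_analysis_seed(seed, i)
        env = cohort.observed_emg[sid]
        env_values = _prepare_envelope(env, config)

        markers = cohort.marker_trials[sid]
        marker_fs = cohort.config_echo.marker_fs
        com3d = com_mod.estimate_com(markers)
        x, y = com_mod.to_sagittal_relative(
            com3d,
            com_mod.marker_xyz(markers, "malleolus_left"),
            com_mod.marker_xyz(markers, "malleolus_right"),
        )
        cycles = pre_mod.segment_upward_cycles(y, marker_fs)
        if len(cycles) == 0:
            raise RuntimeError(f"segmentation: no sit-to-stand cycles found for {sid}")
        selected = pre_mod.select_random_cycles(cycles, config.target_duration, s_seed)

        segments = []
        for interval in selected.intervals:
            a, b = _emg_interval(interval, marker_fs, env.fs, env_values.shape[1])
            if b - a < 2:
                raise RuntimeError(f"synergy input: empty EMG slice for {sid} cycle {interval}")
            segments.append(pre_mod.time_normalize(env_values[:, a:b], config.n_points))
        V = np.concatenate(segments, axis=1)
        V_by_subject[sid] = V

        # order selection and weight extraction on the cycle-averaged
        # envelope: uncorrelated noise averages down across repetitions while
        # any genuine low-amplitude synergy, being cycle-coherent, survives
        V_avg = np.mean(np.stack(segments), axis=0)
        sel = syn_mod.select_n_syn(
            V_avg, config.orders,
            n_restarts=config.n_restarts, max_iter=config.max_iter,
            tol=config.tol, seed=s_seed,
        )
        dec = sel.decompositions[sel.selected_n]

        trajs = com_mod.build_phase_trajectory(x, y, marker_fs, selected, config.n_points)
        params = com_mod.phase_space_parameters(trajs)

        per_subject[sid] = {
            "selected_n": sel.selected_n,
            "orders": list(sel.candidate_orders),
            "aic_values": sel.aic_values,
            "vaf": dec.vaf,
            "decomposition": dec,
            "order_selection": sel,
            "phase_parameters": params,
            "phase_summary": {
                var: {stat: float(params.summary.loc[var, stat]) for stat in STAT_COLUMNS}
                for var in com_mod.VARIABLE_NAMES
            },
            "trajectories": trajs,
            "n_cycles_selected": len(selected),
            "seed": s_seed,
        }
        cycle_cache[sid] = {
            "x": x, "y": y, "marker_fs": marker_fs,
            "intervals": selected.intervals, "env_values": env_values, "emg_fs": env.fs,
        }

    # ---- partition by selected synergy count -----------------------------
    groups: dict[int, list[str]] = {}
    for sid, rec in per_subject.items():
        groups.setdefault(rec["selected_n"], []).append(sid)
    for n in sorted(groups):
        if n not in config.group_orders:
            warnings.warn(
                f"subjects {groups[n]} selected N_syn={n}, outside the group "
                f"orders {config.group_orders}; excluded from group statistics",
                stacklevel=2,
            )
            notes.append(f"N_syn={n} group ({groups[n]}) excluded from group statistics")

    # ---- group-average weights and reconstructions -----------------------
    group_weights: dict[int, np.ndarray] = {}
    reconstructions: dict[str, dict[int, dict]] = {sid: {} for sid in per_subject}
    mappings: dict[int, map_mod.GroupMappingResults] = {}

    for n, members in sorted(groups.items()):
        W_list = [per_subject[sid]["decomposition"].W for sid in members]
        ref_sid = max(members, key=lambda s: per_subject[s]["vaf"])
        reference = per_subject[ref_sid]["decomposition"].W
        perms = syn_mod.match_synergies(W_list, reference)
        Wbar = group_weights[n] = syn_mod.average_weights(W_list, perms)

        # reconstruct every subject with this group's average W; own-group
        # profiles feed the mapping, cross-reconstructions are kept as-is
        for sid in per_subject:
            V = V_by_subject[sid]
            H = syn_mod.reconstruct_activations(V, Wbar)
            reconstructions[sid][n] = {
                "H": H,
                "vaf": syn_mod.vaf(V, Wbar, H),
                "own_group": sid in members,
            }

        # group mapping: features and labels paired at the original marker
        # sampling within every retained upward-phase cycle
        records = []
        for sid in members:
            cc = cycle_cache[sid]
            for interval in cc["intervals"]:
                n_k = interval[1] - interval[0]
                a, b = _emg_interval(interval, cc["marker_fs"], cc["emg_fs"],
                                     cc["env_values"].shape[1])
                V_k = pre_mod.time_normalize(cc["env_values"][:, a:b], n_k)
                H_k = syn_mod.reconstruct_activations(V_k, Wbar)
                features = com_mod.phase_variables(cc["x"], cc["y"], cc["marker_fs"], interval)
                records.append({"features": features, "labels": map_mod.label_most_active(H_k)})
        try:
            mappings[n] = map_mod.run_group_mappings(
                records, n, test_fraction=config.test_fraction,
                seed=_subject_analysis_seed(seed, 1000 + n), surface_n=config.surface_n,
            )
        except ValueError as exc:
            notes.append(f"mapping skipped for N_syn={n} group: {exc}")

    # ---- Kruskal-Wallis of phase-space parameters across groups ----------
    stats: dict[str, dict[str, dict[str, float]]] = {}
    stat_groups = [n for n in config.group_orders if n in groups]
    if len(stat_groups) >= 2:
        for var in com_mod.VARIABLE_NAMES:
            stats[var] = {}
            for stat in STAT_COLUMNS:
                samples = [
                    np.array([per_subject[sid]["phase_summary"][var][stat] for sid in groups[n]])
                    for n in stat_groups
                ]
                H, p = kruskal_wallis(samples)
                stats[var][stat] = {"H": H, "p": p, "significant": bool(p < config.alpha)}
    else:
        notes.append("fewer than two synergy-count groups: group statistics skipped")

    return StudyResult(
        master_seed=seed,
        config=config,
        per_subject=per_subject,
        groups=groups,
        group_weights=group_weights,
        reconstructions=reconstructions,
        mappings=mappings,
        stats=stats,
        notes=notes,
    )
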