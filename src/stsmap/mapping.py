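"""Probabilistic mapping from 2D phase-space position to the most-active synergy.

Each sample of a sit-to-stand cycle is labeled with the index of the most
active synergy (argmax over max-rescaled activation rows) and described by a
2-feature vector taken from one of the eight 2D variable combinations of the
cartesian and polar phase spaces, or from the first two principal components
of all eight variables.  A Gaussian naive Bayes model fitted on these labeled
states yields, at any point of a 2D space, the posterior probability of each
synergy being the most active — the mapping output is deliberately fuzzy
(a probability vector), so overlapping dominance regions are representable.

Features and labels are paired at the original (pre-normalization) sampling
of each upward-phase cycle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.model_selection import train_test_split

from .com import PhaseTrajectory, VARIABLE_NAMES

#: the eight 2D variable combinations, in the naming used for results tables
FEATURE_PAIRS: dict[str, tuple[str, str]] = {
    "cartesian position-position": ("x", "y"),
    "cartesian velocity-velocity": ("vx", "vy"),
    "cartesian AP position-velocity": ("x", "vx"),
    "cartesian VT position-velocity": ("y", "vy"),
    "polar position-position": ("mag", "ang"),
    "polar velocity-velocity": ("vmag", "vang"),
    "polar magnitude position-velocity": ("mag", "vmag"),
    "polar angle position-velocity": ("ang", "vang"),
}

PCA_SPACE = "pca 2d"


# --------------------------------------------------------------------------
# labeling
# --------------------------------------------------------------------------

def label_most_active(H: np.ndarray, rescale: bool = True) -> np.ndarray:
    """Index of the most active synergy per sample.

    By default each activation row is divided by its trial maximum first:
    with unit-norm weight columns the raw rows carry arbitrary relative
    scale, and rescaling makes the across-synergy argmax meaningful.  Ties
    resolve to the lowest index; an all-zero sample carries the previous
    sample's label forward (label 0 if there is no previous sample).
    """
    H = np.asarray(H, dtype=float)
    if H.ndim != 2:
        raise ValueError("H must be 2-D (n_syn x samples)")
    if np.any(H < 0):
        raise ValueError("H must be nonnegative")
    Hr = H
    if rescale:
        peaks = H.max(axis=1, keepdims=True)
        Hr = H / np.where(peaks > 0, peaks, 1.0)
    labels = np.argmax(Hr, axis=0)
    dead = Hr.max(axis=0) == 0
    if np.any(dead):
        labels = labels.copy()
        prev = 0
        for j in range(labels.size):
            if dead[j]:
                labels[j] = prev
            else:
                prev = labels[j]
    return labels


def make_feature_pairs(
    traj: PhaseTrajectory | Mapping[str, np.ndarray],
) -> dict[str, np.ndarray]:
    """The 8 two-column feature datasets, each (n_samples, 2)."""
    if isinstance(traj, PhaseTrajectory):
        series = {name: getattr(traj, name) for name in VARIABLE_NAMES}
    else:
        series = {name: np.asarray(traj[name], dtype=float) for name in VARIABLE_NAMES}
    return {
        pair_id: np.column_stack([series[a], series[b]])
        for pair_id, (a, b) in FEATURE_PAIRS.items()
    }


# --------------------------------------------------------------------------
# Gaussian naive Bayes
# --------------------------------------------------------------------------

@dataclass
class SynergyMap:
    """Per-class Gaussian feature model over one 2D feature pair."""

    classes: np.ndarray        # label values, ascending
    class_priors: np.ndarray   # (C,), sums to 1
    means: np.ndarray          # (C, 2)
    variances: np.ndarray      # (C, 2), floored
    feature_pair_id: str | None = None
    n_syn_group: int | None = None

    @property
    def n_classes(self) -> int:
        return self.classes.size


def fit_gnb(
    X: np.ndarray,
    y: np.ndarray,
    var_floor_frac: float = 1e-9,
    feature_pair_id: str | None = None,
    n_syn_group: int | None = None,
) -> SynergyMap:
    """Fit a Gaussian naive Bayes model: empirical priors, per-class feature
    means and variances.

    Variances are floored at ``var_floor_frac`` times the squared feature
    range (with an absolute floor of 1e-12) so near-constant features never
    produce degenerate Gaussians.  Every present class needs >= 2 samples.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be (n_samples, n_features)")
    classes, counts = np.unique(y, return_counts=True)
    thin = classes[counts < 2]
    if thin.size:
        raise ValueError(f"classes {thin.tolist()} have fewer than 2 samples")

    priors = counts / counts.sum()
    means = np.vstack([X[y == c].mean(axis=0) for c in classes])
    variances = np.vstack([X[y == c].var(axis=0) for c in classes])
    ranges = X.max(axis=0) - X.min(axis=0)
    floor = np.maximum(var_floor_frac * ranges**2, 1e-12)
    variances = np.maximum(variances, floor)
    return SynergyMap(
        classes=classes,
        class_priors=priors,
        means=means,
        variances=variances,
        feature_pair_id=feature_pair_id,
        n_syn_group=n_syn_group,
    )


def predict_proba(smap: SynergyMap, features: np.ndarray) -> np.ndarray:
    """Exact class posterior at one or many feature points, computed in log space.

    Returns (C,) for a single 2-vector, else (n, C); rows sum to 1.
    """
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    # log N(x | mu, sigma^2) summed over the (conditionally independent) features
    diff = X[:, None, :] - smap.means[None, :, :]          # (n, C, F)
    log_lik = -0.5 * (
        np.log(2.0 * np.pi * smap.variances)[None] + diff**2 / smap.variances[None]
    ).sum(axis=2)
    log_post = np.log(smap.class_priors)[None] + log_lik
    log_post -= logsumexp(log_post, axis=1, keepdims=True)
    proba = np.exp(log_post)
    return proba[0] if np.asarray(features).ndim == 1 else proba


def evaluate_mapping(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    **fit_kwargs,
) -> float:
    """Held-out accuracy of the mapping under a stratified random split.

    Fits on the (1 - test_fraction) training portion and scores the argmax
    posterior on the held-out portion.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    try:
        X_tr, X_te, y_tr, y_te = train_test_split(
            X, y, test_size=test_fraction, stratify=y, random_state=seed % (2**32)
        )
    except ValueError as exc:
        raise ValueError(f"cannot stratify the train/test split: {exc}") from exc
    smap = fit_gnb(X_tr, y_tr, **fit_kwargs)
    proba = predict_proba(smap, X_te)
    predicted = smap.classes[np.argmax(proba, axis=1)]
    return float(np.mean(predicted == y_te))


# --------------------------------------------------------------------------
# probability surfaces
# --------------------------------------------------------------------------

@dataclass
class ProbabilitySurface:
    """Posterior probabilities of each synergy on a regular 2D lattice."""

    grid_x: np.ndarray         # (nx,)
    grid_y: np.ndarray         # (ny,)
    probabilities: np.ndarray  # (ny, nx, C), each node sums to 1
    classes: np.ndarray

    def dominance(self) -> np.ndarray:
        """Per node, the class whose posterior is largest (ties -> lowest index)."""
        return self.classes[np.argmax(self.probabilities, axis=2)]


def probability_surface(
    smap: SynergyMap,
    X: np.ndarray | None = None,
    ranges: tuple[tuple[float, float], tuple[float, float]] | None = None,
    n: int = 100,
    pad: float = 0.05,
) -> ProbabilitySurface:
    """Evaluate the posterior on an ``n x n`` lattice.

    Ranges default to the data extent of ``X`` padded by ``pad`` on each side.
    """
    if ranges is None:
        if X is None:
            raise ValueError("provide either explicit ranges or data X")
        X = np.asarray(X, dtype=float)
        lo, hi = X.min(axis=0), X.max(axis=0)
        span = np.where(hi > lo, hi - lo, 1.0)
        ranges = (
            (lo[0] - pad * span[0], hi[0] + pad * span[0]),
            (lo[1] - pad * span[1], hi[1] + pad * span[1]),
        )
    gx = np.linspace(*ranges[0], n)
    gy = np.linspace(*ranges[1], n)
    XX, YY = np.meshgrid(gx, gy)
    nodes = np.column_stack([XX.ravel(), YY.ravel()])
    proba = predict_proba(smap, nodes).reshape(n, n, smap.n_classes)
    return ProbabilitySurface(grid_x=gx, grid_y=gy, probabilities=proba, classes=smap.classes)


# --------------------------------------------------------------------------
# PCA feature space
# --------------------------------------------------------------------------

@dataclass
class PCA2DResult:
    scores: np.ndarray             # (n, 2)
    explained_fraction: float
    components: np.ndarray         # (n_vars, 2), orthonormal columns
    mean: np.ndarray
    scale: np.ndarray


def pca_2d(parameters: np.ndarray) -> PCA2DResult:
    """First two principal components of the 8 phase-space variables.

    Variables are z-scored (the variables have heterogeneous units, so the
    decomposition acts on the correlation matrix); zero-variance columns get
    zero loadings.  Sign convention: the largest-magnitude loading of each
    component is positive.
    """
    M = np.asarray(parameters, dtype=float)
    if M.ndim != 2 or M.shape[0] < 3:
        raise ValueError("need at least 3 samples of the phase-space variables")
    mean = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    scale = np.where(sd > 0, sd, 1.0)
    Z = (M - mean) / scale
    corr = (Z.T @ Z) / (M.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(corr)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    comps = eigvecs[:, :2].copy()
    for j in range(2):
        if comps[np.argmax(np.abs(comps[:, j])), j] < 0:
            comps[:, j] = -comps[:, j]
    total = eigvals.sum()
    explained = float((eigvals[0] + eigvals[1]) / total) if total > 0 else 0.0
    return PCA2DResult(
        scores=Z @ comps,
        explained_fraction=explained,
        components=comps,
        mean=mean,
        scale=scale,
    )


# --------------------------------------------------------------------------
# group-level mapping runs
# --------------------------------------------------------------------------

@dataclass
class MappingResult:
    feature_space: str
    accuracy: float
    map: SynergyMap
    surface: ProbabilitySurface
    n_samples: int


@dataclass
class GroupMappingResults:
    n_syn_group: int
    by_space: dict[str, MappingResult]
    pca_explained_fraction: float

    def accuracy_table(self) -> dict[str, float]:
        return {k: v.accuracy for k, v in self.by_space.items()}


def run_group_mappings(
    cycle_records: Sequence[Mapping],
    n_syn_group: int,
    test_fraction: float = 0.2,
    seed: int = 0,
    surface_n: int = 100,
) -> GroupMappingResults:
    """Fit and evaluate the mapping in all 8 variable pairs plus the PCA space.

    ``cycle_records`` are per-cycle dicts with key ``"features"`` (a mapping
    of the 8 variable names to same-length arrays at the cycle's original
    sampling) and ``"labels"`` (the simultaneous most-active-synergy series).
    Samples are pooled across cycles and subjects before fitting.
    """
    if not cycle_records:
        raise ValueError("group is empty")
    pooled = {
        name: np.concatenate([np.asarray(r["features"][name]) for r in cycle_records])
        for name in VARIABLE_NAMES
    }
    labels = np.concatenate([np.asarray(r["labels"]) for r in cycle_records])

    results: dict[str, MappingResult] = {}
    for pair_id, (a, b) in FEATURE_PAIRS.items():
        X = np.column_stack([pooled[a], pooled[b]])
        acc = evaluate_mapping(X, labels, test_fraction, seed)
        smap = fit_gnb(X, labels, feature_pair_id=pair_id, n_syn_group=n_syn_group)
        surf = probability_surface(smap, X=X, n=surface_n)
        results[pair_id] = MappingResult(pair_id, acc, smap, surf, X.shape[0])

    M = np.column_stack([pooled[name] for name in VARIABLE_NAMES])
    pca = pca_2d(M)
    acc = evaluate_mapping(pca.scores, labels, test_fraction, seed)
    smap = fit_gnb(pca.scores, labels, feature_pair_id=PCA_SPACE, n_syn_group=n_syn_group)
    surf = probability_surface(smap, X=pca.scores, n=surface_n)
    results[PCA_SPACE] = MappingResult(PCA_SPACE, acc, smap, surf, pca.scores.shape[0])

    return GroupMappingResults(
        n_syn_group=n_syn_group,
        by_space=results,
        pca_explained_fraction=pca.explained_fraction,
    )
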