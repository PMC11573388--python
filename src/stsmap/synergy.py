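"""Muscle synergy extraction by nonnegative matrix factorization.

An envelope matrix V (muscles x samples) is approximated as V ~ W H with
W >= 0 the synergy weight vectors (muscles x N_syn, unit-norm columns) and
H >= 0 the activation coefficients (N_syn x samples).  The factorization uses
Lee-Seung multiplicative updates on the Frobenius cost, restarted from
several random initializations; the model order N_syn is selected by an
information criterion balancing residual energy against the number of free
parameters.  Group-level analysis matches synergies across subjects by
weight-vector cosine similarity, averages the matched weights, and
reconstructs activations for a *fixed* average W by nonnegative least
squares.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import nnls as _nnls

_EPS = 1e-12


@dataclass
class SynergyDecomposition:
    """Result of one NNMF fit (best restart kept)."""

    W: np.ndarray              # muscles x n_syn, unit-norm columns
    H: np.ndarray              # n_syn x samples
    vaf: float                 # variance accounted for on the fitted data
    n_iter: int
    cost_trace: np.ndarray     # Frobenius cost per iteration, non-increasing
    restarts_used: int
    seed: int

    @property
    def n_syn(self) -> int:
        return self.W.shape[1]


@dataclass
class OrderSelectionResult:
    candidate_orders: list[int]
    aic_values: np.ndarray
    selected_n: int
    vaf_curve: np.ndarray
    decompositions: dict[int, SynergyDecomposition] = field(default_factory=dict)


def vaf(V: np.ndarray, W: np.ndarray, H: np.ndarray) -> float:
    """Variance accounted for: 1 - ||V - WH||_F^2 / ||V||_F^2, clipped to [0, 1]."""
    V = np.asarray(V, dtype=float)
    total = float(np.sum(V**2))
    if total == 0.0:
        raise ValueError("vaf undefined for an all-zero matrix")
    resid = float(np.sum((V - W @ H) ** 2))
    return float(np.clip(1.0 - resid / total, 0.0, 1.0))


def _order_by_peak_time(W: np.ndarray, H: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # "first synergy" is temporally first: sort columns by H peak sample
    peaks = np.argmax(H, axis=1)
    order = np.argsort(peaks, kind="stable")
    return W[:, order], H[order]


def _mu_fit(
    V: np.ndarray, n_syn: int, rng: np.random.Generator, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    m, t = V.shape
    scale = math.sqrt(max(V.mean(), _EPS) / n_syn)
    W = scale * rng.random((m, n_syn)) + _EPS
    H = scale * rng.random((n_syn, t)) + _EPS

    trace: list[float] = []
    prev = float(np.sum((V - W @ H) ** 2))
    trace.append(prev)
    for _ in range(max_iter):
        H *= (W.T @ V) / (W.T @ W @ H + _EPS)
        W *= (V @ H.T) / (W @ (H @ H.T) + _EPS)
        cost = float(np.sum((V - W @ H) ** 2))
        if cost > prev * (1 + 1e-12) + _EPS:
            break  # monotonicity exhausted by round-off: converged
        trace.append(cost)
        if prev - cost <= tol * max(prev, _EPS):
            prev = cost
            break
        prev = cost
    return W, H, trace


def nnmf(
    V: np.ndarray,
    n_syn: int,
    max_iter: int = 1000,
    tol: float = 1e-6,
    n_restarts: int = 20,
    seed: int = 0,
) -> SynergyDecomposition:
    """Factor V >= 0 into W H by multiplicative updates, best of ``n_restarts``.

    The Frobenius cost is non-increasing along the returned ``cost_trace``.
    W columns are normalized to unit Euclidean norm with the compensating
    scale moved into H, then ordered by ascending activation peak time.
    """
    V = np.asarray(V, dtype=float)
    if V.ndim != 2:
        raise ValueError("V must be 2-D")
    if np.any(V < 0):
        raise ValueError("V must be elementwise nonnegative")
    if not 1 <= n_syn <= min(V.shape):
        raise ValueError(f"n_syn={n_syn} outside [1, {min(V.shape)}]")

    best: tuple[float, np.ndarray, np.ndarray, list[float]] | None = None
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        W, H, trace = _mu_fit(V, n_syn, rng, max_iter, tol)
        if best is None or trace[-1] < best[0]:
            best = (trace[-1], W, H, trace)
    assert best is not None
    _, W, H, trace = best

    norms = np.linalg.norm(W, axis=0)
    safe = np.where(norms > _EPS, norms, 1.0)
    W = W / safe
    H = H * safe[:, None]
    W, H = _order_by_peak_time(W, H)

    return SynergyDecomposition(
        W=W,
        H=H,
        vaf=vaf(V, W, H) if np.any(V) else 1.0,
        n_iter=len(trace) - 1,
        cost_trace=np.asarray(trace),
        restarts_used=n_restarts,
        seed=seed,
    )


# --------------------------------------------------------------------------
# model-order selection
# --------------------------------------------------------------------------

def aic_gaussian_rss(rss: float, n_obs: int, n_params: int) -> float:
    """Classic Gaussian-residual AIC: n_obs ln(RSS / n_obs) + 2 k.

    With an envelope matrix the parameter count k = N (M + T) grows with the
    sample count, a regime where the 2-per-parameter penalty is known to
    over-select; kept available for comparison, but
    :func:`bic_gaussian_rss` is the default criterion.
    """
    return n_obs * math.log(rss / n_obs) + 2 * n_params


def bic_gaussian_rss(rss: float, n_obs: int, n_params: int) -> float:
    """Gaussian-residual information criterion with a ln(n_obs) penalty.

    The stronger per-parameter penalty keeps the criterion consistent when
    the activation parameters scale with the number of time samples: fitting
    an extra synergy to pure noise reduces the RSS by at most the leading
    noise-eigenvalue share (~1/M for M muscles), which this penalty rejects,
    while a genuine low-amplitude synergy coherent across cycles survives.
    """
    return n_obs * math.log(rss / n_obs) + math.log(n_obs) * n_params


def select_n_syn(
    V: np.ndarray,
    orders: Sequence[int],
    criterion: Callable[[float, int, int], float] = bic_gaussian_rss,
    rss_floor_frac: float = 1e-6,
    **nnmf_opts,
) -> OrderSelectionResult:
    """Fit every candidate order and pick the criterion minimizer.

    Free-parameter count is k_N = N (n_muscles + n_samples).  The residual
    sum of squares entering the criterion is floored at
    ``rss_floor_frac * ||V||_F^2``: on exactly factorizable data the RSS at
    and above the true order is optimizer round-off (its level set by the
    iteration budget, not by the data), and flooring turns those orders into
    exact ties, resolved to the smallest order.  The floor sits far below
    any genuinely unexplained signal component at realistic noise levels.
    """
    V = np.asarray(V, dtype=float)
    orders = sorted(int(n) for n in orders)
    m, t = V.shape
    n_obs = m * t
    total = float(np.sum(V**2))

    aics = []
    vafs = []
    decomps: dict[int, SynergyDecomposition] = {}
    for n in orders:
        dec = nnmf(V, n, **nnmf_opts)
        rss = float(np.sum((V - dec.W @ dec.H) ** 2))
        rss_eff = max(rss, rss_floor_frac * total)
        aics.append(criterion(rss_eff, n_obs, n * (m + t)))
        vafs.append(dec.vaf)
        decomps[n] = dec

    aics_arr = np.asarray(aics)
    selected = orders[int(np.argmin(aics_arr))]  # ties -> smallest (orders sorted)
    return OrderSelectionResult(
        candidate_orders=list(orders),
        aic_values=aics_arr,
        selected_n=selected,
        vaf_curve=np.asarray(vafs),
        decompositions=decomps,
    )


# --------------------------------------------------------------------------
# cross-subject matching and averaging
# --------------------------------------------------------------------------

def _cosine_matrix(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na = np.where(na > _EPS, na, 1.0)
    nb = np.where(nb > _EPS, nb, 1.0)
    return (A / na).T @ (B / nb)


def match_synergies(
    W_list: Sequence[np.ndarray], reference: np.ndarray
) -> list[tuple[int, ...]]:
    """Best column permutation of each W against a reference, by total cosine.

    Returns, per subject, the permutation ``perm`` such that
    ``W[:, perm]`` aligns column j with reference column j; found by
    exhaustive search over permutations (N_syn <= 8 in practice).
    """
    n = reference.shape[1]
    perms_out: list[tuple[int, ...]] = []
    for W in W_list:
        if W.shape[1] != n:
            raise ValueError(
                f"cannot match {W.shape[1]} synergies against a {n}-synergy reference"
            )
        cos = _cosine_matrix(W, reference)  # cos[i, j] = sim(W col i, ref col j)
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(n)):
            score = sum(cos[perm[j], j] for j in range(n))
            if score > best_score:
                best_perm, best_score = perm, score
        perms_out.append(tuple(best_perm))
    return perms_out


def average_weights(
    W_list: Sequence[np.ndarray], permutations: Sequence[tuple[int, ...]]
) -> np.ndarray:
    """Column-wise mean of permuted weight matrices, renormalized to unit norm."""
    stacked = np.stack([W[:, list(p)] for W, p in zip(W_list, permutations)])
    Wbar = stacked.mean(axis=0)
    norms = np.linalg.norm(Wbar, axis=0)
    return Wbar / np.where(norms > _EPS, norms, 1.0)


# --------------------------------------------------------------------------
# fixed-W reconstruction
# --------------------------------------------------------------------------

def reconstruct_activations(V: np.ndarray, W_fixed: np.ndarray) -> np.ndarray:
    """H = argmin_{H>=0} ||V - W_fixed H||_F^2 by per-column NNLS.

    Used both for own-group reconstruction and for cross-reconstruction with
    an average W whose order differs from the subject's own.
    """
    V = np.asarray(V, dtype=float)
    W_fixed = np.asarray(W_fixed, dtype=float)
    if np.any(V < 0) or np.any(W_fixed < 0):
        raise ValueError("V and W_fixed must be nonnegative")
    H = np.empty((W_fixed.shape[1], V.shape[1]))
    for j in range(V.shape[1]):
        H[:, j], _ = _nnls(W_fixed, V[:, j])
    return H
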