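"""Transition-matrix estimation with sliding-window, recrossing-filtered counts.

Transitions are counted with a sliding window of the lag time over each
trajectory separately (trajectories are never concatenated).  Because states
are separated by hard geometric cutoffs, a trajectory sitting on top of a
barrier can oscillate rapidly between two states and inflate the apparent
rate; to suppress these recrossings, a cross-state count ``x -> y`` is accepted
only if the trajectory then remains in ``y`` for a minimum residence time
(default 300 ps = 15 frames at 20 ps).  Self-pairs are always counted.

The transition probability matrix is the row-normalized count matrix; its
stationary left eigenvector gives equilibrium state populations, and implied
timescales t_i = -tau / ln(lambda_i) as a function of lag time provide the
Markovianity diagnostic used to select the lag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components

__all__ = [
    "TransitionModel",
    "ImpliedTimescaleCurve",
    "count_transitions",
    "transition_matrix",
    "stationary_distribution",
    "implied_timescales",
    "choose_lag",
    "forward_run_lengths",
]


@dataclass
class TransitionModel:
    """Counts, row-stochastic matrix and stationary distribution at one lag."""

    counts: np.ndarray
    T: np.ndarray
    pi: np.ndarray
    lag_frames: int
    min_residence_frames: int
    dt_ps: float = 20.0

    @property
    def lag_ns(self) -> float:
        return self.lag_frames * self.dt_ps / 1000.0

    @classmethod
    def from_labels(
        cls,
        label_trajs: list[np.ndarray],
        lag_frames: int = 300,
        min_residence_frames: int = 15,
        n_states: int | None = None,
        dt_ps: float = 20.0,
    ) -> "TransitionModel":
        counts = count_transitions(label_trajs, lag_frames, min_residence_frames,
                                   n_states=n_states)
        T = transition_matrix(counts)
        pi = stationary_distribution(T)
        return cls(counts=counts, T=T, pi=pi, lag_frames=lag_frames,
                   min_residence_frames=min_residence_frames, dt_ps=dt_ps)


@dataclass
class ImpliedTimescaleCurve:
    """Top implied timescales (ns) per lag time (ns)."""

    lags_ns: np.ndarray
    timescales_ns: np.ndarray  # shape (n_lags, n_timescales); NaN/inf where undefined

    def slowest(self) -> np.ndarray:
        return self.timescales_ns[:, 0]


def forward_run_lengths(labels: np.ndarray) -> np.ndarray:
    """For each frame, the number of consecutive frames (incl. itself) with the
    same label looking forward."""
    labels = np.asarray(labels)
    n = len(labels)
    if n == 0:
        return np.empty(0, dtype=np.int64)
    out = np.empty(n, dtype=np.int64)
    # run boundaries: positions where the next label differs
    change = np.flatnonzero(labels[1:] != labels[:-1])
    run_ends = np.append(change, n - 1)          # inclusive end index of each run
    starts = np.append(0, change + 1)
    for s, e in zip(starts, run_ends):
        out[s:e + 1] = np.arange(e - s + 1, 0, -1)
    return out


def count_transitions(
    label_trajs: list[np.ndarray] | np.ndarray,
    lag_frames: int,
    min_residence_frames: int = 1,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts with the destination-residence filter.

    For every frame t with t+lag inside the trajectory the pair
    (x=labels[t], y=labels[t+lag]) is a candidate.  Self-pairs are always
    counted.  A cross pair is counted only if the ``min_residence_frames``
    frames starting at t+lag all carry label y; windows truncated by the
    trajectory end are rejected (residence cannot be verified).
    """
    if isinstance(label_trajs, np.ndarray) and label_trajs.ndim == 1:
        label_trajs = [label_trajs]
    if not len(label_trajs):
        raise ValueError("empty trajectory list")
    if lag_frames < 1 or min_residence_frames < 1:
        raise ValueError("lag_frames and min_residence_frames must be >= 1")
    K = n_states if n_states is not None else 1 + max(
        (int(np.max(t)) for t in label_trajs if len(t)), default=0)
    counts = np.zeros((K, K), dtype=np.int64)
    for labels in label_trajs:
        labels = np.asarray(labels, dtype=np.int64)
        n = len(labels)
        if n <= lag_frames:
            continue
        x = labels[:n - lag_frames]
        y = labels[lag_frames:]
        self_pair = x == y
        np.add.at(counts, (x[self_pair], y[self_pair]), 1)
        cross = ~self_pair
        if min_residence_frames > 1:
            runs = forward_run_lengths(labels)
            t_idx = np.flatnonzero(cross)
            dest = t_idx + lag_frames
            ok = (runs[dest] >= min_residence_frames) & \
                 (dest + min_residence_frames <= n)
            sel = t_idx[ok]
        else:
            sel = np.flatnonzero(cross)
        np.add.at(counts, (x[sel], y[sel]), 1)
    return counts


def transition_matrix(counts: np.ndarray) -> np.ndarray:
    """Row-normalize a count matrix; all-zero rows become absorbing self-loops."""
    C = np.asarray(counts, dtype=float)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise ValueError("counts must be square")
    if np.any(C < 0):
        raise ValueError("counts must be nonnegative")
    rows = C.sum(axis=1)
    zero = rows == 0
    if np.any(zero):
        warnings.warn(
            f"{int(zero.sum())} state(s) have no outgoing counts; "
            "treated as absorbing self-loops")
    T = np.where(zero[:, None], np.eye(C.shape[0]), C / np.where(zero, 1.0, rows)[:, None])
    return T


def _closed_classes(T: np.ndarray) -> list[np.ndarray]:
    adj = (T > 0).astype(np.int8)
    n_comp, comp = connected_components(adj, directed=True, connection="strong")
    closed = []
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        outside = np.setdiff1d(np.arange(T.shape[0]), members, assume_unique=True)
        if outside.size == 0 or not np.any(T[np.ix_(members, outside)] > 0):
            closed.append(members)
    return closed


def stationary_distribution(T: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Stationary distribution pi with pi = pi T, supported on the closed class.

    Transient states receive zero mass.  A chain with more than one closed
    communicating class has no unique stationary distribution and is rejected.
    """
    T = np.asarray(T, dtype=float)
    closed = _closed_classes(T)
    if len(closed) != 1:
        raise ValueError(
            "reducible chain with multiple closed communicating classes: "
            + "; ".join(str(list(c[:10])) for c in closed)
        )
    members = closed[0]
    Tc = T[np.ix_(members, members)]
    try:
        vals, vecs = scipy.linalg.eig(Tc, left=True, right=False)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi_c = np.real(vecs[:, i])
        pi_c = np.abs(pi_c)
        pi_c = pi_c / pi_c.sum()
    except Exception:
        pi_c = None
    if pi_c is None or np.linalg.norm(pi_c @ Tc - pi_c, np.inf) > 1e-8:
        # power-iteration fallback
        pi_c = np.full(len(members), 1.0 / len(members))
        for _ in range(100000):
            nxt = pi_c @ Tc
            if np.linalg.norm(nxt - pi_c, np.inf) < tol:
                pi_c = nxt
                break
            pi_c = nxt
        pi_c = pi_c / pi_c.sum()
    pi = np.zeros(T.shape[0])
    pi[members] = pi_c
    return pi


def _sorted_eigenvalues(T: np.ndarray, imag_tol: float = 1e-8) -> np.ndarray:
    vals = scipy.linalg.eigvals(T)
    if np.any(np.abs(vals.imag) > imag_tol):
        warnings.warn(
            "complex transition-matrix eigenvalues beyond tolerance; "
            f"max |imag| = {np.abs(vals.imag).max():.3e}; using real parts")
    real = vals.real
    return real[np.argsort(-np.abs(real))]


def implied_timescales(
    label_trajs: list[np.ndarray],
    lag_list_ns: list[float],
    n_timescales: int = 5,
    min_residence_frames: int = 1,
    dt_ps: float = 20.0,
    n_states: int | None = None,
) -> ImpliedTimescaleCurve:
    """Implied timescales t_i = -tau / ln(lambda_i) over a scan of lag times.

    Eigenvalues within 1e-12 of 1 are the stationary processes and are
    excluded; eigenvalues >= 1 (no decay observed) yield +inf, nonpositive
    eigenvalues yield NaN.
    """
    lag_ns = np.asarray(lag_list_ns, dtype=float)
    frames = lag_ns * 1000.0 / dt_ps
    lag_frames = np.rint(frames).astype(int)
    if np.any(np.abs(frames - lag_frames) > 1e-9) or np.any(lag_frames < 1):
        raise ValueError("every lag must be a positive whole number of frames")
    out = np.full((len(lag_ns), n_timescales), np.nan)
    for i, (tau_ns, tau_f) in enumerate(zip(lag_ns, lag_frames)):
        counts = count_transitions(label_trajs, int(tau_f), min_residence_frames,
                                   n_states=n_states)
        T = transition_matrix(counts)
        vals = _sorted_eigenvalues(T)
        vals = vals[np.abs(vals) < 1.0 - 1e-12][:n_timescales]
        for j, lam in enumerate(vals):
            if lam <= 0.0:
                out[i, j] = np.nan
            else:
                out[i, j] = -tau_ns / np.log(lam)
    return ImpliedTimescaleCurve(lags_ns=lag_ns, timescales_ns=out)


def choose_lag(curve: ImpliedTimescaleCurve, rel_tol: float = 0.10) -> float:
    """Select the working lag from an implied-timescale curve.

    The plateau is the first lag whose slowest timescale changes by less than
    ``rel_tol`` (relative) to the next grid lag; the returned lag is one grid
    step beyond the plateau, mirroring the practice of building the final model
    safely past the leveling-off point.
    """
    lags = curve.lags_ns
    if len(lags) < 3:
        raise ValueError("need at least 3 lags to detect a plateau")
    slow = curve.slowest()
    for p in range(len(lags) - 1):
        a, b = slow[p], slow[p + 1]
        if np.isfinite(a) and np.isfinite(b) and a > 0 and \
                abs(b - a) / abs(a) < rel_tol:
            return float(lags[p + 1])
    raise ValueError(
        "no implied-timescale plateau found over the scanned lags; "
        "extend the lag list to longer lag times")
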