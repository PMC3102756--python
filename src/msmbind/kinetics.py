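"""Kinetic and thermodynamic readouts of a Markov state model.

Mean first passage times are obtained from the linear system
``X_f = 0`` on the target set and ``X_i = tau + sum_j T_ij X_j`` elsewhere,
with bootstrap error bars from trajectory resampling.  The binding free energy
follows the bound/free population-ratio method for a single ligand in a
simulation box,

    dG = -RT ln[ (1 - a_free) / (a_free^2 * c0 / c_std) ],

where ``a_free`` is the fraction of free species, ``c0 = 1/(N_A V_box)`` the
box ligand concentration and ``c_std = 1 mol/L``; the experimental reference
is ``dG = RT ln(Kd / c_std)``.  The association timescale is the
pseudo-first-order half-life ``tau_1/2 = ln 2 / (k_on c0)``.

Transition-path analysis uses the forward committor and the net reactive flux
``F_ij = max(0, f_ij - f_ji)`` with ``f_ij = pi_i (1 - q_i) T_ij q_j``; the top
pathways are peeled off by repeatedly extracting the bottleneck (widest)
source->sink path and subtracting its flux, a greedy backtracking
decomposition.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .featurize import superpose

__all__ = [
    "GAS_CONSTANT_KCAL",
    "MFPTResult",
    "TPTResult",
    "mfpt",
    "bootstrap_statistic",
    "binding_free_energy",
    "dG_from_Kd",
    "association_timescale",
    "committor",
    "net_flux",
    "top_flux_paths",
    "transition_event_features",
    "free_energy_surface",
    "medoid_conformations",
]

#: Gas constant in kcal/(mol K).
GAS_CONSTANT_KCAL = 1.987e-3
#: Standard concentration (mol/L).
C_STANDARD = 1.0


@dataclass
class MFPTResult:
    value_us: float
    source_set: tuple[int, ...]
    target_set: tuple[int, ...]
    per_source_us: dict[int, float]
    lag_ns: float
    bootstrap_mean_us: float | None = None
    bootstrap_sd_us: float | None = None


@dataclass
class TPTResult:
    q_plus: np.ndarray
    flux: np.ndarray
    total_flux: float
    paths: list[tuple[list[int], float, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Mean first passage times
# ---------------------------------------------------------------------------

def _reach_mask(T: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """States from which the target set is reachable (graph search on T > 0)."""
    n = T.shape[0]
    rev = (T > 0).T
    seen = np.zeros(n, dtype=bool)
    stack = list(targets)
    seen[targets] = True
    while stack:
        j = stack.pop()
        nbrs = np.flatnonzero(rev[j] & ~seen)
        seen[nbrs] = True
        stack.extend(nbrs.tolist())
    return seen


def mfpt(
    T: np.ndarray,
    lag_ns: float,
    source_set: Sequence[int],
    target_set: Sequence[int],
    weights: np.ndarray | None = None,
    pi: np.ndarray | None = None,
) -> MFPTResult:
    """Stationary-weighted mean first passage time (microseconds) between state sets.

    Sources overlapping the target contribute zero.  Sources from which the
    target is unreachable yield an infinite MFPT (flagged per source).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    targets = np.unique(np.asarray(target_set, dtype=np.int64))
    sources = np.unique(np.asarray(source_set, dtype=np.int64))
    if targets.size == 0 or sources.size == 0:
        raise ValueError("source and target sets must be nonempty")

    reachable = _reach_mask(T, targets)
    x = np.full(n, np.inf)
    x[targets] = 0.0
    free = np.flatnonzero(reachable & ~np.isin(np.arange(n), targets))
    if free.size:
        A = np.eye(free.size) - T[np.ix_(free, free)]
        b = np.full(free.size, lag_ns)  # target states contribute X = 0
        x[free] = np.linalg.solve(A, b)
    unreachable_sources = [int(s) for s in sources if not reachable[s]]
    if unreachable_sources:
        warnings.warn(f"target unreachable from sources {unreachable_sources}; MFPT infinite")

    per_source = {int(s): float(x[s] / 1000.0) for s in sources}
    eff_sources = np.setdiff1d(sources, targets, assume_unique=True)
    if eff_sources.size == 0:
        value = 0.0
    else:
        if weights is None:
            if pi is None:
                from .msm import stationary_distribution
                pi = stationary_distribution(T)
            weights = pi[eff_sources]
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != eff_sources.size:
            raise ValueError("weights must match the (target-excluded) source set")
        if w.sum() <= 0:
            w = np.ones_like(w)
        w = w / w.sum()
        value = float(np.dot(w, x[eff_sources]) / 1000.0)
    return MFPTResult(
        value_us=value,
        source_set=tuple(int(s) for s in sources),
        target_set=tuple(int(t) for t in targets),
        per_source_us=per_source,
        lag_ns=float(lag_ns),
    )


def bootstrap_statistic(
    trajectories: Sequence,
    pipeline_statistic: Callable[[list], float],
    n_boot: int = 100,
    n_draw: int | None = None,
    seed: int = 0,
) -> tuple[float, float]:
    """Bootstrap a statistic over trajectory resamples (with replacement)."""
    trajs = list(trajectories)
    if len(trajs) < 2:
        raise ValueError("need at least 2 trajectories to bootstrap")
    n_draw = n_draw if n_draw is not None else len(trajs)
    rng = np.random.default_rng(seed)
    values = []
    n_failed = 0
    for _ in range(n_boot):
        idx = rng.integers(0, len(trajs), size=n_draw)
        try:
            values.append(float(pipeline_statistic([trajs[i] for i in idx])))
        except Exception as exc:  # noqa: BLE001 - resample-level robustness
            n_failed += 1
            warnings.warn(f"statistic failed on a bootstrap resample: {exc}")
    if n_failed:
        warnings.warn(f"{n_failed}/{n_boot} bootstrap resamples failed and were skipped")
    if not values:
        raise RuntimeError("statistic failed on every bootstrap resample")
    arr = np.asarray(values)
    return float(arr.mean()), float(arr.std(ddof=0))


# ---------------------------------------------------------------------------
# Thermodynamics
# ---------------------------------------------------------------------------

def binding_free_energy(alpha_free: float, c0_molar: float, T_K: float) -> float:
    """Binding free energy (kcal/mol) from the free-species fraction.

    dG = -RT ln[(1 - alpha_free) / (alpha_free^2 c0 / c_std)] for a single
    protein and single ligand in a box of ligand concentration ``c0``.
    """
    if not 0.0 < alpha_free < 1.0:
        raise ValueError("alpha_free must lie strictly between 0 and 1")
    if c0_molar <= 0 or T_K <= 0:
        raise ValueError("concentration and temperature must be positive")
    ratio = (1.0 - alpha_free) / (alpha_free ** 2 * c0_molar / C_STANDARD)
    return -GAS_CONSTANT_KCAL * T_K * np.log(ratio)


def dG_from_Kd(Kd_molar: float, T_K: float) -> float:
    """Free energy (kcal/mol) of binding from a dissociation constant."""
    if Kd_molar <= 0 or T_K <= 0:
        raise ValueError("Kd and temperature must be positive")
    return GAS_CONSTANT_KCAL * T_K * np.log(Kd_molar / C_STANDARD)


def association_timescale(k_on: float, c0_molar: float) -> float:
    """Pseudo-first-order association half-life tau_1/2 = ln 2 / (k_on c0), seconds."""
    if k_on <= 0 or c0_molar <= 0:
        raise ValueError("k_on and c0 must be positive")
    return float(np.log(2.0) / (k_on * c0_molar))


# ---------------------------------------------------------------------------
# Transition path theory
# ---------------------------------------------------------------------------

def committor(T: np.ndarray, source_set: Sequence[int], sink_set: Sequence[int]) -> np.ndarray:
    """Forward committor: probability of reaching the sink before the source."""
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A = np.unique(np.asarray(source_set, dtype=np.int64))
    B = np.unique(np.asarray(sink_set, dtype=np.int64))
    if A.size == 0 or B.size == 0:
        raise ValueError("source and sink sets must be nonempty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink sets must be disjoint")
    q = np.zeros(n)
    q[B] = 1.0
    inter = np.setdiff1d(np.arange(n), np.union1d(A, B), assume_unique=False)
    if inter.size:
        no_path = ~_reach_mask(T, B)
        if np.any(no_path[inter]):
            warnings.warn(
                f"states {np.flatnonzero(no_path)[:10].tolist()} cannot reach the sink; "
                "their committor is 0")
        solve = inter[~no_path[inter]]
        if solve.size:
            M = np.eye(solve.size) - T[np.ix_(solve, solve)]
            rhs = T[np.ix_(solve, B)].sum(axis=1)
            q[solve] = np.linalg.solve(M, rhs)
    return np.clip(q, 0.0, 1.0)


def backward_committor(
    T: np.ndarray,
    pi: np.ndarray,
    source_set: Sequence[int],
    sink_set: Sequence[int],
) -> np.ndarray:
    """Probability of having last come from the source rather than the sink.

    Computed as the forward committor of the time-reversed chain
    ``T~_ij = pi_j T_ji / pi_i`` (no detailed balance assumed; for a
    reversible chain this reduces to ``1 - q_plus``).
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    safe = np.where(pi > 0, pi, 1.0)
    Trev = (T.T * pi[None, :]) / safe[:, None]
    # zero-population states get a uniform dummy row; they carry no flux anyway
    rows = Trev.sum(axis=1)
    bad = rows <= 0
    if np.any(bad):
        Trev[bad] = 1.0 / T.shape[0]
    else:
        Trev = Trev / rows[:, None]
    return committor(Trev, sink_set, source_set)


def net_flux(
    T: np.ndarray,
    pi: np.ndarray,
    q_plus: np.ndarray,
    source_set: Sequence[int],
    sink_set: Sequence[int],
) -> tuple[np.ndarray, float]:
    """Net reactive flux matrix and total source->sink flux (probability / lag).

    Gross flux f_ij = pi_i q^-_i T_ij q^+_j with the backward committor q^-
    from the time-reversed chain; the net flux F_ij = max(0, f_ij - f_ji) is
    conserved at every intermediate state for general (non-reversible) chains.
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    q = np.asarray(q_plus, dtype=float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        q_minus = backward_committor(T, pi, source_set, sink_set)
    gross = pi[:, None] * q_minus[:, None] * T * q[None, :]
    np.fill_diagonal(gross, 0.0)
    F = np.clip(gross - gross.T, 0.0, None)
    A = np.unique(np.asarray(source_set, dtype=np.int64))
    total = float(F[A, :].sum() - F[:, A].sum())
    return F, total


def _widest_path(F: np.ndarray, sources: np.ndarray, sinks: np.ndarray):
    """Maximum-bottleneck path from any source to any sink (max-min Dijkstra)."""
    n = F.shape[0]
    best = np.zeros(n)
    prev = np.full(n, -1, dtype=np.int64)
    heap = []
    for s in sources:
        best[s] = np.inf
        heapq.heappush(heap, (-np.inf, int(s)))
    visited = np.zeros(n, dtype=bool)
    sink_mask = np.zeros(n, dtype=bool)
    sink_mask[sinks] = True
    while heap:
        negw, u = heapq.heappop(heap)
        if visited[u]:
            continue
        visited[u] = True
        if sink_mask[u]:
            path = [u]
            while prev[path[-1]] != -1:
                path.append(int(prev[path[-1]]))
            if path[-1] not in set(int(s) for s in sources):
                pass
            return list(reversed(path)), float(best[u])
        for v in np.flatnonzero(F[u] > 0):
            w = min(best[u], F[u, v])
            if w > best[v]:
                best[v] = w
                prev[v] = u
                heapq.heappush(heap, (-w, int(v)))
    return None, 0.0


def top_flux_paths(
    F: np.ndarray,
    source_set: Sequence[int],
    sink_set: Sequence[int],
    n_paths: int = 10,
    total_flux: float | None = None,
) -> list[tuple[list[int], float, float]]:
    """Greedy bottleneck decomposition of the net flux into its top pathways.

    Repeatedly extracts the source->sink path with the largest minimum edge
    flux, records it, and subtracts its bottleneck flux from every edge on it.
    Returns (path, flux, fraction-of-total) triples; fewer paths are returned
    if the flux is exhausted early.
    """
    F = np.array(F, dtype=float, copy=True)
    A = np.unique(np.asarray(source_set, dtype=np.int64))
    B = np.unique(np.asarray(sink_set, dtype=np.int64))
    if total_flux is None:
        total_flux = float(F[A, :].sum() - F[:, A].sum())
    out = []
    for _ in range(n_paths):
        path, bottleneck = _widest_path(F, A, B)
        if path is None or bottleneck <= 0:
            break
        for u, v in zip(path[:-1], path[1:]):
            F[u, v] -= bottleneck
        frac = bottleneck / total_flux if total_flux > 0 else np.nan
        out.append((path, bottleneck, frac))
    return out


# ---------------------------------------------------------------------------
# Transition-event localization, free-energy surfaces, medoids
# ---------------------------------------------------------------------------

def transition_event_features(
    label_traj: np.ndarray,
    features: np.ndarray,
    from_state: int,
    to_state: int,
    min_residence_frames: int = 1,
) -> np.ndarray:
    """Feature vectors at frames where a persistent from->to transition occurs.

    An event is a frame t with label[t-1] == from_state, label[t] == to_state,
    and the destination persisting for at least ``min_residence_frames``
    (windows truncated by the trajectory end are rejected).
    """
    labels = np.asarray(label_traj)
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if feats.shape[0] != labels.shape[0]:
        feats = feats.T
    if feats.shape[0] != labels.shape[0]:
        raise ValueError("features and labels differ in length")
    from .msm import forward_run_lengths
    runs = forward_run_lengths(labels)
    n = len(labels)
    t = np.flatnonzero((labels[:-1] == from_state) & (labels[1:] == to_state)) + 1
    ok = (runs[t] >= min_residence_frames) & (t + min_residence_frames <= n)
    return feats[t[ok]]


def free_energy_surface(
    x: np.ndarray,
    y: np.ndarray,
    bin_x: float,
    bin_y: float,
    kT: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Binned 2-D free-energy surface F = -kT ln(n / n_max); empty bins are NaN.

    Returns (x_edges, y_edges, F) with the deepest bin at exactly 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("x and y must be nonempty and matched")
    if bin_x <= 0 or bin_y <= 0:
        raise ValueError("bin sizes must be positive")
    def edges(v, width):
        lo = np.floor(v.min() / width) * width
        hi = np.ceil(v.max() / width) * width
        if hi <= lo:
            hi = lo + width
        return np.arange(lo, hi + 0.5 * width, width)
    xe, ye = edges(x, bin_x), edges(y, bin_y)
    H, xe, ye = np.histogram2d(x, y, bins=[xe, ye])
    with np.errstate(divide="ignore"):
        F = -kT * np.log(H / H.max())
    F[H == 0] = np.nan
    return xe, ye, F


def medoid_conformations(
    coords: np.ndarray,
    n: int = 3,
    max_exact: int = 2000,
    seed: int = 0,
) -> np.ndarray:
    """Indices of the ``n`` most central conformations by mean pairwise RMSD.

    Each pair is compared after optimal rigid superposition.  Exact all-pairs
    evaluation for up to ``max_exact`` conformations; larger samples are
    subsampled with a fixed seed.  Ties break to the lowest index.
    """
    X = np.asarray(coords, dtype=float)
    if X.ndim != 3 or X.shape[-1] != 3:
        raise ValueError("coords must have shape (n_conf, n_atoms, 3)")
    m = X.shape[0]
    if m < n:
        raise ValueError("need at least n conformations")
    idx = np.arange(m)
    if m > max_exact:
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(m, size=max_exact, replace=False))
    sub = X[idx]
    k = len(idx)
    D = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            _, r = superpose(sub[j], sub[i])
            D[i, j] = D[j, i] = r
    mean_r = D.sum(axis=1) / (k - 1)
    order = np.lexsort((np.arange(k), mean_r))
    return idx[order[:n]]
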