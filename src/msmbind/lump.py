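"""Super-level-set hierarchical lumping of microstates into macrostates.

Macrostates are grown from high-density regions downward.  Microstates are
ranked by their empirical density (fraction of all frames they hold); a density
level L selects the minimal prefix of that ranking whose cumulative density
reaches L.  Iterating levels from the densest prefix outward, each connected
component of the (symmetrized) transition graph restricted to the level set is
spectral-clustered; clusters containing no previously assigned microstate seed
new macrostates, while unassigned microstates falling in a cluster that already
contains assigned ones are absorbed by the macrostate of their most strongly
coupled assigned neighbor.  Seeds created at denser levels are therefore never
dissolved later, only grown.  High- and low-resolution (bound-regime /
diffusing-regime) microstates are lumped separately with their own level
ladders and the macrostate label ranges are kept disjoint.

The number of clusters in a spectral split is chosen by the largest gap among
the leading eigenvalues of the symmetrically normalized affinity (capped at 5
per connected component); a strongly mixing component therefore stays whole.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

__all__ = [
    "DensityLevels",
    "MacroMapping",
    "state_densities",
    "super_level_sets",
    "spectral_split",
    "shc_lump",
    "aggregate_counts",
]

DEFAULT_LEVELS_HIGH = (0.50, 0.55, 0.60, 0.65, 0.70, 0.75, 0.80, 0.85, 0.90, 0.95, 0.99)
DEFAULT_LEVELS_LOW = (0.4, 0.95)


@dataclass(frozen=True)
class DensityLevels:
    """Density-level ladders for the two regimes (strictly increasing, in (0, 1])."""

    levels_high: tuple[float, ...] = DEFAULT_LEVELS_HIGH
    levels_low: tuple[float, ...] = DEFAULT_LEVELS_LOW

    def __post_init__(self) -> None:
        for name, levels in (("levels_high", self.levels_high),
                             ("levels_low", self.levels_low)):
            arr = np.asarray(levels, dtype=float)
            if arr.size == 0 or np.any(arr <= 0) or np.any(arr > 1):
                raise ValueError(f"{name} must lie in (0, 1]")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")


@dataclass
class MacroMapping:
    """Surjective microstate -> macrostate map with populations and seed levels."""

    micro_to_macro: np.ndarray
    M: int
    macro_populations: np.ndarray
    level_of_seed: np.ndarray

    def __post_init__(self) -> None:
        m2m = np.asarray(self.micro_to_macro, dtype=np.int64)
        if m2m.min(initial=0) < 0 or (self.M and m2m.max(initial=-1) >= self.M):
            raise ValueError("micro_to_macro entries must lie in [0, M)")
        if self.M and len(np.unique(m2m)) != self.M:
            raise ValueError("micro_to_macro must be surjective onto [0, M)")
        self.micro_to_macro = m2m


def state_densities(frame_counts: np.ndarray) -> np.ndarray:
    """Per-microstate density: fraction of all frames assigned to each state."""
    c = np.asarray(frame_counts, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("no frames assigned")
    return c / total


def super_level_sets(densities: np.ndarray, levels) -> list[np.ndarray]:
    """Nested super-level sets: minimal descending-density prefixes reaching each level."""
    d = np.asarray(densities, dtype=float)
    order = np.lexsort((np.arange(len(d)), -d))  # descending density, ties by index
    csum = np.cumsum(d[order])
    out = []
    for L in np.asarray(levels, dtype=float):
        k = int(np.searchsorted(csum, L - 1e-12) + 1)
        k = min(k, len(d))
        out.append(np.sort(order[:k]))
    return out


def _split_eigengap(A: np.ndarray, max_clusters: int, seed: int) -> np.ndarray:
    """Eigengap-selected spectral partition of a connected affinity matrix."""
    m = A.shape[0]
    if m == 1:
        return np.zeros(1, dtype=np.int64)
    deg = A.sum(axis=1)
    deg = np.where(deg > 0, deg, 1.0)
    dinv = 1.0 / np.sqrt(deg)
    S = dinv[:, None] * A * dinv[None, :]
    vals, vecs = scipy.linalg.eigh(S)
    vals, vecs = vals[::-1], vecs[:, ::-1]
    kmax = min(max_clusters, m)
    # gap below the k-th eigenvalue supports k clusters; negative eigenvalues
    # carry no block structure and are treated as zero, and the sequence is
    # padded with zero so that k = m (all states kinetically distinct) is
    # expressible for small components
    lead = np.clip(vals[:kmax], 0.0, None)
    padded = np.append(lead, 0.0)
    gaps = padded[:kmax] - padded[1:kmax + 1]
    k = int(np.argmax(gaps)) + 1
    if k == 1:
        return np.zeros(m, dtype=np.int64)
    emb = vecs[:, :k] * dinv[:, None]
    norms = np.linalg.norm(emb, axis=1, keepdims=True)
    emb = emb / np.where(norms > 0, norms, 1.0)
    km = KMeans(n_clusters=k, random_state=seed, n_init=10)
    labels = km.fit_predict(emb)
    # deterministic relabeling by lowest member index
    firsts = [np.flatnonzero(labels == c)[0] for c in range(k)]
    order = np.argsort(firsts)
    remap = np.empty(k, dtype=np.int64)
    remap[order] = np.arange(k)
    return remap[labels]


def spectral_split(
    subgraph: np.ndarray,
    max_clusters: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Cluster the states of a (sub)graph given by a nonnegative affinity matrix.

    Disconnected components are separated first; within each component the
    cluster count is chosen by the largest eigengap (capped at ``max_clusters``).
    Returns dense cluster labels ordered by lowest member index.
    """
    A = np.asarray(subgraph, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("subgraph must be a square matrix")
    if A.shape[0] == 0:
        raise ValueError("subgraph is empty")
    A = 0.5 * (A + A.T)
    n_comp, comp = connected_components((A > 0).astype(np.int8), directed=False)
    labels = np.full(A.shape[0], -1, dtype=np.int64)
    nxt = 0
    for c in range(n_comp):
        members = np.flatnonzero(comp == c)
        sub = _split_eigengap(A[np.ix_(members, members)], max_clusters, seed)
        labels[members] = sub + nxt
        nxt += sub.max() + 1
    # densify in order of lowest member index
    firsts = [np.flatnonzero(labels == c)[0] for c in range(nxt)]
    order = np.argsort(firsts)
    remap = np.empty(nxt, dtype=np.int64)
    remap[order] = np.arange(nxt)
    return remap[labels]


def _lump_regime(
    Csym: np.ndarray,
    densities: np.ndarray,
    levels,
    max_clusters: int,
    seed: int,
) -> tuple[np.ndarray, dict[int, float]]:
    """Run the hierarchical lumping for one regime; returns macro labels and
    the density level at which each macro was seeded."""
    K = len(densities)
    assign = np.full(K, -1, dtype=np.int64)
    seed_level: dict[int, float] = {}
    n_macro = 0
    total = densities.sum()
    dnorm = densities / total if total > 0 else densities
    for L, level_set in zip(levels, super_level_sets(dnorm, levels)):
        sub = Csym[np.ix_(level_set, level_set)]
        n_comp, comp = connected_components((sub > 0).astype(np.int8), directed=False)
        for c in range(n_comp):
            members = level_set[np.flatnonzero(comp == c)]
            if np.all(assign[members] == -1):
                clusters = spectral_split(Csym[np.ix_(members, members)],
                                          max_clusters, seed)
                for cl in range(clusters.max() + 1):
                    sel = members[clusters == cl]
                    assign[sel] = n_macro
                    seed_level[n_macro] = float(L)
                    n_macro += 1
            else:
                clusters = spectral_split(Csym[np.ix_(members, members)],
                                          max_clusters, seed)
                for cl in range(clusters.max() + 1):
                    sel = members[clusters == cl]
                    if np.all(assign[sel] == -1):
                        assign[sel] = n_macro
                        seed_level[n_macro] = float(L)
                        n_macro += 1
                    else:
                        n_macro, _ = _attach(sel, assign, Csym, dnorm, n_macro,
                                             seed_level, L, members)
    # after the final level: absorb leftovers by strongest coupling
    n_macro, _ = _attach(np.flatnonzero(assign == -1), assign, Csym, dnorm,
                         n_macro, seed_level, float(levels[-1]), None,
                         allow_isolated=True)
    return assign, seed_level


def _attach(
    pending: np.ndarray,
    assign: np.ndarray,
    Csym: np.ndarray,
    densities: np.ndarray,
    n_macro: int,
    seed_level: dict[int, float],
    level: float,
    scope: np.ndarray | None,
    allow_isolated: bool = False,
) -> tuple[int, np.ndarray]:
    """Attach unassigned states to their strongest-coupled assigned neighbor.

    Iterates until no further attachment is possible; processes states in
    descending density (ties by index).  With ``allow_isolated`` states with no
    coupling to any assigned state become singleton macrostates.
    """
    pending = [int(s) for s in pending if assign[s] == -1]
    pending.sort(key=lambda s: (-densities[s], s))
    progress = True
    while pending and progress:
        progress = False
        remaining = []
        for s in pending:
            cols = np.flatnonzero(assign >= 0) if scope is None else \
                scope[assign[scope] >= 0]
            if cols.size and Csym[s, cols].max() > 0:
                # aggregate the symmetrized counts per candidate macrostate
                # (the state's total kinetic contact with each); exact ties --
                # transitional states touching two macrostates equally -- break
                # to the larger per-capita affinity (coupling per unit of
                # macrostate frame mass), then to the lowest macro index
                macros = np.unique(assign[cols])
                total = np.array([Csym[s, cols[assign[cols] == m]].sum()
                                  for m in macros], dtype=float)
                mass = np.array([max(densities[assign == m].sum(), 1e-300)
                                 for m in macros])
                best = np.flatnonzero(total == total.max())
                if best.size > 1:
                    pc = total[best] / mass[best]
                    best = best[pc == pc.max()]
                assign[s] = int(macros[best[0]])
                progress = True
            else:
                remaining.append(s)
        pending = remaining
    for s in pending:
        if allow_isolated:
            warnings.warn(f"isolated zero-coupling microstate {s} becomes its own macrostate")
            assign[s] = n_macro
            seed_level[n_macro] = level
            n_macro += 1
    return n_macro, assign


def shc_lump(
    counts: np.ndarray,
    frame_counts: np.ndarray,
    regime_of_state: np.ndarray,
    levels: DensityLevels | None = None,
    pi: np.ndarray | None = None,
    max_clusters: int = 5,
    seed: int = 0,
) -> MacroMapping:
    """Lump microstates into macrostates, handling the two regimes separately.

    ``counts`` is the microstate transition count matrix, ``frame_counts`` the
    per-microstate frame totals defining densities, ``regime_of_state`` the
    per-microstate regime flag ('high-res' / 'low-res').  Macro populations are
    aggregated from ``pi`` when given (stationary microstate distribution), and
    from frame densities otherwise.
    """
    levels = levels or DensityLevels()
    C = np.asarray(counts, dtype=float)
    K = C.shape[0]
    if len(frame_counts) != K or len(regime_of_state) != K:
        raise ValueError("counts, frame_counts and regime_of_state sizes disagree")
    Csym = C + C.T
    dens = state_densities(frame_counts)
    regime_of_state = np.asarray(regime_of_state)

    micro_to_macro = np.full(K, -1, dtype=np.int64)
    level_of_seed: list[float] = []
    offset = 0
    for regime, lv in (("high-res", levels.levels_high), ("low-res", levels.levels_low)):
        members = np.flatnonzero(regime_of_state == regime)
        if members.size == 0:
            continue
        sub_assign, seed_lv = _lump_regime(
            Csym[np.ix_(members, members)], dens[members], lv, max_clusters, seed)
        micro_to_macro[members] = sub_assign + offset
        for m in range(sub_assign.max() + 1):
            level_of_seed.append(seed_lv[m])
        offset += sub_assign.max() + 1

    M = offset
    weights = np.asarray(pi, dtype=float) if pi is not None else dens
    pops = np.zeros(M)
    np.add.at(pops, micro_to_macro, weights)
    pops = pops / pops.sum()
    return MacroMapping(
        micro_to_macro=micro_to_macro,
        M=M,
        macro_populations=pops,
        level_of_seed=np.asarray(level_of_seed),
    )


def aggregate_counts(counts: np.ndarray, mapping: MacroMapping) -> np.ndarray:
    """Aggregate a microstate count matrix onto macrostates (totals preserved)."""
    C = np.asarray(counts)
    m2m = mapping.micro_to_macro
    K, M = len(m2m), mapping.M
    Z = np.zeros((K, M), dtype=C.dtype)
    Z[np.arange(K), m2m] = 1
    return Z.T @ C @ Z
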