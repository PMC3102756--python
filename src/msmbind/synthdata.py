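"""Synthetic trajectory generation with planted ground truth.

The MD dataset this analysis is designed for is not publicly deposited, so every
downstream stage is exercised against synthetic data whose answers are known
exactly: discrete-state Markov chains with Gaussian feature emissions
(:class:`PlantedChainSpec`), a Metropolis Monte Carlo sampler on a multi-well
toy free-energy landscape (:class:`ToyLandscape`), and synthetic point-set
structures whose hinge dihedrals are constructed to prescribed values
(:func:`build_toy_structure`).

The default scenario :func:`lao_like` plants the state architecture of a
two-lobed receptor binding a small ligand: an open unbound state, a partially
closed encounter complex that gates binding, a dominant closed bound state,
and a weakly populated mis-bound state in which the ligand sticks outside the
binding site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .featurize import FeatureTrajectory, ResidueGroups, hinge_dihedral, wrap_angle

__all__ = [
    "FEATURE_COLUMNS",
    "PlantedChainSpec",
    "ToyLandscape",
    "sample_chain",
    "emit_features",
    "generate_dataset",
    "simulate_landscape",
    "build_toy_structure",
    "lao_like",
    "write_labels",
    "read_labels",
]

#: Emission columns of a planted chain, in order.
FEATURE_COLUMNS = ("opening_deg", "twisting_deg", "min_dist_A",
                   "lig_com_x", "lig_com_y", "lig_com_z")


@dataclass(frozen=True)
class PlantedChainSpec:
    """A hidden Markov chain over metastable basins with Gaussian emissions.

    ``transition_matrix`` holds per-frame jump probabilities (row-stochastic).
    ``emission_means``/``emission_sds`` have one row per state over the columns
    in :data:`FEATURE_COLUMNS`; the ligand--site distance is derived as the norm
    of the emitted ligand COM so the two are always consistent.
    """

    n_states: int
    transition_matrix: np.ndarray
    emission_means: np.ndarray
    emission_sds: np.ndarray
    dt_ps: float = 20.0
    seed: int = 0
    state_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        object.__setattr__(self, "transition_matrix", T)
        if T.ndim != 2 or T.shape[0] != T.shape[1] or T.shape[0] != self.n_states:
            raise ValueError("transition_matrix must be square with n_states rows")
        if np.any(T < 0):
            row = int(np.argwhere(T < 0)[0, 0])
            raise ValueError(f"transition_matrix row {row} has a negative entry")
        sums = T.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > 1e-12)
        if bad.size:
            raise ValueError(
                f"transition_matrix row {bad[0]} sums to {sums[bad[0]]!r}, not 1"
            )
        mu = np.atleast_2d(np.asarray(self.emission_means, dtype=float))
        sd = np.atleast_2d(np.asarray(self.emission_sds, dtype=float))
        if mu.shape != (self.n_states, len(FEATURE_COLUMNS)):
            raise ValueError(
                f"emission_means must have shape ({self.n_states}, {len(FEATURE_COLUMNS)})"
            )
        if sd.shape != mu.shape:
            raise ValueError("emission_sds must match emission_means in shape")
        if np.any(sd < 0):
            raise ValueError("emission_sds must be nonnegative")
        object.__setattr__(self, "emission_means", mu)
        object.__setattr__(self, "emission_sds", sd)

    @property
    def stationary(self) -> np.ndarray:
        """Analytic stationary distribution of the planted matrix."""
        vals, vecs = np.linalg.eig(self.transition_matrix.T)
        i = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, i])
        pi = np.abs(pi)
        return pi / pi.sum()


def sample_chain(
    spec: PlantedChainSpec,
    n_steps: int,
    start: int,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample a label sequence of length ``n_steps`` from the planted chain."""
    if not 0 <= start < spec.n_states:
        raise ValueError(f"start state {start} out of range [0, {spec.n_states})")
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cum = np.cumsum(spec.transition_matrix, axis=1)
    cum[:, -1] = 1.0  # guard against round-off in searchsorted
    u = rng.random(n_steps - 1)
    labels = np.empty(n_steps, dtype=np.int64)
    labels[0] = start
    s = start
    for t in range(1, n_steps):
        s = int(np.searchsorted(cum[s], u[t - 1], side="right"))
        labels[t] = s
    return labels


def emit_features(
    labels: np.ndarray,
    spec: PlantedChainSpec,
    rng: np.random.Generator | None = None,
) -> FeatureTrajectory:
    """Draw one feature record per label from the state's diagonal Gaussian.

    Distance-like columns are clipped at zero to respect the nonnegativity of
    physical distances (the planted means sit many standard deviations above
    zero, so the clipped mass is negligible).
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size and (labels.min() < 0 or labels.max() >= spec.n_states):
        raise ValueError("label out of range for this chain spec")
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    n = labels.size
    mu = spec.emission_means[labels] if n else np.empty((0, len(FEATURE_COLUMNS)))
    sd = spec.emission_sds[labels] if n else np.empty((0, len(FEATURE_COLUMNS)))
    x = mu + sd * rng.standard_normal((n, len(FEATURE_COLUMNS)))
    com = x[:, 3:6]
    return FeatureTrajectory(
        opening_deg=wrap_angle(x[:, 0]) if n else np.empty(0),
        twisting_deg=wrap_angle(x[:, 1]) if n else np.empty(0),
        site_distance_A=np.linalg.norm(com, axis=1),
        min_dist_A=np.clip(x[:, 2], 0.0, None),
        ligand_com=com,
        dt_ps=spec.dt_ps,
    )


def generate_dataset(
    spec: PlantedChainSpec,
    n_traj: int,
    n_frames: int,
    seed: int | None = None,
) -> tuple[list[FeatureTrajectory], list[np.ndarray]]:
    """Generate an equilibrium dataset of independent trajectories.

    One random generator per trajectory is derived from ``(seed, index)`` so
    generation is reproducible and order-independent.  Start states are drawn
    from the planted stationary distribution, emulating a converged dataset.
    """
    base = spec.seed if seed is None else seed
    pi = spec.stationary
    trajs: list[FeatureTrajectory] = []
    labels: list[np.ndarray] = []
    for i in range(n_traj):
        rng = np.random.default_rng([base, i])
        start = int(rng.choice(spec.n_states, p=pi))
        lab = sample_chain(spec, n_frames, start, rng=rng)
        trajs.append(emit_features(lab, spec, rng=rng))
        labels.append(lab)
    return trajs, labels


# ---------------------------------------------------------------------------
# Toy free-energy landscape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyLandscape:
    """Gaussian-mixture free-energy landscape U(x) = -kT ln sum_b w_b N(x; c_b, sd_b).

    Coordinates are (opening deg, twisting deg, ligand displacement A).
    """

    basins: tuple[tuple[np.ndarray, np.ndarray, float], ...]
    kT: float = 1.0
    step_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.basins:
            raise ValueError("landscape needs at least one basin")
        norm = []
        for center, sd, weight in self.basins:
            c = np.asarray(center, float).reshape(3)
            s = np.asarray(sd, float).reshape(3)
            if np.any(s <= 0):
                raise ValueError("basin standard deviations must be positive")
            if weight <= 0:
                raise ValueError("basin weights must be positive")
            norm.append((c, s, float(weight)))
        object.__setattr__(self, "basins", tuple(norm))
        if self.kT <= 0 or self.step_sd <= 0:
            raise ValueError("kT and step_sd must be positive")

    def potential(self, x: np.ndarray) -> float:
        x = np.asarray(x, float).reshape(3)
        dens = 0.0
        for c, s, w in self.basins:
            z = (x - c) / s
            dens += w * np.exp(-0.5 * np.dot(z, z)) / np.prod(s)
        # mixture density is strictly positive, so U is finite everywhere
        return -self.kT * np.log(dens)


def simulate_landscape(
    landscape: ToyLandscape,
    n_steps: int,
    start_point: np.ndarray,
    seed: int | None = None,
) -> FeatureTrajectory:
    """Metropolis Monte Carlo on the toy landscape with isotropic Gaussian proposals.

    Records the position after every proposal (accepted or retained), plus the
    start point, giving ``n_steps + 1`` frames.  The third coordinate is mapped
    to the ligand COM x-component; the site distance is its absolute value.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    rng = np.random.default_rng(landscape.seed if seed is None else seed)
    x = np.asarray(start_point, float).reshape(3).copy()
    out = np.empty((n_steps + 1, 3))
    out[0] = x
    u_cur = landscape.potential(x)
    steps = rng.standard_normal((n_steps, 3)) * landscape.step_sd
    accept_u = rng.random(n_steps)
    for t in range(n_steps):
        prop = x + steps[t]
        u_prop = landscape.potential(prop)
        if u_prop <= u_cur or accept_u[t] < np.exp(-(u_prop - u_cur) / landscape.kT):
            x, u_cur = prop, u_prop
        out[t + 1] = x
    com = np.zeros((n_steps + 1, 3))
    com[:, 0] = out[:, 2]
    dist = np.abs(out[:, 2])
    return FeatureTrajectory(
        opening_deg=wrap_angle(out[:, 0]),
        twisting_deg=wrap_angle(out[:, 1]),
        site_distance_A=dist,
        min_dist_A=dist,
        ligand_com=com,
        dt_ps=20.0,
    )


# ---------------------------------------------------------------------------
# Toy structures with prescribed hinge dihedrals
# ---------------------------------------------------------------------------

# toy hinge scaffold: opening hinge along +z, twisting hinge along +x (Angstrom)
_TOY_OH1 = np.array([0.0, 0.0, 0.0])
_TOY_OH2 = np.array([0.0, 0.0, 2.0])
_TOY_TH1 = np.array([1.0, 0.0, 0.0])
_TOY_TH2 = np.array([3.0, 0.0, 0.0])

TOY_GROUPS = ResidueGroups(
    opening_outer_A=frozenset({1}),
    opening_outer_B=frozenset({4}),
    opening_hinge1=frozenset({2}),
    opening_hinge2=frozenset({3}),
    twisting_hinge1=frozenset({5}),
    twisting_hinge2=frozenset({6}),
)


def _toy_outer_points(opening_deg: float, twisting_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Exact analytic placement of the two outer (lobe) centroids.

    The dihedral about the z hinge is the azimuth difference of the outer
    points in the x-y plane; the dihedral about the x hinge is their azimuth
    difference in the y-z plane.  Placing lobe A at azimuths
    (90 - opening/2, -twisting/2) and lobe B at (90 + opening/2, +twisting/2)
    realizes both requested dihedrals exactly, for any angles strictly inside
    (-180, 180); the exact +/-180 folds are geometrically degenerate on this
    scaffold.
    """
    if abs(opening_deg) >= 180.0 - 1e-9 or abs(twisting_deg) >= 180.0 - 1e-9:
        raise ValueError("toy scaffold supports angles strictly inside (-180, 180)")

    def point(az_z_deg: float, az_x_deg: float, radius: float) -> np.ndarray:
        a1 = np.radians(az_z_deg)
        a2 = np.radians(az_x_deg)
        # azimuth in x-y plane = az_z; azimuth of (y, z) in y-z plane = az_x
        return radius * np.array([np.cos(a1), np.sin(a1), np.sin(a1) * np.tan(a2)])

    a = point(90.0 - opening_deg / 2.0, -twisting_deg / 2.0, 2.0)
    b = point(90.0 + opening_deg / 2.0, +twisting_deg / 2.0, 1.0)
    return a, b


@dataclass
class PointStructure:
    """Synthetic point-set structure (duck-types the AtomArray fields the
    featurization reads, but keeps float64 coordinates)."""

    coord: np.ndarray
    res_id: np.ndarray
    atom_name: np.ndarray
    res_name: np.ndarray
    chain_id: np.ndarray
    hetero: np.ndarray

    def array_length(self) -> int:
        return self.coord.shape[0]


def build_toy_structure(
    opening_deg: float,
    twisting_deg: float,
    ligand_position: np.ndarray | None = None,
) -> tuple[PointStructure, ResidueGroups]:
    """Build a synthetic point-set structure realizing the requested hinge angles.

    Returns a :class:`PointStructure` with one C-alpha pseudo-atom per residue
    group (so the group centroids are the scaffold points themselves) plus a
    single-particle ligand, together with the matching toy
    :class:`ResidueGroups`.  Feeding the result through ``opening_twisting``
    with the (0, 0) toy structure as reference recovers the requested angles.
    """
    if not (-180.0 < opening_deg <= 180.0 and -180.0 < twisting_deg <= 180.0):
        raise ValueError("angles must lie in (-180, 180]")
    a, b = _toy_outer_points(float(opening_deg), float(twisting_deg))
    positions = [a, _TOY_OH1, _TOY_OH2, b, _TOY_TH1, _TOY_TH2]
    lig = np.array([5.0, 5.0, 5.0]) if ligand_position is None else np.asarray(
        ligand_position, float).reshape(3)
    n = len(positions)
    return PointStructure(
        coord=np.vstack(positions + [lig]).astype(np.float64),
        res_id=np.array(list(range(1, n + 1)) + [900]),
        atom_name=np.array(["CA"] * n + ["C1"]),
        res_name=np.array(["GLY"] * n + ["LIG"]),
        chain_id=np.array(["A"] * n + ["L"]),
        hetero=np.array([False] * n + [True]),
    ), TOY_GROUPS


# ---------------------------------------------------------------------------
# The default "lao-like" scenario
# ---------------------------------------------------------------------------

#: basin order of the default scenario
LAO_LIKE_STATES = ("unbound", "encounter", "bound", "misbound")


def lao_like(include_misbound: bool = True, seed: int = 20260921) -> PlantedChainSpec:
    """Four-basin planted scenario emulating two-lobed receptor/ligand binding.

    Basins (opening deg, twisting deg, min protein-ligand distance A, ligand
    COM A): open unbound far from the site, a partially closed encounter
    complex that gates binding, the dominant closed bound state, and a
    mis-bound state with the ligand attached outside the site.  Per-frame
    (20 ps) jump probabilities make the bound state dominant (~84.9% of the
    stationary mass) with the encounter complex as the obligatory gateway.
    With ``include_misbound=False`` the well-separated three-basin variant used
    for lumping-recovery checks is returned.
    """
    P = np.array([
        #  U      E      B      M
        [0.993, 0.006, 0.000, 0.001],
        [0.004, 0.976, 0.020, 0.000],
        [0.000, 0.002, 0.998, 0.000],
        [0.006, 0.000, 0.000, 0.994],
    ])
    means = np.array([
        # open  twist  mind   com_x  com_y  com_z
        [40.0, -25.0, 25.0,  28.0,  10.0,   0.0],
        [25.0, -15.0,  2.0,   3.7,   1.5,   0.0],
        [0.0,    0.0,  1.0,   1.0,   0.0,   0.0],
        [38.0,  -22.0, 2.0,   0.0,  -6.0,   0.0],
    ])
    sds = np.array([
        [4.0, 4.0, 2.0, 1.5, 1.5, 1.5],
        [2.5, 2.5, 0.4, 0.3, 0.3, 0.3],
        [3.0, 3.0, 0.25, 0.3, 0.3, 0.3],
        [2.0, 2.0, 0.4, 0.3, 0.3, 0.3],
    ])
    names = LAO_LIKE_STATES
    if not include_misbound:
        P = P[:3, :3].copy()
        P[0, 0] += 0.001   # reroute the dropped mis-bound probability
        means, sds, names = means[:3], sds[:3], names[:3]
    return PlantedChainSpec(
        n_states=len(names),
        transition_matrix=P,
        emission_means=means,
        emission_sds=sds,
        dt_ps=20.0,
        seed=seed,
        state_names=names,
    )


# ---------------------------------------------------------------------------
# Plain-text I/O
# ---------------------------------------------------------------------------

def write_labels(labels: np.ndarray, path: str | Path) -> None:
    np.savetxt(path, np.asarray(labels, dtype=np.int64), fmt="%d")


def read_labels(path: str | Path) -> np.ndarray:
    return np.loadtxt(path, dtype=np.int64).reshape(-1)
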