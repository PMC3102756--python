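"""Microstate discretization: k-centers clustering and two-regime product states.

Conformations are discretized by two independent geometric clusterings -- one on
the protein hinge angles, one on the ligand position -- combined as product
states.  Frames are split into two regimes by the minimum protein--ligand
heavy-atom distance: while the ligand is in contact (<= 5 A) a high-resolution
clustering is used (ligand metric: heavy-atom coordinates); while it diffuses
freely a much coarser clustering on the ligand COM suffices.  The two regimes
occupy disjoint microstate label ranges.

The clustering primitive is the greedy farthest-point (Gonzalez) k-centers
algorithm, which guarantees a covering radius within a factor two of optimal
and, with fixed seed index and lowest-index tie-breaking, is fully
deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .featurize import FeatureTrajectory

__all__ = [
    "ClusterModel",
    "MicrostateAssignment",
    "k_centers",
    "product_assign",
    "two_regime_assign",
]

REGIME_HIGH = "high-res"
REGIME_LOW = "low-res"


@dataclass
class ClusterModel:
    """Result of a k-centers clustering: centers are actual data points."""

    centers: np.ndarray
    center_indices: np.ndarray
    metric: str
    radius: float
    seed_index: int = 0

    def assign(self, points: np.ndarray) -> np.ndarray:
        """Nearest-center labels for new points (ties to the lowest center index)."""
        pts = np.asarray(points, float)
        d = _pairwise_sq(pts, self.centers)
        return np.argmin(d, axis=1)


@dataclass
class MicrostateAssignment:
    """Dense per-frame microstate labels with regime and product provenance."""

    labels: list[np.ndarray]
    regime: list[np.ndarray]          # per-frame regime strings
    K: int
    provenance: list[tuple[int, int, str]] = field(default_factory=list)
    models: dict = field(default_factory=dict)

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate(self.labels) if self.labels else np.empty(0, dtype=np.int64)

    def frame_counts(self) -> np.ndarray:
        return np.bincount(self.concatenated, minlength=self.K)

    def regime_of_state(self) -> np.ndarray:
        """Regime flag per microstate (uniform by construction)."""
        return np.array([p[2] for p in self.provenance])


def _pairwise_sq(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    return ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)


def k_centers(
    points: np.ndarray,
    k: int,
    metric: str = "euclidean",
    seed_index: int = 0,
) -> tuple[ClusterModel, np.ndarray]:
    """Greedy farthest-point (Gonzalez) k-centers clustering.

    Center 0 is ``points[seed_index]``; each subsequent center is the point
    farthest from all chosen centers (ties to the lowest index).  Returns the
    model (with covering radius) and the per-point nearest-center labels.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim == 1:
        pts = pts[:, None]
    n = pts.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if not 0 <= seed_index < n:
        raise ValueError("seed_index out of range")
    center_idx = np.empty(k, dtype=np.int64)
    center_idx[0] = seed_index
    d2 = ((pts - pts[seed_index]) ** 2).sum(axis=1)
    labels = np.zeros(n, dtype=np.int64)
    for i in range(1, k):
        far = int(np.argmax(d2))
        if d2[far] == 0.0:
            raise ValueError(
                f"k={k} exceeds the number of distinct points ({i} found)"
            )
        center_idx[i] = far
        nd2 = ((pts - pts[far]) ** 2).sum(axis=1)
        closer = nd2 < d2
        labels[closer] = i
        d2 = np.where(closer, nd2, d2)
    radius = float(np.sqrt(np.max(d2))) if n else 0.0
    model = ClusterModel(
        centers=pts[center_idx].copy(),
        center_indices=center_idx,
        metric=metric,
        radius=radius,
        seed_index=seed_index,
    )
    return model, labels


def product_assign(
    protein_labels: np.ndarray,
    ligand_labels: np.ndarray,
    n_ligand_clusters: int | None = None,
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Combine independent protein and ligand clusterings as product states.

    Raw combined labels are ``protein * N + ligand``; empty combinations are
    dropped and labels densified.  Returns the dense labels and, per dense
    label, the originating (protein, ligand) cluster pair.
    """
    p = np.asarray(protein_labels, dtype=np.int64)
    l = np.asarray(ligand_labels, dtype=np.int64)
    if p.shape != l.shape:
        raise ValueError("protein and ligand label arrays differ in length")
    N = int(n_ligand_clusters) if n_ligand_clusters is not None else int(l.max(initial=-1)) + 1
    raw = p * N + l
    uniq, dense = np.unique(raw, return_inverse=True)
    pairs = [(int(r // N), int(r % N)) for r in uniq]
    return dense.astype(np.int64), pairs


def _cap_k(points: np.ndarray, k: int, what: str) -> int:
    n_distinct = np.unique(np.atleast_2d(points), axis=0).shape[0]
    if k > n_distinct:
        warnings.warn(
            f"{what}: requested {k} clusters but only {n_distinct} distinct points; "
            f"using {n_distinct}", stacklevel=3)
        return n_distinct
    return k


def two_regime_assign(
    trajs: list[FeatureTrajectory] | FeatureTrajectory,
    threshold_A: float = 5.0,
    k_protein_high: int = 50,
    k_ligand_high: int = 5000,
    k_protein_low: int = 10,
    k_ligand_low: int = 100,
    seed_index: int = 0,
) -> MicrostateAssignment:
    """Discretize trajectories with the two-regime product-state scheme.

    Frames with minimum protein--ligand distance <= ``threshold_A`` are
    clustered at high resolution (protein: hinge angles; ligand: heavy-atom
    coordinates, falling back to the COM for single-particle ligands); the
    remaining freely diffusing frames at low resolution (ligand: COM).  Cluster
    counts are capped at the number of distinct points.  The label spaces of
    the two regimes are disjoint; empty product combinations are dropped.
    """
    if isinstance(trajs, FeatureTrajectory):
        trajs = [trajs]
    if not trajs:
        raise ValueError("no trajectories given")
    lengths = [t.n_frames for t in trajs]
    angles = np.concatenate([
        np.column_stack([t.opening_deg, t.twisting_deg]) for t in trajs])
    if all(t.ligand_coords is not None for t in trajs):
        lig_high_feats = np.concatenate([
            t.ligand_coords.reshape(t.n_frames, -1) for t in trajs])
    else:
        lig_high_feats = np.concatenate([t.ligand_com for t in trajs])
    lig_com = np.concatenate([t.ligand_com for t in trajs])
    min_dist = np.concatenate([t.min_dist_A for t in trajs])
    n = len(min_dist)

    high = min_dist <= threshold_A
    low = ~high
    combined = np.full(n, -1, dtype=np.int64)
    provenance: list[tuple[int, int, str]] = []
    models: dict = {}
    offset = 0
    for mask, regime, kp, kl, lig_feats, lig_metric in (
        (high, REGIME_HIGH, k_protein_high, k_ligand_high, lig_high_feats,
         "euclidean-ligand-heavy"),
        (low, REGIME_LOW, k_protein_low, k_ligand_low, lig_com,
         "euclidean-ligand-com"),
    ):
        if not mask.any():
            warnings.warn(f"no frames in the {regime} regime; proceeding without it")
            continue
        kp_eff = _cap_k(angles[mask], kp, f"{regime} protein clustering")
        kl_eff = _cap_k(lig_feats[mask], kl, f"{regime} ligand clustering")
        pmodel, plabels = k_centers(angles[mask], kp_eff, "euclidean-angles", seed_index)
        lmodel, llabels = k_centers(lig_feats[mask], kl_eff, lig_metric, seed_index)
        dense, pairs = product_assign(plabels, llabels, kl_eff)
        combined[mask] = dense + offset
        provenance.extend((pp, ll, regime) for pp, ll in pairs)
        models[regime] = {"protein": pmodel, "ligand": lmodel}
        offset += len(pairs)

    K = offset
    regimes = np.where(high, REGIME_HIGH, REGIME_LOW)
    out_labels, out_regimes = [], []
    pos = 0
    for ln in lengths:
        out_labels.append(combined[pos:pos + ln].copy())
        out_regimes.append(regimes[pos:pos + ln].copy())
        pos += ln
    return MicrostateAssignment(
        labels=out_labels, regime=out_regimes, K=K,
        provenance=provenance, models=models,
    )
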