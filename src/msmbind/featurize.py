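"""Reaction coordinates for two-lobed (periplasmic-binding-protein-like) receptors.

The slow degrees of freedom of a PBP-type receptor closing around its ligand are
captured by two inter-lobe hinge dihedrals -- an *opening* angle and a *twisting*
angle -- plus the position of the ligand relative to the binding site.  Each angle
is the signed dihedral between two planes that share two hinge points; every plane
point is the centroid of a group of C-alpha atoms.  Angles are reported relative to
a reference (holo) structure, which therefore scores (0, 0) by construction.

Structures are represented as :class:`biotite.structure.AtomArray`; the low-level
geometry operates on plain coordinate arrays so it can be tested in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ResidueGroups",
    "BindingSiteDef",
    "FeatureTrajectory",
    "DegenerateGeometryError",
    "hinge_dihedral",
    "opening_twisting",
    "ligand_site_distance",
    "min_heavy_distance",
    "rotational_acf",
    "ca_rmsd",
    "superpose",
    "load_pdb",
    "group_centroid",
]


class DegenerateGeometryError(ValueError):
    """Raised when a dihedral is requested for collinear/degenerate points."""


def _ids(*ranges: tuple[int, int]) -> frozenset[int]:
    out: set[int] = set()
    for lo, hi in ranges:
        out.update(range(lo, hi + 1))
    return frozenset(out)


@dataclass(frozen=True)
class ResidueGroups:
    """C-alpha residue groups defining the opening and twisting hinge dihedrals.

    Defaults are the LAO-protein lobe and hinge definitions: lobe I
    (residues 6-88 and 195-227) and lobe II (92-185) are the outer points shared
    by both angles; the opening angle hinges on residues 162-168 / 121-127 and
    the twisting angle on 83-88 & 194-199 / 92-97 & 156-161.
    """

    opening_outer_A: frozenset[int] = field(default_factory=lambda: _ids((6, 88), (195, 227)))
    opening_outer_B: frozenset[int] = field(default_factory=lambda: _ids((92, 185)))
    opening_hinge1: frozenset[int] = field(default_factory=lambda: _ids((162, 168)))
    opening_hinge2: frozenset[int] = field(default_factory=lambda: _ids((121, 127)))
    twisting_hinge1: frozenset[int] = field(default_factory=lambda: _ids((83, 88), (194, 199)))
    twisting_hinge2: frozenset[int] = field(default_factory=lambda: _ids((92, 97), (156, 161)))

    def __post_init__(self) -> None:
        for angle, groups in (
            ("opening", (self.opening_outer_A, self.opening_outer_B,
                         self.opening_hinge1, self.opening_hinge2)),
            ("twisting", (self.opening_outer_A, self.opening_outer_B,
                          self.twisting_hinge1, self.twisting_hinge2)),
        ):
            for g in groups:
                if not g:
                    raise ValueError(f"empty residue group in {angle} definition")
            for i, a in enumerate(groups):
                for b in groups[i + 1:]:
                    if a & b:
                        raise ValueError(
                            f"residue groups of the {angle} angle overlap: {sorted(a & b)[:5]}..."
                        )


#: Binding-site C-alpha residues (within 8 A of the ligand COM in the holo form).
DEFAULT_BINDING_SITE: frozenset[int] = _ids(
    (9, 15), (17, 19), (30, 30), (50, 53), (55, 56), (67, 74), (77, 77),
    (83, 83), (88, 88), (90, 92), (117, 124), (141, 143), (159, 162),
    (164, 164), (190, 191), (194, 196),
)


@dataclass(frozen=True)
class BindingSiteDef:
    """Residue ids whose C-alpha centroid defines the binding-site location."""

    residue_ids: frozenset[int] = field(default_factory=lambda: DEFAULT_BINDING_SITE)

    def __post_init__(self) -> None:
        if not self.residue_ids:
            raise ValueError("binding site residue set is empty")


# ---------------------------------------------------------------------------
# FeatureTrajectory
# ---------------------------------------------------------------------------

_TSV_COLUMNS = ["frame", "opening_deg", "twisting_deg", "site_distance_A",
                "min_dist_A", "lig_com_x", "lig_com_y", "lig_com_z"]


@dataclass
class FeatureTrajectory:
    """Per-frame reaction coordinates at a fixed frame spacing.

    Arrays are one entry per frame: hinge angles in degrees (wrapped to
    (-180, 180]), ligand--binding-site centroid distance and minimum
    protein--ligand heavy-atom distance in Angstrom, and the ligand center of
    mass in the protein-aligned frame.  ``ligand_coords`` optionally carries the
    full per-frame ligand heavy-atom coordinates (n_frames, n_atoms, 3); when
    absent the ligand is treated as a single particle at its COM.
    """

    opening_deg: np.ndarray
    twisting_deg: np.ndarray
    site_distance_A: np.ndarray
    min_dist_A: np.ndarray
    ligand_com: np.ndarray
    dt_ps: float = 20.0
    ligand_coords: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.opening_deg = np.asarray(self.opening_deg, dtype=float)
        self.twisting_deg = np.asarray(self.twisting_deg, dtype=float)
        self.site_distance_A = np.asarray(self.site_distance_A, dtype=float)
        self.min_dist_A = np.asarray(self.min_dist_A, dtype=float)
        self.ligand_com = np.asarray(self.ligand_com, dtype=float).reshape(-1, 3)
        n = len(self.opening_deg)
        for name in ("twisting_deg", "site_distance_A", "min_dist_A"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"length mismatch: {name}")
        if len(self.ligand_com) != n:
            raise ValueError("length mismatch: ligand_com")
        if n and (np.min(self.site_distance_A) < 0 or np.min(self.min_dist_A) < 0):
            raise ValueError("distances must be nonnegative")
        for name in ("opening_deg", "twisting_deg"):
            a = getattr(self, name)
            if n and (np.max(a) > 180.0 or np.min(a) <= -180.0):
                raise ValueError(f"{name} must lie in (-180, 180]")
        if self.ligand_coords is not None:
            self.ligand_coords = np.asarray(self.ligand_coords, dtype=float)
            if self.ligand_coords.shape[0] != n or self.ligand_coords.shape[-1] != 3:
                raise ValueError("ligand_coords must have shape (n_frames, n_atoms, 3)")

    @property
    def n_frames(self) -> int:
        return len(self.opening_deg)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "opening_deg": self.opening_deg,
            "twisting_deg": self.twisting_deg,
            "site_distance_A": self.site_distance_A,
            "min_dist_A": self.min_dist_A,
            "lig_com_x": self.ligand_com[:, 0],
            "lig_com_y": self.ligand_com[:, 1],
            "lig_com_z": self.ligand_com[:, 2],
        })

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")

    @classmethod
    def from_tsv(cls, path: str | Path, dt_ps: float = 20.0) -> "FeatureTrajectory":
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _TSV_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"feature table {path} lacks columns {missing}")
        return cls(
            opening_deg=df["opening_deg"].to_numpy(),
            twisting_deg=df["twisting_deg"].to_numpy(),
            site_distance_A=df["site_distance_A"].to_numpy(),
            min_dist_A=df["min_dist_A"].to_numpy(),
            ligand_com=df[["lig_com_x", "lig_com_y", "lig_com_z"]].to_numpy(),
            dt_ps=dt_ps,
        )


# ---------------------------------------------------------------------------
# Geometry primitives
# ---------------------------------------------------------------------------

def wrap_angle(a):
    """Wrap angle(s) in degrees to the interval (-180, 180]."""
    a = np.asarray(a, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def hinge_dihedral(p_outer_a, p_hinge1, p_hinge2, p_outer_b, *, tol: float = 1e-10) -> float:
    """Signed dihedral (degrees) of the planes (A,h1,h2) and (B,h1,h2).

    The sign follows the right-hand rule about the hinge axis oriented from
    ``p_hinge1`` to ``p_hinge2``: rotating the B half-plane by +90 degrees about
    that axis from the coplanar (same-side) configuration yields +90.
    """
    a = np.asarray(p_outer_a, float)
    h1 = np.asarray(p_hinge1, float)
    h2 = np.asarray(p_hinge2, float)
    b = np.asarray(p_outer_b, float)

    axis = h2 - h1
    norm_axis = np.linalg.norm(axis)
    if norm_axis < tol:
        raise DegenerateGeometryError("hinge points coincide")
    u = axis / norm_axis
    va = a - h1
    vb = b - h1
    # components of the outer points perpendicular to the hinge axis
    pa = va - np.dot(va, u) * u
    pb = vb - np.dot(vb, u) * u
    if np.linalg.norm(pa) < tol or np.linalg.norm(pb) < tol:
        raise DegenerateGeometryError("outer point collinear with the hinge axis")
    x = np.dot(pa, pb)
    y = np.dot(np.cross(pa, pb), u)
    return wrap_angle(np.degrees(np.arctan2(y, x)))


def load_pdb(path: str | Path, model: int = 1) -> struc.AtomArray:
    """Read a single model from a PDB file as a biotite AtomArray."""
    pdb = PDBFile.read(str(path))
    atoms = pdb.get_structure(model=model)
    if atoms.array_length() == 0:
        raise ValueError(f"no atoms read from {path}")
    if "ins_code" in atoms.get_annotation_categories():
        if np.any(np.char.strip(atoms.ins_code.astype(str)) != ""):
            raise ValueError("structures with insertion codes are not supported")
    return atoms


def _ca_mask(atoms: struc.AtomArray) -> np.ndarray:
    return (atoms.atom_name == "CA") & ~atoms.hetero


def group_centroid(atoms: struc.AtomArray, residue_ids: Iterable[int]) -> np.ndarray:
    """Centroid of the C-alpha atoms of the given residue ids (unit masses)."""
    rid = np.asarray(sorted(residue_ids))
    mask = _ca_mask(atoms) & np.isin(atoms.res_id, rid)
    present = np.unique(atoms.res_id[mask])
    missing = sorted(set(rid.tolist()) - set(present.tolist()))
    if missing:
        raise ValueError(f"missing C-alpha atoms for residues {missing}")
    return atoms.coord[mask].mean(axis=0)


def _raw_angles(atoms: struc.AtomArray, groups: ResidueGroups) -> tuple[float, float]:
    com_a = group_centroid(atoms, groups.opening_outer_A)
    com_b = group_centroid(atoms, groups.opening_outer_B)
    opening = hinge_dihedral(
        com_a,
        group_centroid(atoms, groups.opening_hinge1),
        group_centroid(atoms, groups.opening_hinge2),
        com_b,
    )
    twisting = hinge_dihedral(
        com_a,
        group_centroid(atoms, groups.twisting_hinge1),
        group_centroid(atoms, groups.twisting_hinge2),
        com_b,
    )
    return opening, twisting


def opening_twisting(
    atoms: struc.AtomArray,
    groups: ResidueGroups,
    reference: struc.AtomArray,
) -> tuple[float, float]:
    """Opening and twisting hinge angles relative to a reference structure.

    Raw inter-lobe dihedrals are computed from group centroids on both
    structures and the reference values are subtracted, so
    ``opening_twisting(ref, groups, ref) == (0.0, 0.0)`` exactly.
    """
    o, t = _raw_angles(atoms, groups)
    o_ref, t_ref = _raw_angles(reference, groups)
    return wrap_angle(o - o_ref), wrap_angle(t - t_ref)


def ligand_site_distance(
    protein: struc.AtomArray | np.ndarray,
    ligand_coords: np.ndarray,
    site: BindingSiteDef | None = None,
) -> float:
    """Distance (A) between the ligand heavy-atom COM and the site C-alpha centroid.

    ``protein`` may be an AtomArray (the site centroid is computed from
    ``site.residue_ids``) or a precomputed 3-vector site centroid.
    """
    lig = np.asarray(ligand_coords, float).reshape(-1, 3)
    if lig.shape[0] == 0:
        raise ValueError("ligand has no heavy atoms")
    if isinstance(protein, np.ndarray):
        site_com = np.asarray(protein, float).reshape(3)
    else:
        site_com = group_centroid(protein, (site or BindingSiteDef()).residue_ids)
    return float(np.linalg.norm(lig.mean(axis=0) - site_com))


def min_heavy_distance(protein_coords: np.ndarray, ligand_coords: np.ndarray) -> float:
    """Minimum over all protein-heavy x ligand-heavy atom pair distances (A)."""
    p = np.asarray(protein_coords, float).reshape(-1, 3)
    l = np.asarray(ligand_coords, float).reshape(-1, 3)
    if p.shape[0] == 0 or l.shape[0] == 0:
        raise ValueError("empty atom selection")
    return float(cdist(p, l).min())


def rotational_acf(orientation_vectors: np.ndarray, max_lag_frames: int) -> np.ndarray:
    """Orientation autocorrelation C(t) = <u(s) . u(s+t)> for t = 0..max_lag."""
    u = np.asarray(orientation_vectors, float)
    if u.ndim != 2 or u.shape[1] != 3 or u.shape[0] < 2:
        raise ValueError("need at least 2 orientation 3-vectors")
    norms = np.linalg.norm(u, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ValueError("orientation vectors must be unit-normalized (within 1e-6)")
    n = u.shape[0]
    max_lag_frames = int(max_lag_frames)
    if max_lag_frames >= n:
        raise ValueError("max_lag_frames must be smaller than the trajectory length")
    out = np.empty(max_lag_frames + 1)
    for t in range(max_lag_frames + 1):
        out[t] = np.mean(np.sum(u[: n - t] * u[t:], axis=1))
    return out


def superpose(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimally superpose ``mobile`` onto ``target`` (proper rotation + translation).

    Returns the transformed mobile coordinates and the resulting RMSD (A).
    """
    mob = np.asarray(mobile, float).reshape(-1, 3)
    tgt = np.asarray(target, float).reshape(-1, 3)
    if mob.shape != tgt.shape:
        raise ValueError(f"coordinate sets differ in shape: {mob.shape} vs {tgt.shape}")
    mc = mob - mob.mean(axis=0)
    tc = tgt.mean(axis=0)
    rot, _ = Rotation.align_vectors(tgt - tc, mc)
    moved = rot.apply(mc) + tc
    rmsd = float(np.sqrt(np.mean(np.sum((moved - tgt) ** 2, axis=1))))
    return moved, rmsd


def ca_rmsd(
    struct_a: struc.AtomArray | np.ndarray,
    struct_b: struc.AtomArray | np.ndarray,
    selection: Iterable[int] | None = None,
) -> float:
    """C-alpha RMSD (A) after optimal rigid superposition.

    Accepts AtomArrays (C-alpha atoms extracted, optionally restricted to
    ``selection`` residue ids) or plain matched coordinate arrays.
    """
    def _coords(s):
        if isinstance(s, np.ndarray):
            return np.asarray(s, float).reshape(-1, 3)
        mask = _ca_mask(s)
        if selection is not None:
            mask &= np.isin(s.res_id, np.asarray(sorted(selection)))
        return s.coord[mask]

    a, b = _coords(struct_a), _coords(struct_b)
    if a.shape != b.shape:
        raise ValueError(f"matched C-alpha sets required: {a.shape} vs {b.shape}")
    _, rmsd = superpose(a, b)
    return rmsd
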