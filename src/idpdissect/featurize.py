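"""Trajectory featurization: exclusion-filtered Ca-Ca distances, intra-chain
contact maps, ligand-contact profiles, radius of gyration, min-max scaling.

Conventions (matching the analysis this package implements):

* residues are indexed 1-based and contiguous;
* the distance feature set excludes pairs (i, i+1) and (i, i+2), i.e. only
  pairs with sequence offset >= 3 enter the feature matrix;
* intra-chain contacts use a strict 8 A (0.8 nm) Ca-Ca cutoff;
* ligand contacts use a strict 0.6 nm minimum distance between any ligand
  heavy atom and the atoms of a residue (all residue atoms by default).
"""

from __future__ import annotations

import dataclasses

import numpy as np

CA_CONTACT_CUTOFF_NM = 0.8
LIGAND_CONTACT_CUTOFF_NM = 0.6


@dataclasses.dataclass
class AtomRecord:
    residue_index: int      # 1-based
    atom_name: str
    element: str
    mass: float
    is_ligand: bool = False


@dataclasses.dataclass
class EnsembleTrajectory:
    """Frames of labelled atoms.  ``coordinates`` is (frames, atoms, 3) nm."""

    atoms: list
    coordinates: np.ndarray
    frame_interval_ns: float | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must be (frames, atoms, 3)")
        if self.coordinates.shape[1] != len(self.atoms):
            raise ValueError("atom table and coordinate width disagree")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_residues(self) -> int:
        return max(a.residue_index for a in self.atoms if not a.is_ligand)

    def ca_indices(self) -> np.ndarray:
        """Atom index of the Ca of each protein residue, in residue order."""
        n_res = self.n_residues
        idx = np.full(n_res, -1, dtype=int)
        for i, a in enumerate(self.atoms):
            if not a.is_ligand and a.atom_name == "CA":
                if idx[a.residue_index - 1] != -1:
                    raise ValueError(
                        f"residue {a.residue_index} has more than one CA")
                idx[a.residue_index - 1] = i
        missing = np.nonzero(idx < 0)[0]
        if missing.size:
            raise ValueError(f"residue {missing[0] + 1} has no CA atom")
        return idx

    @classmethod
    def from_ca_coordinates(cls, coords: np.ndarray,
                            frame_interval_ns: float | None = None
                            ) -> "EnsembleTrajectory":
        """Build a Ca-only trajectory (synthetic mode)."""
        coords = np.asarray(coords, dtype=float)
        atoms = [AtomRecord(r + 1, "CA", "C", 12.011)
                 for r in range(coords.shape[1])]
        return cls(atoms=atoms, coordinates=coords,
                   frame_interval_ns=frame_interval_ns)

    @classmethod
    def from_mdtraj(cls, traj, ligand_resnames: tuple = ()) -> "EnsembleTrajectory":
        atoms = []
        for a in traj.topology.atoms:
            atoms.append(AtomRecord(
                residue_index=a.residue.index + 1,
                atom_name=a.name,
                element=a.element.symbol if a.element is not None else "X",
                mass=a.element.mass if a.element is not None else 0.0,
                is_ligand=a.residue.name in ligand_resnames))
        return cls(atoms=atoms, coordinates=np.asarray(traj.xyz, dtype=float))


@dataclasses.dataclass
class DistanceFeatureMatrix:
    values: np.ndarray          # (frames, P) nm
    pair_index: np.ndarray      # (P, 2) 1-based residue pairs, j - i >= 3


@dataclasses.dataclass
class ContactMap:
    probabilities: np.ndarray   # (n, n) symmetric, in [0, 1], diagonal 1
    cutoff_nm: float
    n_frames_used: int


@dataclasses.dataclass
class LigandContactProfile:
    probabilities: np.ndarray   # (n_residues,) in [0, 1]
    cutoff_nm: float


@dataclasses.dataclass
class MinMaxRecord:
    minimum: np.ndarray
    maximum: np.ndarray
    per_feature: bool


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def enumerate_feature_pairs(n_residues: int) -> np.ndarray:
    """Lexicographically ordered 1-based residue pairs (i, j) with j >= i+3.

    For n >= 2 the count is C(n,2) - (2n - 3); a 140-residue chain yields
    9453 pairs.
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    pairs = [(i, j)
             for i in range(1, n_residues + 1)
             for j in range(i + 3, n_residues + 1)]
    return np.asarray(pairs, dtype=int).reshape(-1, 2)


def compute_distance_features(traj: EnsembleTrajectory,
                              stride: int = 1) -> DistanceFeatureMatrix:
    """Euclidean Ca-Ca distances for all offset->=3 pairs, one row per
    retained frame (every ``stride``-th frame)."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    ca = traj.ca_indices()
    pairs = enumerate_feature_pairs(traj.n_residues)
    xyz = traj.coordinates[::stride][:, ca, :]
    if pairs.size == 0:
        return DistanceFeatureMatrix(np.empty((xyz.shape[0], 0)), pairs)
    diff = xyz[:, pairs[:, 0] - 1, :] - xyz[:, pairs[:, 1] - 1, :]
    return DistanceFeatureMatrix(np.linalg.norm(diff, axis=2), pairs)


def compute_contact_map(traj: EnsembleTrajectory,
                        frame_subset=None,
                        cutoff_nm: float = CA_CONTACT_CUTOFF_NM) -> ContactMap:
    """Per-pair fraction of frames with Ca-Ca distance strictly below the
    cutoff; symmetric, diagonal fixed at 1 by convention."""
    frames = (np.arange(traj.n_frames) if frame_subset is None
              else np.asarray(frame_subset, dtype=int))
    if frames.size == 0:
        raise ValueError("empty frame subset")
    ca = traj.ca_indices()
    xyz = traj.coordinates[frames][:, ca, :]
    d = np.linalg.norm(xyz[:, :, None, :] - xyz[:, None, :, :], axis=-1)
    prob = np.mean(d < cutoff_nm, axis=0)
    np.fill_diagonal(prob, 1.0)
    return ContactMap(probabilities=prob, cutoff_nm=cutoff_nm,
                      n_frames_used=int(frames.size))


def compute_ligand_contacts(traj: EnsembleTrajectory,
                            frame_subset=None,
                            cutoff_nm: float = LIGAND_CONTACT_CUTOFF_NM,
                            protein_heavy_only: bool = False
                            ) -> LigandContactProfile:
    """Per-residue fraction of frames in which the minimum distance between
    any ligand heavy atom and the residue's atoms is strictly below 0.6 nm.

    Ligand hydrogens never count (heavy-atom rule).  ``protein_heavy_only``
    restricts the protein side to heavy atoms too (default: all atoms).
    """
    lig_idx = np.array([i for i, a in enumerate(traj.atoms)
                        if a.is_ligand and a.element.upper() != "H"], dtype=int)
    if lig_idx.size == 0:
        raise ValueError("trajectory contains no ligand heavy atoms")
    frames = (np.arange(traj.n_frames) if frame_subset is None
              else np.asarray(frame_subset, dtype=int))
    if frames.size == 0:
        raise ValueError("empty frame subset")
    n_res = traj.n_residues
    probs = np.zeros(n_res)
    lig_xyz = traj.coordinates[frames][:, lig_idx, :]
    for r in range(1, n_res + 1):
        res_idx = np.array([i for i, a in enumerate(traj.atoms)
                            if not a.is_ligand and a.residue_index == r
                            and not (protein_heavy_only
                                     and a.element.upper() == "H")], dtype=int)
        res_xyz = traj.coordinates[frames][:, res_idx, :]
        d = np.linalg.norm(res_xyz[:, :, None, :] - lig_xyz[:, None, :, :],
                           axis=-1)
        probs[r - 1] = np.mean(d.min(axis=(1, 2)) < cutoff_nm)
    return LigandContactProfile(probabilities=probs, cutoff_nm=cutoff_nm)


def minmax_scale(matrix: np.ndarray, per_feature: bool = True
                 ) -> tuple[np.ndarray, MinMaxRecord]:
    """Scale to [0, 1] as (x - xmin) / (xmax - xmin); constant features map
    to 0 and their degenerate range is recorded for the inverse transform."""
    x = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("matrix must be finite")
    axis = 0 if per_feature else None
    lo = np.min(x, axis=axis, keepdims=per_feature)
    hi = np.max(x, axis=axis, keepdims=per_feature)
    span = hi - lo
    safe = np.where(span == 0, 1.0, span)
    scaled = (x - lo) / safe
    scaled = np.where(span == 0, 0.0, scaled)
    rec = MinMaxRecord(minimum=np.asarray(lo), maximum=np.asarray(hi),
                       per_feature=per_feature)
    return scaled, rec


def minmax_apply(matrix: np.ndarray, rec: MinMaxRecord,
                 clip: bool = False) -> np.ndarray:
    """Scale new data with previously recorded (min, max) statistics."""
    span = rec.maximum - rec.minimum
    safe = np.where(span == 0, 1.0, span)
    scaled = (np.asarray(matrix, dtype=float) - rec.minimum) / safe
    scaled = np.where(span == 0, 0.0, scaled)
    return np.clip(scaled, 0.0, 1.0) if clip else scaled


def minmax_invert(scaled: np.ndarray, rec: MinMaxRecord) -> np.ndarray:
    span = rec.maximum - rec.minimum
    return np.asarray(scaled, dtype=float) * span + rec.minimum


def compute_rg(traj: EnsembleTrajectory,
               mass_weighted: bool | None = None) -> np.ndarray:
    """Per-frame radius of gyration (nm).

    Uniform weights in Ca-only synthetic mode, mass-weighted when a full
    topology is present (override with ``mass_weighted``).
    """
    masses = np.array([a.mass for a in traj.atoms if not a.is_ligand])
    prot = np.array([i for i, a in enumerate(traj.atoms) if not a.is_ligand])
    xyz = traj.coordinates[:, prot, :]
    ca_only = all(a.atom_name == "CA" for a in traj.atoms if not a.is_ligand)
    if mass_weighted is None:
        mass_weighted = not ca_only
    w = masses if mass_weighted else np.ones_like(masses)
    w = w / w.sum()
    com = np.einsum("a,fax->fx", w, xyz)
    sq = np.einsum("a,fax->f", w, (xyz - com[:, None, :]) ** 2)
    return np.sqrt(sq)
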