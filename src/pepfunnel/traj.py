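"""Conformational metrics on coordinate ensembles.

Operations on an F-frame x A-atom x 3 coordinate ensemble: Kabsch
least-squares superposition and RMSD, per-residue RMSF, radius of gyration,
Shrake-Rupley solvent-accessible surface area, the dynamic cross-correlation
matrix (DCCM) of atomic displacements, and principal component analysis of
the 3N-coordinate covariance.

Conventions: all Angstrom; per-frame metrics are computed after aligning the
selection to the time-averaged structure (the mean is recomputed once after a
first alignment pass); residue numbering is preserved from the input so
selections can be written in the source structure's numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from ._scales import VDW_RADII

__all__ = [
    "TrajectoryEnsemble",
    "DccmMatrix",
    "PcaResult",
    "select",
    "superpose_rmsd",
    "align_ensemble",
    "rmsd_series",
    "rmsf",
    "radius_of_gyration",
    "rog_series",
    "sasa",
    "sasa_series",
    "dccm",
    "pca_project",
    "vdw_radii_for",
]


@dataclass
class TrajectoryEnsemble:
    """Frames x atoms x 3 coordinates with per-atom metadata."""

    coords: np.ndarray                 # (F, A, 3)
    residue_ids: np.ndarray            # (A,) 1-based, preserved from input
    residue_names: np.ndarray          # (A,) three-letter codes
    atom_names: np.ndarray             # (A,)
    chain_ids: np.ndarray | None = None
    elements: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (frames, atoms, 3)")
        if not np.isfinite(self.coords).all():
            raise ValueError("coordinates must be finite")
        a = self.coords.shape[1]
        for name in ("residue_ids", "residue_names", "atom_names"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != (a,):
                raise ValueError(f"{name} must have one entry per atom")
            setattr(self, name, arr)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def subset(self, mask: np.ndarray) -> "TrajectoryEnsemble":
        return TrajectoryEnsemble(
            coords=self.coords[:, mask],
            residue_ids=self.residue_ids[mask],
            residue_names=self.residue_names[mask],
            atom_names=self.atom_names[mask],
            chain_ids=None if self.chain_ids is None else self.chain_ids[mask],
            elements=None if self.elements is None else self.elements[mask],
        )

    @classmethod
    def from_pdb(cls, path) -> "TrajectoryEnsemble":
        """Read a multi-model PDB into an ensemble (biotite backend)."""
        import biotite.structure.io.pdb as pdb

        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
        return cls(
            coords=np.asarray(stack.coord, dtype=float),
            residue_ids=np.asarray(stack.res_id),
            residue_names=np.asarray(stack.res_name),
            atom_names=np.asarray(stack.atom_name),
            chain_ids=np.asarray(stack.chain_id),
            elements=np.asarray(stack.element),
        )

    def to_pdb(self, path) -> None:
        """Write as a multi-model PDB."""
        import biotite.structure as struc
        import biotite.structure.io.pdb as pdb

        a = self.n_atoms
        stack = struc.AtomArrayStack(self.n_frames, a)
        stack.coord = self.coords.astype(np.float32)
        stack.res_id = np.asarray(self.residue_ids)
        stack.res_name = np.asarray(self.residue_names, dtype="U5")
        stack.atom_name = np.asarray(self.atom_names, dtype="U6")
        stack.chain_id = (
            np.asarray(self.chain_ids, dtype="U4")
            if self.chain_ids is not None
            else np.full(a, "A", dtype="U4")
        )
        stack.element = (
            np.asarray(self.elements, dtype="U2")
            if self.elements is not None
            else np.array([n[:1] for n in self.atom_names], dtype="U2")
        )
        stack.hetero = np.zeros(a, dtype=bool)
        pdb_file = pdb.PDBFile()
        pdb_file.set_structure(stack)
        pdb_file.write(str(path))


def select(traj: TrajectoryEnsemble, expr: str) -> np.ndarray:
    """Boolean atom mask from a small selection language.

    Clauses (AND-combined): ``all``, ``calpha``, ``name CA CB ...``,
    ``resid 373 399-405 ...``, ``chain A ...``.  Example:
    ``"calpha resid 373 399-405 526-537"``.
    """
    tokens = expr.split()
    mask = np.ones(traj.n_atoms, dtype=bool)
    i = 0
    while i < len(tokens):
        kw = tokens[i].lower()
        i += 1
        args = []
        while i < len(tokens) and tokens[i].lower() not in (
            "all", "calpha", "name", "resid", "chain"
        ):
            args.append(tokens[i])
            i += 1
        if kw == "all":
            continue
        elif kw == "calpha":
            mask &= traj.atom_names == "CA"
        elif kw == "name":
            mask &= np.isin(traj.atom_names, args)
        elif kw == "chain":
            if traj.chain_ids is None:
                raise ValueError("ensemble has no chain ids")
            mask &= np.isin(traj.chain_ids, args)
        elif kw == "resid":
            wanted: set[int] = set()
            for a in args:
                if "-" in a[1:]:
                    lo, hi = a.split("-")
                    wanted.update(range(int(lo), int(hi) + 1))
                else:
                    wanted.add(int(a))
            mask &= np.isin(traj.residue_ids, sorted(wanted))
        else:
            raise ValueError(f"unknown selection keyword {kw!r}")
    return mask


# ---------------------------------------------------------------- Kabsch ----

def _kabsch(mobile: np.ndarray, reference: np.ndarray):
    """Optimal proper rotation R and translation t mapping mobile onto
    reference in the least-squares sense (x' = x @ R + t)."""
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    h = (mobile - mob_c).T @ (reference - ref_c)
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(u @ vt))
    correction = np.diag([1.0, 1.0, d])
    rot = u @ correction @ vt
    trans = ref_c - mob_c @ rot
    return rot, trans


def superpose_rmsd(
    mobile: np.ndarray,
    reference: np.ndarray,
    selection: np.ndarray | None = None,
) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """Least-squares superposition of one frame onto another.

    Returns ``((rotation, translation), rmsd)`` where the proper rotation
    (det = +1) and translation minimise the RMSD over the selected atoms.
    Needs at least 3 non-collinear selected atoms.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if selection is not None:
        mobile_sel, reference_sel = mobile[selection], reference[selection]
    else:
        mobile_sel, reference_sel = mobile, reference
    if mobile_sel.shape != reference_sel.shape:
        raise ValueError("selected atom counts differ between frames")
    if mobile_sel.shape[0] < 3:
        raise ValueError("need at least 3 atoms for superposition")
    centered = mobile_sel - mobile_sel.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-10) < 2:
        raise ValueError("selection is collinear; superposition is degenerate")
    rot, trans = _kabsch(mobile_sel, reference_sel)
    fitted = mobile_sel @ rot + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - reference_sel) ** 2, axis=1))))
    return (rot, trans), rmsd


def align_ensemble(
    traj: TrajectoryEnsemble, selection: np.ndarray | None = None
) -> TrajectoryEnsemble:
    """Superpose every frame onto the time-averaged structure.

    The mean is computed from frames aligned to frame 0, then every frame is
    re-aligned onto that mean (one iteration of the usual mean-structure
    refinement).  The fit uses the selection; the transform moves all atoms.
    """
    coords = traj.coords
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    aligned = np.empty_like(coords)
    ref = coords[0]
    for f in range(traj.n_frames):
        rot, trans = _kabsch(coords[f][sel], ref[sel])
        aligned[f] = coords[f] @ rot + trans
    mean = aligned.mean(axis=0)
    out = np.empty_like(coords)
    for f in range(traj.n_frames):
        rot, trans = _kabsch(coords[f][sel], mean[sel])
        out[f] = coords[f] @ rot + trans
    return TrajectoryEnsemble(
        coords=out,
        residue_ids=traj.residue_ids,
        residue_names=traj.residue_names,
        atom_names=traj.atom_names,
        chain_ids=traj.chain_ids,
        elements=traj.elements,
    )


def rmsd_series(
    traj: TrajectoryEnsemble,
    reference: int | np.ndarray = 0,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame RMSD (after optimal superposition) to a reference frame."""
    ref = traj.coords[reference] if isinstance(reference, int) else np.asarray(reference)
    return np.array(
        [
            superpose_rmsd(traj.coords[f], ref, selection)[1]
            for f in range(traj.n_frames)
        ]
    )


def rmsf(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    per_residue: bool = True,
    prealigned: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Root-mean-square fluctuation about the time-mean position.

    Frames are aligned to the mean structure first (skip with
    ``prealigned=True``).  Returns ``(labels, values)``: per-residue ids and
    the per-atom RMSF averaged within each residue, or per-atom values when
    ``per_residue=False``.
    """
    if traj.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    work = traj if prealigned else align_ensemble(traj, selection)
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    coords = work.coords[:, sel]
    mean = coords.mean(axis=0)
    per_atom = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))
    if not per_residue:
        return np.arange(sel.sum()), per_atom
    res_ids = work.residue_ids[sel]
    unique = np.unique(res_ids)
    values = np.array([per_atom[res_ids == rid].mean() for rid in unique])
    return unique, values


def radius_of_gyration(
    frame: np.ndarray, weights: np.ndarray | None = None
) -> float:
    """Radius of gyration: sqrt of the (weighted) mean squared distance from
    the (weighted) centroid.  Uniform weights by default."""
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 2 or frame.shape[0] < 1:
        raise ValueError("frame must be (atoms, 3) with at least one atom")
    w = np.ones(frame.shape[0]) if weights is None else np.asarray(weights, float)
    w = w / w.sum()
    centroid = (frame * w[:, None]).sum(axis=0)
    sq = np.sum((frame - centroid) ** 2, axis=1)
    return float(np.sqrt(np.sum(w * sq)))


def rog_series(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> np.ndarray:
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    return np.array(
        [radius_of_gyration(traj.coords[f][sel], weights) for f in range(traj.n_frames)]
    )


# --------------------------------------------------------- Shrake-Rupley ----

def _sphere_points(n: int) -> np.ndarray:
    """Quasi-uniform unit-sphere points (golden-spiral construction)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def vdw_radii_for(traj: TrajectoryEnsemble) -> np.ndarray:
    """Per-atom van der Waals radii guessed from elements / atom names."""
    if traj.elements is not None:
        symbols = [str(e).upper() or "C" for e in traj.elements]
    else:
        symbols = [str(n)[:1].upper() for n in traj.atom_names]
    return np.array([VDW_RADII.get(s, VDW_RADII["C"]) for s in symbols])


def sasa(
    frame: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> tuple[float, np.ndarray]:
    """Shrake-Rupley solvent-accessible surface area of one frame.

    Test points on each atom's solvent-expanded sphere (radius + probe) are
    kept if they fall outside every neighbouring expanded sphere; the
    accessible fraction times the sphere area gives the per-atom SASA.
    Returns ``(total, per_atom)`` in A^2.  Atoms sharing identical
    coordinates are treated as fully buried duplicates (with a warning).
    """
    frame = np.asarray(frame, dtype=float)
    radii = np.asarray(radii, dtype=float)
    if (radii <= 0).any():
        raise ValueError("radii must be positive")
    if n_points < 100:
        raise ValueError("n_points must be >= 100")
    n = frame.shape[0]
    unit = _sphere_points(n_points)

    # exact-duplicate centers: keep the first, bury the rest
    _, first_index = np.unique(frame, axis=0, return_index=True)
    keep = np.zeros(n, dtype=bool)
    keep[first_index] = True
    if not keep.all():
        warnings.warn(
            "atoms with identical coordinates treated as fully buried duplicates",
            stacklevel=2,
        )

    expanded = radii + probe
    tree = cKDTree(frame[keep])
    keep_idx = np.flatnonzero(keep)
    per_atom = np.zeros(n)
    max_reach = 2.0 * expanded.max()
    for pos, i in enumerate(keep_idx):
        points = frame[i] + expanded[i] * unit
        neighbours = tree.query_ball_point(frame[i], r=max_reach)
        accessible = np.ones(n_points, dtype=bool)
        for j_pos in neighbours:
            j = keep_idx[j_pos]
            if j == i:
                continue
            d2 = np.sum((points - frame[j]) ** 2, axis=1)
            accessible &= d2 > expanded[j] ** 2
        per_atom[i] = (
            4.0 * np.pi * expanded[i] ** 2 * accessible.sum() / n_points
        )
    return float(per_atom.sum()), per_atom


def sasa_series(
    traj: TrajectoryEnsemble,
    radii: np.ndarray | None = None,
    probe: float = 1.4,
    n_points: int = 960,
    selection: np.ndarray | None = None,
) -> np.ndarray:
    """Per-frame total SASA."""
    work = traj if selection is None else traj.subset(selection)
    r = vdw_radii_for(work) if radii is None else radii
    return np.array(
        [sasa(work.coords[f], r, probe, n_points)[0] for f in range(work.n_frames)]
    )


# ------------------------------------------------------------------ DCCM ----

@dataclass(frozen=True)
class DccmMatrix:
    """Normalised cross-correlation of atomic displacement vectors."""

    matrix: np.ndarray
    labels: np.ndarray = field(default=None)


def dccm(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    prealigned: bool = False,
) -> DccmMatrix:
    """Dynamic cross-correlation matrix over the selected atoms.

    ``C_ij = <dr_i . dr_j> / sqrt(<|dr_i|^2><|dr_j|^2>)`` with ``dr`` the
    displacement from the time-mean position.  Entries lie in [-1, 1], the
    diagonal is exactly 1; zero-variance atoms get 0 off-diagonal (warning).
    """
    if traj.n_frames < 2:
        raise ValueError("DCCM needs at least 2 frames")
    work = traj if prealigned else align_ensemble(traj, selection)
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    coords = work.coords[:, sel]
    disp = coords - coords.mean(axis=0)
    # inner products of displacement vectors, averaged over frames
    inner = np.einsum("fik,fjk->ij", disp, disp) / disp.shape[0]
    var = np.diag(inner).copy()
    # "zero" variance up to float rounding of the mean subtraction
    zero = var <= 1e-10 * max(float(var.max()), 1.0)
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} zero-variance atom(s) in DCCM; rows zeroed",
            stacklevel=2,
        )
        var[zero] = 1.0
    denom = np.sqrt(np.outer(var, var))
    matrix = inner / denom
    matrix[zero, :] = 0.0
    matrix[:, zero] = 0.0
    np.fill_diagonal(matrix, 1.0)
    matrix = np.clip(matrix, -1.0, 1.0)
    return DccmMatrix(matrix=matrix, labels=work.residue_ids[sel])


# ------------------------------------------------------------------- PCA ----

@dataclass(frozen=True)
class PcaResult:
    """Eigendecomposition of the 3N-coordinate covariance matrix."""

    eigenvalues: np.ndarray      # descending, >= 0
    eigenvectors: np.ndarray     # (3N, k), orthonormal columns
    projections: np.ndarray      # (F, n_components), centred
    total_variance: float


def pca_project(
    traj: TrajectoryEnsemble,
    selection: np.ndarray | None = None,
    n_components: int = 2,
    prealigned: bool = False,
) -> PcaResult:
    """Principal components of the aligned ensemble's coordinate covariance.

    The eigenvalue sum equals the total positional variance (trace of the
    covariance); per-frame projections onto the leading components describe
    the dominant collective motions.
    """
    if traj.n_frames < 3:
        raise ValueError("PCA needs at least 3 frames")
    work = traj if prealigned else align_ensemble(traj, selection)
    sel = np.ones(traj.n_atoms, dtype=bool) if selection is None else selection
    x = work.coords[:, sel].reshape(work.n_frames, -1)
    if n_components > x.shape[1]:
        raise ValueError(
            f"n_components {n_components} exceeds coordinate dimension {x.shape[1]}"
        )
    x = x - x.mean(axis=0)
    # economy SVD: covariance eigenpairs without forming the 3N x 3N matrix
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigvals = s**2 / (x.shape[0] - 1)
    eigvecs = vt.T
    projections = x @ eigvecs[:, :n_components]
    total_var = float(np.sum(x**2) / (x.shape[0] - 1))
    return PcaResult(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        projections=projections,
        total_variance=total_var,
    )
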