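"""Rigid superposition, representative selection and conformational change.

To quantify how cosolvent probes remodel an allosteric site, representative
structures from cosolvent and pure-water simulations are compared:

* :func:`kabsch_superpose` — least-squares optimal rigid transform (Kabsch
  algorithm, proper rotation enforced via SVD sign correction);
* :func:`select_representative` — the ensemble medoid, i.e. the structure
  minimizing the summed pairwise RMSD to all others.  This realizes the
  mutual-similarity ("3D-jury"-style) ranking under an RMSD similarity —
  a deliberate approximation of the original contact-based score;
* :func:`per_residue_rmsd` — heavy-atom RMSD per site residue in the global
  superposition frame (no per-residue refit), capturing both displacement
  and rotamer change;
* :func:`backbone_rmsd_series` — per-frame backbone (N, CA, C, O) RMSD to a
  reference, the standard simulation-stability readout.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateGeometryError, RosterMismatchError
from .structio import StructureModel, TrajectoryFrames

__all__ = [
    "SuperpositionResult",
    "BACKBONE_ATOMS",
    "kabsch_superpose",
    "superposed_rmsd",
    "pairwise_rmsd_matrix",
    "select_representative",
    "per_residue_rmsd",
    "backbone_rmsd_series",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")


@dataclass
class SuperpositionResult:
    """Optimal rigid transform mapping mobile onto reference coordinates."""

    rotation: np.ndarray      # (3, 3) proper rotation, det = +1
    translation: np.ndarray   # (3,) Å
    rmsd: float               # Å, after transformation

    def apply(self, coords: np.ndarray) -> np.ndarray:
        """Transform an ``(n, 3)`` coordinate array into the reference frame."""
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Least-squares optimal rigid superposition (Kabsch algorithm).

    Parameters
    ----------
    mobile, reference:
        Matched ``(n, 3)`` coordinate arrays, n >= 3 with non-degenerate
        spread (collinear point sets leave a rotation axis undetermined and
        raise :class:`DegenerateGeometryError`).
    weights:
        Optional per-point weights for the fit and the reported RMSD.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise RosterMismatchError(
            f"point counts differ or not (n, 3): {mobile.shape} vs {reference.shape}"
        )
    n = len(mobile)
    if n < 3:
        raise DegenerateGeometryError(f"need >= 3 points for superposition, got {n}")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise ValueError("weights must be non-negative with positive sum")
    w = w / w.sum()

    mob_c = mobile - (w[:, None] * mobile).sum(axis=0)
    ref_c = reference - (w[:, None] * reference).sum(axis=0)
    cov = (w[:, None] * mob_c).T @ ref_c
    u, s, vt = np.linalg.svd(cov)
    # collinear (or coincident) points: covariance rank < 2
    if s[1] <= 1e-10 * max(s[0], 1e-300):
        raise DegenerateGeometryError("degenerate (collinear) point geometry")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rotation = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    translation = (w[:, None] * reference).sum(axis=0) - rotation @ (
        (w[:, None] * mobile).sum(axis=0)
    )
    moved = mobile @ rotation.T + translation
    rmsd = float(np.sqrt((w * np.sum((moved - reference) ** 2, axis=1)).sum()))
    return SuperpositionResult(rotation=rotation, translation=translation, rmsd=rmsd)


def superposed_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Convenience: minimal RMSD between two matched coordinate sets."""
    return kabsch_superpose(a, b).rmsd


def _select_coords(
    structure: StructureModel,
    selector: Literal["backbone", "heavy"],
) -> tuple[list[tuple], np.ndarray]:
    keys: list[tuple] = []
    coords: list[np.ndarray] = []
    for a in structure.atoms:
        if a.is_hydrogen or a.is_hetero:
            continue
        if selector == "backbone" and a.name not in BACKBONE_ATOMS:
            continue
        keys.append((a.chain, a.resnum, a.icode, a.name))
        coords.append(a.coord)
    return keys, np.array(coords)


def pairwise_rmsd_matrix(
    structures: Sequence[StructureModel],
    selector: Literal["backbone", "heavy"] = "backbone",
) -> np.ndarray:
    """Symmetric matrix of post-superposition RMSDs over a shared atom roster."""
    if not structures:
        raise ValueError("no structures given")
    rosters_coords = [_select_coords(s, selector) for s in structures]
    keys0 = rosters_coords[0][0]
    if not keys0:
        raise RosterMismatchError(f"no {selector} atoms found in first structure")
    for i, (keys, _) in enumerate(rosters_coords[1:], start=1):
        if keys != keys0:
            raise RosterMismatchError(f"structure {i} atom roster differs from structure 0")
    n = len(structures)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = kabsch_superpose(rosters_coords[i][1], rosters_coords[j][1]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def select_representative(
    structures: Sequence[StructureModel] | np.ndarray,
    selector: Literal["backbone", "heavy"] = "backbone",
) -> int:
    """Index of the ensemble medoid (minimal summed pairwise RMSD).

    Accepts either a list of structures (the RMSD matrix is computed) or a
    precomputed symmetric distance matrix.  Ties break to the lowest index.
    """
    if isinstance(structures, np.ndarray):
        mat = structures
    else:
        if len(structures) == 1:
            return 0
        mat = pairwise_rmsd_matrix(structures, selector)
    return int(np.argmin(mat.sum(axis=1)))


def per_residue_rmsd(
    rep_a: StructureModel,
    rep_b: StructureModel,
    site_residues: Sequence,
    site_label: str = "",
    probe_label: str = "",
    presuperposed: bool = False,
) -> pd.DataFrame:
    """Heavy-atom RMSD per site residue between two representative structures.

    Structure B is first superposed onto A over the shared protein backbone
    (set ``presuperposed=True`` to skip); per-residue RMSDs are then measured
    in that global frame without any per-residue refit, so the values capture
    displacement plus rotamer change.  Residues missing from either structure
    (e.g. truncated termini) yield a flagged row with NaN rather than 0.

    Returns a DataFrame with columns residue, rmsd, n_atoms, missing,
    site, probe.
    """
    if not presuperposed:
        keys_a, xyz_a = _select_coords(rep_a, "backbone")
        keys_b, xyz_b = _select_coords(rep_b, "backbone")
        shared = [k for k in keys_a if k in set(keys_b)]
        if len(shared) < 3:
            raise RosterMismatchError("fewer than 3 shared backbone atoms")
        idx_a = {k: i for i, k in enumerate(keys_a)}
        idx_b = {k: i for i, k in enumerate(keys_b)}
        sup = kabsch_superpose(
            np.array([xyz_b[idx_b[k]] for k in shared]),
            np.array([xyz_a[idx_a[k]] for k in shared]),
        )
        rep_b = rep_b.with_coords(sup.apply(rep_b.coords))

    rows = []
    for rid in site_residues:
        atoms_a = {a.name: a for a in rep_a.residue(rid) if not a.is_hydrogen}
        atoms_b = {a.name: a for a in rep_b.residue(rid) if not a.is_hydrogen}
        shared_names = sorted(set(atoms_a) & set(atoms_b))
        if not atoms_a or not atoms_b or not shared_names:
            rows.append({"residue": str(rid), "rmsd": np.nan, "n_atoms": 0,
                         "missing": True, "site": site_label, "probe": probe_label})
            continue
        da = np.array([atoms_a[n].coord for n in shared_names])
        db = np.array([atoms_b[n].coord for n in shared_names])
        rmsd = float(np.sqrt(np.mean(np.sum((da - db) ** 2, axis=1))))
        rows.append({"residue": str(rid), "rmsd": rmsd, "n_atoms": len(shared_names),
                     "missing": False, "site": site_label, "probe": probe_label})
    return pd.DataFrame(rows)


def backbone_rmsd_series(
    frames: TrajectoryFrames,
    reference: StructureModel,
) -> list[tuple[int, float]]:
    """Per-frame backbone RMSD to a reference after superposition."""
    ref_keys, ref_xyz = _select_coords(reference, "backbone")
    if not ref_keys:
        raise RosterMismatchError("reference has no backbone atoms")
    ref_index = {k: i for i, k in enumerate(ref_keys)}
    series: list[tuple[int, float]] = []
    for fi, frame in enumerate(frames):
        keys, xyz = _select_coords(frame, "backbone")
        shared = [k for k in keys if k in ref_index]
        if len(shared) < 3:
            raise RosterMismatchError(f"frame {fi} shares < 3 backbone atoms with reference")
        idx_f = {k: i for i, k in enumerate(keys)}
        mob = np.array([xyz[idx_f[k]] for k in shared])
        ref = np.array([ref_xyz[ref_index[k]] for k in shared])
        series.append((fi, kabsch_superpose(mob, ref).rmsd))
    return series
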