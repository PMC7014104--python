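"""Hydration-site clustering, occupancy filtering and MD/crystal consensus.

Two independent routes predict conserved water positions at a binding site:

1. water-oxygen snapshots from a restrained explicit-water MD simulation,
2. crystallographic waters pooled from many superimposed structures.

Both are clustered with DBSCAN (defaults ε = 0.9 Å, min_pts = 2, the query
point counted among its own neighbors).  A cluster becomes a hydration site
with a centroid and an *occupancy*: the fraction of distinct sources (frames
or structures) contributing at least one member.  Sites passing a minimal
occupancy criterion — a step schedule on the number of input sources — are
"conserved".  MD and crystal predictions are merged into a consensus by
greedy nearest-pair matching under a distance threshold (default 1.4 Å).
Per-site desolvation thermodynamics (ΔH, −TΔS in kcal/mol) are consumed from
external tables, never computed here; sites with ΔH below a cutoff
(default −1.0 kcal/mol) are flagged as favorably displaceable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.cluster import DBSCAN

from .errors import EmptyInputError
from .structio import Atom, StructureModel, TrajectoryFrames

__all__ = [
    "WaterObservationSet",
    "HydrationSite",
    "DEFAULT_OCCUPANCY_SCHEDULE",
    "dbscan_cluster",
    "site_from_cluster",
    "cluster_sites",
    "occupancy_threshold",
    "filter_conserved",
    "consensus_match",
    "flag_favorable",
    "extract_crystal_waters",
    "extract_md_waters",
    "sites_to_dataframe",
    "write_sites_pdb",
]

#: Minimal-occupancy criterion by source count: few structures demand high
#: occupancy; large ensembles tolerate lower.  Entries are
#: (minimum source count, occupancy threshold), checked top-down.
DEFAULT_OCCUPANCY_SCHEDULE: tuple[tuple[int, float], ...] = (
    (30, 0.3),
    (10, 0.4),
    (0, 0.5),
)


@dataclass
class WaterObservationSet:
    """Water-oxygen positions tagged by source (frame index or structure id)."""

    points: np.ndarray        # (n, 3) Å
    sources: np.ndarray       # (n,) integer source ids
    source_count: int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.sources = np.asarray(self.sources, dtype=int).reshape(-1)
        if len(self.points) != len(self.sources):
            raise ValueError("points and sources must have equal length")
        if self.source_count < 1:
            raise ValueError("source count must be >= 1")
        if len(self.sources) and self.sources.max() >= self.source_count:
            raise ValueError("source id exceeds source count")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class HydrationSite:
    """A clustered water position with occupancy and optional thermodynamics."""

    centroid: np.ndarray
    members: int
    occupancy: float
    provenance: str                 # "MD" | "crystal" | "consensus"
    dH: float | None = None         # desolvation enthalpy, kcal/mol
    mTdS: float | None = None       # -T*dS, kcal/mol
    favorable: bool = False

    def __post_init__(self) -> None:
        self.centroid = np.asarray(self.centroid, dtype=float).reshape(3)
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def dbscan_cluster(
    points: np.ndarray,
    epsilon: float = 0.9,
    min_pts: int = 2,
) -> np.ndarray:
    """DBSCAN labels over 3D Euclidean distance; -1 marks noise.

    A core point has at least ``min_pts`` neighbors within ``epsilon``,
    *counting itself* — so min_pts = 2 means "at least one other point within
    ε".  Border points join the first core cluster that reaches them in
    input order (the classic DBSCAN order dependence; inputs are processed
    deterministically).
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    if min_pts < 1:
        raise ValueError(f"min_pts must be >= 1, got {min_pts}")
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    if len(points) == 0:
        return np.empty(0, dtype=int)
    return DBSCAN(eps=epsilon, min_samples=min_pts).fit(points).labels_


def site_from_cluster(
    member_points: np.ndarray,
    member_sources: Sequence[int],
    source_count: int,
    provenance: str = "MD",
) -> HydrationSite:
    """Build a hydration site from one cluster's members.

    Centroid is the unweighted mean of member coordinates; occupancy is the
    number of *distinct* sources represented divided by the source count.
    """
    member_points = np.asarray(member_points, dtype=float).reshape(-1, 3)
    if len(member_points) == 0:
        raise EmptyInputError("cluster has no members")
    occupancy = len(set(int(s) for s in member_sources)) / source_count
    return HydrationSite(
        centroid=member_points.mean(axis=0),
        members=len(member_points),
        occupancy=occupancy,
        provenance=provenance,
    )


def cluster_sites(
    observations: WaterObservationSet,
    epsilon: float = 0.9,
    min_pts: int = 2,
    provenance: str = "MD",
) -> list[HydrationSite]:
    """Cluster a water observation set and return one site per cluster.

    Sites are ordered by descending occupancy, then member count, then
    centroid (deterministic given the input order).
    """
    labels = dbscan_cluster(observations.points, epsilon, min_pts)
    sites: list[HydrationSite] = []
    for lab in sorted(set(labels) - {-1}):
        mask = labels == lab
        sites.append(site_from_cluster(
            observations.points[mask],
            observations.sources[mask],
            observations.source_count,
            provenance,
        ))
    sites.sort(key=lambda s: (-s.occupancy, -s.members, tuple(s.centroid)))
    return sites


# ---------------------------------------------------------------------------
# Conservation filtering and consensus
# ---------------------------------------------------------------------------

def occupancy_threshold(
    source_count: int,
    schedule: Sequence[tuple[int, float]] = DEFAULT_OCCUPANCY_SCHEDULE,
) -> float:
    """Minimal-occupancy criterion for a given number of input sources."""
    for min_sources, threshold in sorted(schedule, key=lambda t: -t[0]):
        if source_count >= min_sources:
            return threshold
    return sorted(schedule, key=lambda t: t[0])[0][1]


def filter_conserved(
    sites: Sequence[HydrationSite],
    source_count: int,
    min_occupancy: float | None = None,
    schedule: Sequence[tuple[int, float]] = DEFAULT_OCCUPANCY_SCHEDULE,
) -> list[HydrationSite]:
    """Keep sites whose occupancy meets the (scheduled or explicit) minimum."""
    if min_occupancy is None:
        min_occupancy = occupancy_threshold(source_count, schedule)
    if not (0.0 < min_occupancy <= 1.0):
        raise ValueError(f"min occupancy {min_occupancy} outside (0, 1]")
    return [s for s in sites if s.occupancy >= min_occupancy]


def consensus_match(
    md_sites: Sequence[HydrationSite],
    crystal_sites: Sequence[HydrationSite],
    threshold: float = 1.4,
) -> tuple[list[HydrationSite], list[HydrationSite], list[HydrationSite]]:
    """Pair MD and crystal sites within a distance threshold into a consensus.

    Greedy global matching: repeatedly pair the closest unmatched (MD,
    crystal) couple with centroid distance <= threshold; each site is matched
    at most once.  The consensus centroid is the midpoint; occupancy is the
    mean of the two; ΔH / −TΔS are carried over from the MD site when present.

    Returns ``(consensus, unmatched_md, unmatched_crystal)``.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    consensus: list[HydrationSite] = []
    if md_sites and crystal_sites:
        dists = cdist(
            np.array([s.centroid for s in md_sites]),
            np.array([s.centroid for s in crystal_sites]),
        )
        free_md = set(range(len(md_sites)))
        free_xt = set(range(len(crystal_sites)))
        pairs: list[tuple[int, int]] = []
        # stable global-minimum sweep over all candidate pairs
        order = sorted(
            ((dists[i, j], i, j) for i in free_md for j in free_xt
             if dists[i, j] <= threshold),
        )
        for _, i, j in order:
            if i in free_md and j in free_xt:
                pairs.append((i, j))
                free_md.discard(i)
                free_xt.discard(j)
        for i, j in sorted(pairs):
            md, xt = md_sites[i], crystal_sites[j]
            consensus.append(HydrationSite(
                centroid=(md.centroid + xt.centroid) / 2.0,
                members=md.members + xt.members,
                occupancy=(md.occupancy + xt.occupancy) / 2.0,
                provenance="consensus",
                dH=md.dH, mTdS=md.mTdS,
            ))
        unmatched_md = [md_sites[i] for i in sorted(free_md)]
        unmatched_xt = [crystal_sites[j] for j in sorted(free_xt)]
    else:
        unmatched_md = list(md_sites)
        unmatched_xt = list(crystal_sites)
    return consensus, unmatched_md, unmatched_xt


def flag_favorable(
    sites: Sequence[HydrationSite],
    dH_cutoff: float = -1.0,
) -> list[HydrationSite]:
    """Flag sites whose ΔH lies below the cutoff (favorably displaceable).

    Sites lacking a ΔH value are left unflagged.
    """
    return [
        replace(s, favorable=(s.dH is not None and s.dH < dH_cutoff))
        for s in sites
    ]


# ---------------------------------------------------------------------------
# Water extraction
# ---------------------------------------------------------------------------

def extract_crystal_waters(structures: Sequence[StructureModel]) -> WaterObservationSet:
    """Pool water-oxygen positions from superimposed crystal structures.

    One point per water oxygen; the source id is the structure index.  A
    water residue lacking an oxygen atom is skipped with a warning; a
    structure without waters simply contributes no points.
    """
    if not structures:
        raise EmptyInputError("no structures given")
    points: list[np.ndarray] = []
    sources: list[int] = []
    for idx, st in enumerate(structures):
        oxygens = {(a.chain, a.resnum, a.icode): a for a in st.water_oxygens()}
        water_rids = {
            a.residue_id for a in st.atoms if a.resname in ("HOH", "WAT")
        }
        for rid in water_rids:
            key = (rid.chain, rid.resnum, rid.icode)
            if key not in oxygens:
                warnings.warn(f"water {rid} in structure {idx} has no oxygen; skipped")
        for a in oxygens.values():
            points.append(a.coord)
            sources.append(idx)
    pts = np.array(points) if points else np.empty((0, 3))
    return WaterObservationSet(
        points=pts, sources=np.array(sources, dtype=int),
        source_count=len(structures),
    )


def extract_md_waters(frames: TrajectoryFrames) -> WaterObservationSet:
    """Water-oxygen positions from MD snapshots; source id = frame index."""
    return extract_crystal_waters(list(frames.frames))


# ---------------------------------------------------------------------------
# Tables and pseudo-atom output
# ---------------------------------------------------------------------------

def sites_to_dataframe(sites: Sequence[HydrationSite]) -> pd.DataFrame:
    """Site table with columns provenance, x, y, z, members, occupancy, dH, mTdS, favorable_flag."""
    return pd.DataFrame([
        {
            "provenance": s.provenance,
            "x": s.centroid[0], "y": s.centroid[1], "z": s.centroid[2],
            "members": s.members,
            "occupancy": s.occupancy,
            "dH": s.dH if s.dH is not None else np.nan,
            "mTdS": s.mTdS if s.mTdS is not None else np.nan,
            "favorable_flag": bool(s.favorable),
        }
        for s in sites
    ])


def attach_thermodynamics(
    sites: Sequence[HydrationSite],
    table: pd.DataFrame,
    max_distance: float = 1.0,
) -> list[HydrationSite]:
    """Attach externally computed ΔH / −TΔS to the nearest site within a radius.

    ``table`` needs columns x, y, z, dH and optionally mTdS (kcal/mol).
    """
    out = list(sites)
    if not len(out) or table.empty:
        return out
    centroids = np.array([s.centroid for s in out])
    coords = table[["x", "y", "z"]].to_numpy(dtype=float)
    dists = cdist(coords, centroids)
    for row_idx in range(len(table)):
        i = int(np.argmin(dists[row_idx]))
        if dists[row_idx, i] <= max_distance:
            out[i] = replace(
                out[i],
                dH=float(table.iloc[row_idx]["dH"]),
                mTdS=float(table.iloc[row_idx]["mTdS"]) if "mTdS" in table else out[i].mTdS,
            )
    return out


def write_sites_pdb(sites: Sequence[HydrationSite], path: str | Path) -> Path:
    """Write site centroids as HETATM water-oxygen pseudo-atoms (PyMol-viewable)."""
    path = Path(path)
    lines = []
    for i, s in enumerate(sites, start=1):
        lines.append(
            f"HETATM{i:>5}  O   HOH W{i:>4}    "
            f"{s.centroid[0]:8.3f}{s.centroid[1]:8.3f}{s.centroid[2]:8.3f}"
            f"{s.occupancy:6.2f}{0.0:6.2f}           O"
        )
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path
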