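"""Binding-site residue selection and pairwise conservation scoring.

Allosteric sites on nuclear-receptor ligand-binding domains (the AF-2
coactivator groove and the adjacent BF-3 surface) are defined here as the
contact shell of a cocrystallized ligand: every protein residue with a heavy
atom within a radius (default 5 Å) of any ligand heavy atom.  Site residues
are then compared across receptors through a multiple sequence alignment with
a simple substitution-aware score: an identical residue pair counts 1.0, a
pair from the same physicochemical residue group counts 0.5, anything else
(including gaps) counts 0.  The per-pair conservation percentage is the summed
score over the site columns divided by the site residue count — i.e. a
percentage of the maximally achievable score — which yields a symmetric
receptor-by-receptor matrix with a diagonal of 100.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import AllositeError, EmptyInputError, MappingError
from .structio import AlignmentSet, Atom, ResidueId, StructureModel

__all__ = [
    "ResidueGroupScheme",
    "DEFAULT_GROUPS",
    "SiteDefinition",
    "ConservationMatrix",
    "select_site_residues",
    "chain_sequence",
    "map_site_to_alignment",
    "score_residue_pair",
    "conservation_percentage",
    "build_conservation_matrix",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    # common modified residues mapped to their parent
    "MSE": "M", "SEC": "C", "HYP": "P", "SEP": "S", "TPO": "T", "PTR": "Y",
}

#: Default physicochemical grouping; overridable because published analyses
#: differ in where they draw these lines (e.g. whether G and P are "polar").
DEFAULT_GROUPS: Mapping[str, frozenset[str]] = {
    "hydrophobic": frozenset("AVLIM"),
    "aromatic": frozenset("FWY"),
    "polar": frozenset("STNQCGP"),
    "positive": frozenset("KRH"),
    "negative": frozenset("DE"),
}


class ResidueGroupScheme:
    """A named partition of the 20 amino acids into physicochemical classes."""

    def __init__(self, groups: Mapping[str, Sequence[str]] | None = None):
        groups = groups if groups is not None else DEFAULT_GROUPS
        self.groups: dict[str, frozenset[str]] = {
            name: frozenset(str(m).upper() for m in members)
            for name, members in groups.items()
        }
        covered: dict[str, str] = {}
        for name, members in self.groups.items():
            for aa in members:
                if aa not in AMINO_ACIDS:
                    raise ValueError(f"group {name!r} contains non-amino-acid {aa!r}")
                if aa in covered:
                    raise ValueError(f"{aa} appears in both {covered[aa]!r} and {name!r}")
                covered[aa] = name
        missing = set(AMINO_ACIDS) - set(covered)
        if missing:
            raise ValueError(f"grouping does not cover amino acids: {sorted(missing)}")
        self._class_of = covered

    def class_of(self, aa: str) -> str:
        aa = aa.upper()
        if aa not in self._class_of:
            raise ValueError(f"unknown amino-acid letter {aa!r}")
        return self._class_of[aa]

    def same_group(self, a: str, b: str) -> bool:
        return self.class_of(a) == self.class_of(b)

    @classmethod
    def from_config(cls, path) -> "ResidueGroupScheme":
        """Load a plain-text ``name: MEMBERS`` grouping file, one group per line."""
        groups: dict[str, str] = {}
        for raw in open(path):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            name, _, members = line.partition(":")
            groups[name.strip()] = members.replace(",", "").replace(" ", "")
        return cls(groups)


@dataclass
class SiteDefinition:
    """One allosteric site on a reference receptor.

    ``residues`` are ordered residue identifiers on the reference structure;
    ``columns`` (0-based) map each residue to its alignment column once
    :func:`map_site_to_alignment` has run.
    """

    label: str
    reference: str
    residues: list[ResidueId]
    columns: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise EmptyInputError("site definition must contain residues")
        if len(set(self.residues)) != len(self.residues):
            raise ValueError("duplicate residues in site definition")
        if self.columns is not None and len(self.columns) != len(self.residues):
            raise ValueError("alignment columns must map 1:1 to site residues")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ConservationMatrix:
    """Symmetric receptor-by-receptor conservation percentages in [0, 100]."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(f"matrix shape {self.values.shape} != ({n}, {n})")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])


# ---------------------------------------------------------------------------
# Site selection and alignment mapping
# ---------------------------------------------------------------------------

def select_site_residues(
    structure: StructureModel,
    ligand: ResidueId | str,
    radius: float = 5.0,
) -> list[ResidueId]:
    """Protein residues with any heavy atom within ``radius`` Å of the ligand.

    The "spherical zone" around a cocrystallized ligand is read as the
    standard contact shell: a residue qualifies if any of its heavy atoms is
    within the radius of *any* ligand heavy atom (a single sphere about the
    ligand centroid would over-select for elongated ligands).  Hydrogens are
    ignored on both sides — crystal structures typically lack them.
    Residues are returned ordered by (chain, residue number, insertion code).
    """
    if isinstance(ligand, str):
        ligand = ResidueId.parse(ligand)
    lig_atoms = [a for a in structure.residue(ligand) if not a.is_hydrogen]
    if not lig_atoms:
        raise EmptyInputError(f"ligand selector {ligand} matches no heavy atoms")
    prot_atoms = [a for a in structure.protein_atoms() if not a.is_hydrogen]
    if not prot_atoms:
        return []
    lig_xyz = np.array([a.coord for a in lig_atoms])
    prot_xyz = np.array([a.coord for a in prot_atoms])
    tree = cKDTree(prot_xyz)
    hit_idx: set[int] = set()
    for hits in tree.query_ball_point(lig_xyz, r=radius):
        hit_idx.update(hits)
    residues = {prot_atoms[i].residue_id for i in hit_idx}
    return sorted(residues, key=lambda r: (r.chain, r.resnum, r.icode))


def chain_sequence(structure: StructureModel, chain: str) -> tuple[str, list[ResidueId]]:
    """One-letter sequence and residue ids for the protein residues of a chain."""
    seq: list[str] = []
    rids: list[ResidueId] = []
    for rid in structure.residue_ids(hetero=False):
        if rid.chain != chain:
            continue
        resname = structure.residue(rid)[0].resname
        letter = THREE_TO_ONE.get(resname)
        if letter is None:
            continue  # skip non-standard polymer residues
        seq.append(letter)
        rids.append(rid)
    return "".join(seq), rids


def map_site_to_alignment(
    site_residues: Sequence[ResidueId],
    structure: StructureModel,
    reference_label: str,
    alignment: AlignmentSet,
    site_label: str = "site",
) -> SiteDefinition:
    """Assign each site residue its 0-based alignment column.

    The reference receptor's aligned row (with gaps removed) must contain, or
    be contained in, the structure-derived chain sequence; site residues are
    located through that correspondence.
    """
    row = alignment.row(reference_label)
    ungapped = row.replace(GAP, "")
    col_of_pos = [i for i, c in enumerate(row) if c != GAP]

    columns: list[int] = []
    for rid in site_residues:
        seq, rids = chain_sequence(structure, rid.chain)
        try:
            res_idx = rids.index(rid)
        except ValueError as exc:
            raise MappingError(f"site residue {rid} not found in structure chain") from exc
        if seq in ungapped:
            pos = ungapped.index(seq) + res_idx
        elif ungapped in seq:
            pos = res_idx - seq.index(ungapped)
            if not (0 <= pos < len(ungapped)):
                raise MappingError(
                    f"site residue {rid} lies outside the aligned span of "
                    f"{reference_label!r}"
                )
        else:
            raise MappingError(
                f"chain {rid.chain} sequence and aligned row of "
                f"{reference_label!r} do not correspond"
            )
        if ungapped[pos] != seq[res_idx]:
            raise MappingError(
                f"residue {rid} ({seq[res_idx]}) does not match aligned row "
                f"position {pos} ({ungapped[pos]})"
            )
        columns.append(col_of_pos[pos])
    return SiteDefinition(
        label=site_label,
        reference=reference_label,
        residues=list(site_residues),
        columns=columns,
    )


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------

def score_residue_pair(a: str, b: str, scheme: ResidueGroupScheme | None = None) -> float:
    """Score one aligned residue pair: identity 1.0, same group 0.5, else 0.

    A gap on either side scores 0 — the pair cannot contribute to the
    maximally achievable score.
    """
    scheme = scheme or ResidueGroupScheme()
    a, b = a.upper(), b.upper()
    if a == GAP or b == GAP:
        return 0.0
    for letter in (a, b):
        if letter not in AMINO_ACIDS:
            raise ValueError(f"unknown residue letter {letter!r}")
    if a == b:
        return 1.0
    if scheme.same_group(a, b):
        return 0.5
    return 0.0


def conservation_percentage(
    columns: Sequence[int],
    row_a: str,
    row_b: str,
    scheme: ResidueGroupScheme | None = None,
) -> float:
    """Site conservation between two aligned rows, as % of the maximal score.

    The denominator is the site residue count (not the gap-free pair count),
    so gapped columns dilute the percentage rather than being excluded.
    """
    if len(columns) == 0:
        raise EmptyInputError("conservation requires at least one site column")
    scheme = scheme or ResidueGroupScheme()
    total = 0.0
    for col in columns:
        if not (0 <= col < len(row_a)) or not (0 <= col < len(row_b)):
            raise IndexError(f"alignment column {col} out of bounds")
        total += score_residue_pair(row_a[col], row_b[col], scheme)
    return 100.0 * total / len(columns)


def build_conservation_matrix(
    alignment: AlignmentSet,
    site: SiteDefinition,
    scheme: ResidueGroupScheme | None = None,
) -> ConservationMatrix:
    """Full symmetric conservation-percentage matrix over all receptors."""
    if site.columns is None:
        raise MappingError("site has no alignment columns; run map_site_to_alignment")
    if site.reference not in alignment.labels:
        raise AllositeError(f"reference receptor {site.reference!r} not in alignment")
    scheme = scheme or ResidueGroupScheme()
    labels = alignment.labels
    n = len(labels)
    values = np.full((n, n), 100.0)
    rows = [alignment.row(lab) for lab in labels]
    for i in range(n):
        for j in range(i + 1, n):
            pct = conservation_percentage(site.columns, rows[i], rows[j], scheme)
            values[i, j] = values[j, i] = pct
    return ConservationMatrix(labels=labels, values=values)
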