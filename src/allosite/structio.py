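"""Structure, alignment and volumetric-map I/O.

This module is the single place where external file formats enter or leave
the pipeline:

* PDB structures and multi-model PDB trajectories (read via gemmi, written
  with standard fixed-column records),
* aligned FASTA multiple sequence alignments (read via Bio.AlignIO),
* OpenDX (``.dx``) and CNS scalar maps for bulk-normalized probe densities.

Coordinates are Å throughout.  Alternate locations are resolved on read by
keeping the highest-occupancy conformer (ties broken by alphabetical alt-loc
id).  Residue identity is keyed by PDB author numbering including the
insertion code.  Waters are HETATM residues named HOH/WAT whose position is
represented by the oxygen atom alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import gemmi
import numpy as np
from Bio import AlignIO

from .errors import (
    AlignmentError,
    EmptyInputError,
    GridError,
    PDBParseError,
)
from .grids import DensityGrid

__all__ = [
    "Atom",
    "ResidueId",
    "StructureModel",
    "TrajectoryFrames",
    "AlignmentSet",
    "read_structure",
    "write_structure",
    "read_alignment",
    "write_grid",
    "read_grid",
    "WATER_RESNAMES",
]

WATER_RESNAMES = frozenset({"HOH", "WAT"})

#: Two-letter elements we disambiguate when the element column is absent.
#: CA/NA are deliberately excluded: in protein records they are almost always
#: the alpha-carbon / a nitrogen, and calcium/sodium ions normally carry an
#: explicit element field.
_TWO_LETTER_HET = frozenset({"CL", "BR", "FE", "ZN", "MG", "MN", "SE", "CU", "NI"})


@dataclass(frozen=True)
class ResidueId:
    """Author-numbering residue key: chain id, residue number, insertion code."""

    chain: str
    resnum: int
    icode: str = ""

    def __str__(self) -> str:  # e.g. "A:720" or "A:720A"
        return f"{self.chain}:{self.resnum}{self.icode}"

    @classmethod
    def parse(cls, token: str) -> "ResidueId":
        """Parse a ``chain:resnum[icode]`` token such as ``B:901`` or ``A:52A``."""
        chain, _, rest = token.partition(":")
        if not chain or not rest:
            raise ValueError(f"cannot parse residue token {token!r}; expected chain:resnum")
        digits = "".join(c for c in rest if c.isdigit() or c == "-")
        icode = rest[len(digits):].strip()
        return cls(chain=chain, resnum=int(digits), icode=icode)


@dataclass(frozen=True)
class Atom:
    """One atom of a structure model (coordinates in Å)."""

    chain: str
    resnum: int
    icode: str
    resname: str
    name: str
    element: str
    x: float
    y: float
    z: float
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def residue_id(self) -> ResidueId:
        return ResidueId(self.chain, self.resnum, self.icode)

    @property
    def coord(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    @property
    def is_hydrogen(self) -> bool:
        return self.element in ("H", "D")


class StructureModel:
    """A single structure model: an ordered list of atoms plus a model index."""

    def __init__(self, atoms: Sequence[Atom], model_index: int = 0):
        self.atoms: list[Atom] = list(atoms)
        self.model_index = int(model_index)
        coords = np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)
        if len(self.atoms) == 0:
            coords = coords.reshape(0, 3)
        if not np.all(np.isfinite(coords)):
            raise PDBParseError("structure contains non-finite coordinates")
        self._coords = coords

    def __len__(self) -> int:
        return len(self.atoms)

    def __repr__(self) -> str:
        return f"<StructureModel {len(self)} atoms, model {self.model_index}>"

    @property
    def coords(self) -> np.ndarray:
        """``(n_atoms, 3)`` coordinate array in Å (copy-free view)."""
        return self._coords

    def with_coords(self, coords: np.ndarray) -> "StructureModel":
        """Same atom roster with replaced coordinates (e.g. after superposition)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(f"coords shape {coords.shape} != ({len(self.atoms)}, 3)")
        atoms = [
            Atom(a.chain, a.resnum, a.icode, a.resname, a.name, a.element,
                 float(xyz[0]), float(xyz[1]), float(xyz[2]), a.occupancy, a.is_hetero)
            for a, xyz in zip(self.atoms, coords)
        ]
        return StructureModel(atoms, self.model_index)

    # ---- selections -------------------------------------------------

    def select(self, predicate) -> "StructureModel":
        return StructureModel([a for a in self.atoms if predicate(a)], self.model_index)

    def heavy_atoms(self, include_hetero: bool = True) -> list[Atom]:
        return [a for a in self.atoms
                if not a.is_hydrogen and (include_hetero or not a.is_hetero)]

    def protein_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hetero]

    def residue(self, rid: ResidueId) -> list[Atom]:
        return [a for a in self.atoms if a.residue_id == rid]

    def residue_ids(self, hetero: bool | None = None) -> list[ResidueId]:
        """Unique residue ids in order of first appearance."""
        seen: dict[ResidueId, None] = {}
        for a in self.atoms:
            if hetero is not None and a.is_hetero != hetero:
                continue
            seen.setdefault(a.residue_id, None)
        return list(seen)

    def water_oxygens(self) -> list[Atom]:
        """Oxygen atoms of HOH/WAT residues (a water's canonical position)."""
        return [a for a in self.atoms
                if a.resname in WATER_RESNAMES and a.element == "O"]

    def atom_map(self, heavy_only: bool = False) -> dict[tuple, int]:
        """Index of each atom keyed by (chain, resnum, icode, atom name)."""
        out: dict[tuple, int] = {}
        for i, a in enumerate(self.atoms):
            if heavy_only and a.is_hydrogen:
                continue
            out[(a.chain, a.resnum, a.icode, a.name)] = i
        return out


@dataclass
class TrajectoryFrames:
    """Ordered frames sharing one atom roster, with optional per-frame box lengths (Å)."""

    frames: list[StructureModel]
    boxes: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise EmptyInputError("trajectory must contain at least one frame")
        roster = [(a.chain, a.resnum, a.icode, a.name) for a in self.frames[0].atoms]
        for k, fr in enumerate(self.frames[1:], start=1):
            other = [(a.chain, a.resnum, a.icode, a.name) for a in fr.atoms]
            if other != roster:
                raise PDBParseError(
                    f"frame {k} atom roster differs from frame 0 "
                    f"({len(other)} vs {len(roster)} atoms or reordered)"
                )
        if self.boxes is not None:
            self.boxes = [np.asarray(b, dtype=float).reshape(3) for b in self.boxes]
            if len(self.boxes) != len(self.frames):
                raise ValueError("one box length triple required per frame")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self):
        return iter(self.frames)

    @property
    def n_atoms(self) -> int:
        return len(self.frames[0])

    def coords_array(self) -> np.ndarray:
        """``(n_frames, n_atoms, 3)`` coordinate stack."""
        return np.stack([f.coords for f in self.frames])


@dataclass
class AlignmentSet:
    """A read-only multiple sequence alignment: labelled equal-length rows."""

    records: list[tuple[str, str]]
    n_columns: int = 0

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError(f"alignment needs >= 2 records, got {len(self.records)}")
        lengths = {len(seq) for _, seq in self.records}
        if len(lengths) != 1:
            raise AlignmentError(f"ragged alignment: row lengths {sorted(lengths)}")
        labels = [lab for lab, _ in self.records]
        if len(set(labels)) != len(labels):
            raise AlignmentError("duplicate record labels in alignment")
        self.n_columns = lengths.pop()

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.records]

    def row(self, label: str) -> str:
        for lab, seq in self.records:
            if lab == label:
                return seq
        raise KeyError(f"no alignment record labelled {label!r}")


# ---------------------------------------------------------------------------
# PDB reading / writing
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    """Raise PDBParseError naming the offending line for malformed records."""
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line.rstrip("\n")) < 54:
            raise PDBParseError(f"line {lineno}: record too short for coordinates")
        try:
            float(line[30:38]); float(line[38:46]); float(line[46:54])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: unparseable coordinates") from exc
        try:
            int(line[22:26])
        except ValueError as exc:
            raise PDBParseError(f"line {lineno}: unparseable residue number") from exc


def _infer_element(name: str, resname: str, is_hetero: bool) -> str:
    """Best-effort element from the atom name when the element column is blank."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    two = stripped[:2].upper()
    if is_hetero and two in _TWO_LETTER_HET:
        return two.capitalize()
    for ch in stripped:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _atoms_from_gemmi_model(model: gemmi.Model) -> list[Atom]:
    # Alt-loc resolution: one atom per (chain, resnum, icode, name), keeping the
    # highest-occupancy conformer; ties broken by alphabetical alt-loc id.
    chosen: dict[tuple, tuple[float, str, Atom]] = {}
    order: list[tuple] = []
    for chain in model:
        for res in chain:
            is_het = res.het_flag == "H"
            for at in res:
                el = at.element.name if at.element and at.element.name not in ("X", "") else ""
                if not el:
                    el = _infer_element(at.name, res.name, is_het)
                atom = Atom(
                    chain=chain.name,
                    resnum=res.seqid.num,
                    icode=(res.seqid.icode or "").strip(),
                    resname=res.name.strip(),
                    name=at.name.strip(),
                    element=el,
                    x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    occupancy=at.occ,
                    is_hetero=is_het,
                )
                key = (atom.chain, atom.resnum, atom.icode, atom.name)
                alt = (at.altloc or "").strip()
                if key not in chosen:
                    chosen[key] = (atom.occupancy, alt, atom)
                    order.append(key)
                else:
                    occ0, alt0, _ = chosen[key]
                    if (atom.occupancy > occ0 + 1e-12) or (
                        abs(atom.occupancy - occ0) <= 1e-12 and alt < alt0
                    ):
                        chosen[key] = (atom.occupancy, alt, atom)
    return [chosen[k][2] for k in order]


def read_structure(
    path: str | Path,
    model_policy: Literal["first", "all"] = "first",
) -> StructureModel | TrajectoryFrames:
    """Read a PDB file.

    Parameters
    ----------
    path:
        PDB-format text file (single- or multi-MODEL).
    model_policy:
        ``"first"`` returns the first model as a :class:`StructureModel`;
        ``"all"`` returns every model as :class:`TrajectoryFrames` (multi-model
        PDB is the trajectory interchange format of this package).

    Raises
    ------
    PDBParseError
        For malformed ATOM/HETATM records (the message names the line).
    EmptyInputError
        If the file contains no atoms.
    """
    path = Path(path)
    text = path.read_text()
    _validate_pdb_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"{path.name}: {exc}") from exc
    models = [(i, _atoms_from_gemmi_model(m)) for i, m in enumerate(st)]
    models = [(i, atoms) for i, atoms in models if atoms]
    if not models:
        raise EmptyInputError(f"{path.name}: no atoms found")
    if model_policy == "first":
        idx, atoms = models[0]
        return StructureModel(atoms, model_index=idx)
    if model_policy != "all":
        raise ValueError(f"model_policy must be 'first' or 'all', got {model_policy!r}")
    frames = [StructureModel(atoms, model_index=i) for i, atoms in models]
    boxes = None
    cell = st.cell
    if cell and cell.a > 1.0:  # gemmi's placeholder cell is 1 Å
        boxes = [np.array([cell.a, cell.b, cell.c])] * len(frames)
    if len(frames) == 1:
        return TrajectoryFrames(frames, boxes)
    return TrajectoryFrames(frames, boxes)


def _format_atom_name(name: str, element: str) -> str:
    # PDB columns 13-16: one-letter elements start in column 14 unless the
    # name is four characters long.
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def _atom_record(a: Atom, serial: int) -> str:
    rec = "HETATM" if a.is_hetero else "ATOM  "
    name = _format_atom_name(a.name, a.element)
    icode = a.icode[:1] if a.icode else " "
    return (
        f"{rec}{serial:>5} {name} {a.resname:>3} {a.chain[:1]}{a.resnum:>4}{icode}   "
        f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}          "
        f"{a.element[:2]:>2}"
    )


def write_structure(
    obj: StructureModel | TrajectoryFrames,
    path: str | Path,
) -> Path:
    """Write a structure or trajectory as (multi-model) PDB text."""
    path = Path(path)
    lines: list[str] = []
    if isinstance(obj, StructureModel):
        frames: Iterable[StructureModel] = [obj]
        multi = False
        boxes = None
    else:
        frames = obj.frames
        multi = len(obj.frames) > 1
        boxes = obj.boxes
    if boxes is not None and len(boxes) > 0:
        b = boxes[0]
        lines.append(
            f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for k, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {k:>4}")
        for serial, a in enumerate(frame.atoms, start=1):
            lines.append(_atom_record(a, min(serial, 99999)))
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# Alignment reading
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path) -> AlignmentSet:
    """Read an aligned-FASTA multiple sequence alignment (>= 2 records).

    Ragged alignments are rejected with :class:`AlignmentError`.
    """
    path = Path(path)
    try:
        msa = AlignIO.read(str(path), "fasta")
    except ValueError as exc:
        raise AlignmentError(f"{path.name}: {exc}") from exc
    records = [(rec.id, str(rec.seq).upper()) for rec in msa]
    return AlignmentSet(records=records)


def write_alignment(aln: AlignmentSet, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for label, seq in aln.records:
            fh.write(f">{label}\n{seq}\n")
    return path


# ---------------------------------------------------------------------------
# Volumetric maps: OpenDX and CNS
# ---------------------------------------------------------------------------

def _check_writable_grid(grid: DensityGrid) -> None:
    if not np.all(np.isfinite(grid.values)):
        raise GridError("grid contains non-finite values; refusing to write")


def _write_opendx(grid: DensityGrid, path: Path) -> None:
    nx, ny, nz = grid.dims
    n = nx * ny * nz
    out = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {grid.origin[0]:.6f} {grid.origin[1]:.6f} {grid.origin[2]:.6f}",
        f"delta {grid.spacing[0]:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing[1]:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing[2]:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {n} data follows",
    ]
    flat = grid.values.reshape(-1)  # x fastest-varying last (C order: z fastest)
    for i in range(0, n, 3):
        out.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    out += [
        'attribute "dep" string "positions"',
        'object "density" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    path.write_text("\n".join(out) + "\n")


def _read_opendx(path: Path) -> DensityGrid:
    dims = None
    origin = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line.startswith("object 1 class gridpositions"):
                dims = tuple(int(t) for t in line.split()[-3:])
            elif line.startswith("origin"):
                origin = [float(t) for t in line.split()[1:4]]
            elif line.startswith("delta"):
                deltas.append([float(t) for t in line.split()[1:4]])
            elif "data follows" in line:
                n_items = int(line.split("items")[1].split()[0])
            elif line.startswith(("object", "attribute", "component")):
                continue
            elif n_items is not None and len(values) < n_items:
                values.extend(float(t) for t in line.split())
    if dims is None or origin is None or len(deltas) != 3 or n_items is None:
        raise GridError(f"{path.name}: not a parsable OpenDX scalar map")
    spacing = np.array([deltas[0][0], deltas[1][1], deltas[2][2]])
    vals = np.array(values[:n_items]).reshape(dims)
    return DensityGrid(origin=np.array(origin), spacing=spacing, values=vals)


def _write_cns(grid: DensityGrid, path: Path) -> None:
    # CNS maps address voxels by integer grid indices within a unit cell, so
    # the origin must be an integer multiple of the spacing on each axis.
    nx, ny, nz = grid.dims
    start = grid.origin / grid.spacing
    istart = np.rint(start).astype(int)
    if not np.allclose(start, istart, atol=1e-6):
        raise GridError(
            "CNS maps require the origin to be an integer multiple of the "
            f"spacing; origin/spacing = {start}"
        )
    # Cell spans the written block exactly; NA..NC are the voxel counts.
    a, b, c = (np.array(grid.dims) * grid.spacing)
    lines = [
        "",
        "       2 !NTITLE",
        " REMARKS bulk-normalized probe density (1.0 = bulk)",
        f" REMARKS probe={grid.probe or 'NA'} frames={grid.n_frames}",
        f"{nx:8d}{istart[0]:8d}{istart[0] + nx - 1:8d}"
        f"{ny:8d}{istart[1]:8d}{istart[1] + ny - 1:8d}"
        f"{nz:8d}{istart[2]:8d}{istart[2] + nz - 1:8d}",
        f"{a:12.5E}{b:12.5E}{c:12.5E}{90.0:12.5E}{90.0:12.5E}{90.0:12.5E}",
        "ZYX",
    ]
    for iz in range(nz):
        lines.append(f"{iz:8d}")
        section = grid.values[:, :, iz].T.reshape(-1)  # y outer, x inner
        for i in range(0, section.size, 6):
            lines.append("".join(f"{v:12.5E}" for v in section[i:i + 6]))
    mean = float(grid.values.mean())
    sd = float(grid.values.std())
    lines.append(f"{-9999:8d}")
    lines.append(f"{mean:12.4E}{sd:12.4E}")
    path.write_text("\n".join(lines) + "\n")


def _read_cns(path: Path) -> DensityGrid:
    with open(path) as fh:
        raw = [ln.rstrip("\n") for ln in fh]
    it = iter(raw)
    header = None
    for ln in it:
        toks = ln.split()
        if len(toks) == 9 and all(t.lstrip("+-").isdigit() for t in toks):
            header = [int(t) for t in toks]
            break
    if header is None:
        raise GridError(f"{path.name}: CNS header not found")
    na, amin, amax, nb, bmin, bmax, nc, cmin, cmax = header
    cell_line = next(it)
    cell = [float(cell_line[i:i + 12]) for i in range(0, 72, 12)]
    order = next(it).strip()
    if order != "ZYX":
        raise GridError(f"{path.name}: unsupported CNS section order {order!r}")
    nx, ny, nz = amax - amin + 1, bmax - bmin + 1, cmax - cmin + 1
    spacing = np.array([cell[0] / na, cell[1] / nb, cell[2] / nc])
    values = np.empty((nx, ny, nz))
    per_section = nx * ny
    for iz in range(nz):
        next(it)  # section index line
        flat: list[float] = []
        while len(flat) < per_section:
            ln = next(it)
            flat.extend(float(ln[i:i + 12]) for i in range(0, len(ln.rstrip()), 12))
        values[:, :, iz] = np.array(flat).reshape(ny, nx).T
    origin = np.array([amin, bmin, cmin]) * spacing
    return DensityGrid(origin=origin, spacing=spacing, values=values)


def write_grid(
    grid: DensityGrid,
    path: str | Path,
    dialect: Literal["opendx", "cns"] = "opendx",
) -> Path:
    """Write a density grid as an OpenDX ``.dx`` or CNS-format map.

    Both dialects round-trip origin, spacing and dims through
    :func:`read_grid` (CNS additionally requires the origin to lie on the
    grid lattice, a constraint of that format).
    """
    _check_writable_grid(grid)
    path = Path(path)
    if dialect == "opendx":
        _write_opendx(grid, path)
    elif dialect == "cns":
        _write_cns(grid, path)
    else:
        raise ValueError(f"unknown grid dialect {dialect!r}")
    return path


def read_grid(path: str | Path, dialect: Literal["opendx", "cns"] | None = None) -> DensityGrid:
    """Read a scalar map written by :func:`write_grid` (dialect auto-detected)."""
    path = Path(path)
    if dialect is None:
        head = path.read_text()[:400]
        dialect = "opendx" if "gridpositions" in head else "cns"
    return _read_opendx(path) if dialect == "opendx" else _read_cns(path)
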