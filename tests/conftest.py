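"""Shared fixtures: tiny hand-built PDB texts and structure factories."""

from __future__ import annotations

import numpy as np
import pytest

from allosite.structio import Atom, StructureModel


def atom_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occupancy: float = 1.0,
    element: str = "",
    altloc: str = " ",
    icode: str = " ",
    hetero: bool = False,
) -> str:
    """One fixed-column ATOM/HETATM record."""
    rec = "HETATM" if hetero else "ATOM  "
    padded = f" {name:<3}" if len(name) < 4 else name[:4]
    return (
        f"{rec}{serial:>5} {padded}{altloc}{resname:>3} {chain}{resnum:>4}{icode}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{occupancy:6.2f}{0.0:6.2f}          {element:>2}"
    )


@pytest.fixture
def make_pdb(tmp_path):
    """Write PDB text lines to a temp file and return the path."""
    counter = {"n": 0}

    def _write(lines: list[str], name: str | None = None):
        counter["n"] += 1
        path = tmp_path / (name or f"fixture_{counter['n']}.pdb")
        path.write_text("\n".join(lines) + "\nEND\n")
        return path

    return _write


def simple_structure(coords: np.ndarray, resname: str = "ALA",
                     names: list[str] | None = None) -> StructureModel:
    """A StructureModel from bare coordinates, one atom per row."""
    coords = np.asarray(coords, dtype=float)
    atoms = []
    for i, (x, y, z) in enumerate(coords):
        name = names[i] if names else f"C{i + 1}"
        atoms.append(Atom(chain="A", resnum=i + 1, icode="", resname=resname,
                          name=name, element="C", x=x, y=y, z=z))
    return StructureModel(atoms)
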