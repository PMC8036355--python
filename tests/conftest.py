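"""Shared fixtures: handwritten PDB snippets and synthetic units."""

from __future__ import annotations

import numpy as np
import pytest

from fodm import ResiduePoint, StructureModel, SyntheticSpec, make_micelle


def pdb_line(
    serial: int,
    name: str,
    resname: str,
    chain: str,
    resnum: int,
    x: float,
    y: float,
    z: float,
    occ: float = 1.0,
    altloc: str = " ",
    icode: str = " ",
    record: str = "ATOM",
    element: str | None = None,
) -> str:
    element = (element or name[0]).rjust(2)
    aname = f" {name:<3s}" if len(name) < 4 else name
    return (
        f"{record:<6s}{serial:5d} {aname}{altloc}{resname:>3s} {chain}"
        f"{resnum:4d}{icode}   {x:8.3f}{y:8.3f}{z:8.3f}{occ:6.2f}{0.0:6.2f}"
        f"          {element}"
    )


def write_pdb(path, lines) -> str:
    text = "\n".join(lines + ["END"]) + "\n"
    path.write_text(text)
    return str(path)


@pytest.fixture
def three_ala_pdb(tmp_path):
    """Chain A with three alanines, two atoms each."""
    lines = []
    serial = 1
    for i, x0 in enumerate([0.0, 4.0, 8.0], start=1):
        for name, dx in (("N", 0.0), ("CA", 1.0)):
            lines.append(pdb_line(serial, name, "ALA", "A", i, x0 + dx, 0.0, 0.0))
            serial += 1
    return write_pdb(tmp_path / "three_ala.pdb", lines)


@pytest.fixture
def three_ala_with_waters_pdb(tmp_path):
    lines = []
    serial = 1
    for i, x0 in enumerate([0.0, 4.0, 8.0], start=1):
        lines.append(pdb_line(serial, "CA", "ALA", "A", i, x0, 0.0, 0.0))
        serial += 1
    for j in range(2):
        lines.append(
            pdb_line(serial, "O", "HOH", "A", 100 + j, 20.0 + j, 0.0, 0.0,
                     record="HETATM")
        )
        serial += 1
    return write_pdb(tmp_path / "ala_waters.pdb", lines)


@pytest.fixture
def micelle_unit():
    """A deterministic micelle-like unit used across metric tests."""
    return make_micelle(SyntheticSpec(kind="micelle", n_residues=80, seed=11)).points


def toy_unit(positions, h) -> list[ResiduePoint]:
    """Build a bare unit from coordinates and intrinsic hydrophobicities."""
    return [
        ResiduePoint("A", i + 1, "ALA", np.asarray(p, dtype=float), float(hi))
        for i, (p, hi) in enumerate(zip(positions, h))
    ]


def random_unit(rng: np.random.Generator, n: int, box: float = 25.0) -> list[ResiduePoint]:
    pos = rng.uniform(-box / 2, box / 2, size=(n, 3))
    h = rng.uniform(0.05, 1.0, size=n)
    return toy_unit(pos, h)
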