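"""Structure reading and residue reduction to effective atoms.

Each amino-acid residue is collapsed to a single *effective atom* — the mean
position of its heavy atoms — carrying one intrinsic hydrophobicity value.
All downstream distributions (T, O, R, M) operate on these points only, so a
:class:`StructureModel` is simply an ordered list of :class:`ResiduePoint`
with a record of everything that was excluded and why.

Parsing of PDB and mmCIF files is delegated to :mod:`gemmi`; the residue- and
atom-level filtering rules (waters, hetero molecules, alternate locations,
non-standard residue aliases) live here.
"""

from __future__ import annotations

import csv
import urllib.request
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np

from .errors import EmptyModelError, SelectionError, StructureFormatError
from .scales import AMINO_ACIDS, DEFAULT_SCALE, get_scale

#: Residue-name aliases mapped to their parent standard amino acid.
RESIDUE_ALIASES: dict[str, str] = {
    "MSE": "MET",  # selenomethionine
    "FME": "MET",
    "SEC": "CYS",  # selenocysteine
    "CSO": "CYS",
    "CME": "CYS",
    "OCS": "CYS",
    "SEP": "SER",
    "TPO": "THR",
    "PTR": "TYR",
    "MLY": "LYS",
    "KCX": "LYS",
    "PYL": "LYS",
    "HSD": "HIS",
    "HSE": "HIS",
    "HSP": "HIS",
    "CGU": "GLU",
    "PCA": "GLU",
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}
_BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}


@dataclass(frozen=True)
class ResidueID:
    """Author-assigned residue identity: chain, number, insertion code."""

    chain_id: str
    residue_number: int
    icode: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}:{self.residue_number}{self.icode}"


@dataclass
class ResiduePoint:
    """One residue reduced to an effective atom with an intrinsic hydrophobicity."""

    chain_id: str
    residue_number: int
    residue_name: str
    position: np.ndarray
    intrinsic_h: float | None = None
    icode: str = ""

    @property
    def residue_id(self) -> ResidueID:
        return ResidueID(self.chain_id, self.residue_number, self.icode)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError(f"non-finite position for residue {self.residue_id}")


@dataclass
class StructureModel:
    """Ordered collection of residue points plus the exclusion record."""

    points: list[ResiduePoint]
    source_id: str = ""
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def positions(self) -> np.ndarray:
        return np.array([p.position for p in self.points], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.points:
            seen.setdefault(p.chain_id, None)
        return list(seen)


def effective_atom(atom_positions: Sequence[Sequence[float]]) -> np.ndarray:
    """Arithmetic mean of a residue's heavy-atom positions (the effective atom)."""
    arr = np.asarray(atom_positions, dtype=float)
    if arr.size == 0:
        raise ValueError("effective_atom requires at least one atom position")
    arr = arr.reshape(-1, 3)
    return arr.mean(axis=0)


def _sort_key(p: ResiduePoint) -> tuple[str, int, str]:
    # "" sorts before any letter, so unlettered residues precede insertions.
    return (p.chain_id, p.residue_number, p.icode)


def _select_altlocs(residue: gemmi.Residue) -> list[gemmi.Atom]:
    """Resolve alternate locations: per atom name keep the highest-occupancy
    copy, ties broken by file order; hydrogens discarded."""
    best: dict[str, gemmi.Atom] = {}
    order: list[str] = []
    for atom in residue:
        if atom.is_hydrogen():
            continue
        name = atom.name
        if name not in best:
            best[name] = atom
            order.append(name)
        elif atom.occ > best[name].occ:
            best[name] = atom
    return [best[name] for name in order]


def load_structure(
    source: str | Path,
    fmt: str | None = None,
    side_chain_only: bool = False,
) -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    Parameters
    ----------
    source
        Path to a PDB or mmCIF file.
    fmt
        Force ``"pdb"`` or ``"mmcif"``; by default the format is detected.
    side_chain_only
        Compute effective atoms from side-chain heavy atoms only (backbone
        N, CA, C, O, OXT excluded; glycine falls back to all heavy atoms).
        The default uses all heavy atoms of the residue.
    """
    path = Path(source)
    if not path.exists():
        raise FileNotFoundError(f"structure file not found: {path}")
    coor_format = {
        None: gemmi.CoorFormat.Detect,
        "pdb": gemmi.CoorFormat.Pdb,
        "mmcif": gemmi.CoorFormat.Mmcif,
    }.get(fmt if fmt is None else fmt.lower())
    if coor_format is None:
        raise ValueError(f"unknown format {fmt!r}: expected 'pdb' or 'mmcif'")
    try:
        st = gemmi.read_structure(str(path), format=coor_format)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise StructureFormatError(f"no coordinate model in {path}")

    points: list[ResiduePoint] = []
    skipped: list[tuple[str, str]] = []
    seen_ids: set[ResidueID] = set()
    model = st[0]  # first model only (NMR ensembles use the first state)
    for chain in model:
        for residue in chain:
            num = residue.seqid.num
            icode = residue.seqid.icode.strip()
            rid = ResidueID(chain.name, num, icode)
            name = residue.name.strip().upper()
            if name in _WATER_NAMES:
                skipped.append((str(rid), f"water ({name})"))
                continue
            if name in RESIDUE_ALIASES:
                name = RESIDUE_ALIASES[name]
            elif name not in AMINO_ACIDS:
                skipped.append((str(rid), f"non-standard residue {name}"))
                continue
            if rid in seen_ids:
                skipped.append((str(rid), "duplicate residue id"))
                continue
            atoms = _select_altlocs(residue)
            if side_chain_only:
                side = [a for a in atoms if a.name not in _BACKBONE_ATOMS]
                if side:
                    atoms = side
            if not atoms:
                skipped.append((str(rid), "no heavy atoms"))
                continue
            pos = effective_atom([[a.pos.x, a.pos.y, a.pos.z] for a in atoms])
            if not np.all(np.isfinite(pos)):
                skipped.append((str(rid), "non-finite coordinates"))
                continue
            seen_ids.add(rid)
            points.append(ResiduePoint(chain.name, num, name, pos, icode=icode))

    if not points:
        raise EmptyModelError(f"no standard amino-acid residues in {path}")
    points.sort(key=_sort_key)
    return StructureModel(points=points, source_id=str(path), skipped=skipped)


def assign_hydrophobicity(
    model: StructureModel, scale: str | dict[str, float] = DEFAULT_SCALE
) -> StructureModel:
    """Set each point's intrinsic hydrophobicity from a named or explicit scale."""
    table = get_scale(scale) if isinstance(scale, str) else scale
    for p in model.points:
        try:
            p.intrinsic_h = float(table[p.residue_name])
        except KeyError:
            raise KeyError(
                f"scale has no entry for residue {p.residue_name} ({p.residue_id})"
            ) from None
    return model


# ---------------------------------------------------------------------------
# Selections


@dataclass(frozen=True)
class RangeSelection:
    """One chain with an optional inclusive author-numbered residue range."""

    chain_id: str
    start: int | None = None
    end: int | None = None

    def matches(self, p: ResiduePoint) -> bool:
        if p.chain_id != self.chain_id:
            return False
        if self.start is not None and p.residue_number < self.start:
            return False
        if self.end is not None and p.residue_number > self.end:
            return False
        return True


def parse_selection(text: str) -> RangeSelection:
    """Parse ``"A"``, ``"A:12"`` or ``"A:25-128"`` into a :class:`RangeSelection`."""
    text = text.strip()
    if ":" not in text:
        if not text:
            raise SelectionError("empty selection string")
        return RangeSelection(text)
    chain, _, rng = text.partition(":")
    chain = chain.strip()
    rng = rng.strip()
    if not chain or not rng:
        raise SelectionError(f"malformed selection {text!r}")
    try:
        if "-" in rng.lstrip("-"):
            # split on the dash separating two ints (allow negative author numbers)
            idx = rng.index("-", 1)
            start = int(rng[:idx])
            tail = rng[idx + 1 :]
            end = int(tail) if tail else None  # "A:261-" = open-ended range
        else:
            start = end = int(rng)
    except ValueError:
        raise SelectionError(f"malformed residue range in {text!r}") from None
    if end is not None and end < start:
        raise SelectionError(f"inverted residue range in {text!r}")
    return RangeSelection(chain, start, end)


@dataclass
class SelectionSpec:
    """A named structural unit: union of chain/range selections."""

    name: str
    selections: list[RangeSelection]

    @classmethod
    def from_strings(cls, name: str, texts: Iterable[str]) -> "SelectionSpec":
        return cls(name, [parse_selection(t) for t in texts])


def resolve_unit(model: StructureModel, spec: SelectionSpec) -> list[ResiduePoint]:
    """Resolve a named selection to its ordered residue points.

    Original model ordering is preserved; every referenced chain must exist
    and the result must be non-empty.
    """
    chains = set(model.chains())
    for sel in spec.selections:
        if sel.chain_id not in chains:
            raise SelectionError(
                f"unit {spec.name!r} references missing chain {sel.chain_id!r}"
            )
    unit = [p for p in model.points if any(s.matches(p) for s in spec.selections)]
    if not unit:
        raise SelectionError(f"unit {spec.name!r} resolved to zero residues")
    return unit


# ---------------------------------------------------------------------------
# Points-table round trip (plain CSV; the package's text fixture format)

_TABLE_FIELDS = ["chain", "residue_number", "icode", "residue_name", "x", "y", "z", "intrinsic_h"]


def write_points(points: Sequence[ResiduePoint], path: str | Path) -> None:
    """Write residue points as CSV with full float precision (round-trip safe)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(_TABLE_FIELDS)
        for p in points:
            writer.writerow(
                [
                    p.chain_id,
                    p.residue_number,
                    p.icode,
                    p.residue_name,
                    repr(float(p.position[0])),
                    repr(float(p.position[1])),
                    repr(float(p.position[2])),
                    "" if p.intrinsic_h is None else repr(float(p.intrinsic_h)),
                ]
            )


def read_points(path: str | Path) -> StructureModel:
    """Read a points table written by :func:`write_points`."""
    points: list[ResiduePoint] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _TABLE_FIELDS:
            raise StructureFormatError(f"unexpected points-table header in {path}")
        for row in reader:
            points.append(
                ResiduePoint(
                    chain_id=row["chain"],
                    residue_number=int(row["residue_number"]),
                    residue_name=row["residue_name"],
                    position=np.array(
                        [float(row["x"]), float(row["y"]), float(row["z"])]
                    ),
                    intrinsic_h=(
                        float(row["intrinsic_h"]) if row["intrinsic_h"] != "" else None
                    ),
                    icode=row["icode"],
                )
            )
    if not points:
        raise EmptyModelError(f"empty points table: {path}")
    return StructureModel(points=points, source_id=str(path))


def fetch_structure(pdb_id: str, dest_dir: str | Path = ".") -> Path:
    """Download a PDB entry from the wwPDB (network helper, never used by tests).

    Returns the path of the downloaded ``<id>.pdb`` file.
    """
    pdb_id = pdb_id.lower()
    dest = Path(dest_dir) / f"{pdb_id}.pdb"
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url) as resp, open(dest, "wb") as out:
        out.write(resp.read())
    return dest


def subset_model(model: StructureModel, points: Sequence[ResiduePoint]) -> StructureModel:
    """A new model holding copies of the given points (utility for fragments)."""
    return StructureModel(
        points=[replace(p, position=p.position.copy()) for p in points],
        source_id=model.source_id,
    )
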