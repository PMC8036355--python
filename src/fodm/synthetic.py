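"""Seedable synthetic structural units with known hydrophobicity organization.

Three generators emulate the organizations the model distinguishes:

micelle   isotropic Gaussian cloud, intrinsic hydrophobicity proportional to
          the local Gaussian density — hydrophobic core, polar shell;
channel   cylindrical shell with hydrophobicity increasing radially —
          hydrophobic rim facing the membrane, polar lumen;
uniform   uniform ball with a flat hydrophobicity assignment — no core.

Every generator is a pure function of its spec (including the seed), so any
metric in the package can be tested without downloading real structures.
Positions only mimic the point statistics of effective atoms; no backbone
geometry is attempted.  Residues carry a single placeholder name (ALA) with
intrinsic_h assigned directly, keeping fixtures independent of any scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .structure import ResiduePoint, StructureModel

PLACEHOLDER_RESIDUE = "ALA"

#: Study-condition defaults: a ~200-residue globular domain of ~18 A radius;
#: channel lumen of 6 A; mild (sd 0.1) noise on intrinsic hydrophobicity.
DEFAULT_N = 200
DEFAULT_RADIUS = 18.0
DEFAULT_CHANNEL_RADIUS = 6.0
DEFAULT_NOISE_SD = 0.1


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic unit; validated on construction."""

    kind: str                   # micelle | channel | uniform
    n_residues: int = DEFAULT_N
    seed: int = 0
    radius: float = DEFAULT_RADIUS
    channel_radius: float = DEFAULT_CHANNEL_RADIUS
    noise_sd: float = DEFAULT_NOISE_SD

    def __post_init__(self) -> None:
        if self.kind not in ("micelle", "channel", "uniform"):
            raise ValueError(f"unknown synthetic kind {self.kind!r}")
        if self.n_residues < 10:
            raise ValueError("n_residues must be at least 10")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.kind == "channel" and not (0 < self.channel_radius < self.radius):
            raise ValueError("channel requires radius > channel_radius > 0")


def _to_model(spec: SyntheticSpec, pos: np.ndarray, h: np.ndarray) -> StructureModel:
    points = [
        ResiduePoint(
            chain_id="A",
            residue_number=i + 1,
            residue_name=PLACEHOLDER_RESIDUE,
            position=pos[i],
            intrinsic_h=float(h[i]),
        )
        for i in range(spec.n_residues)
    ]
    return StructureModel(points=points, source_id=f"synthetic:{spec.kind}:{spec.seed}")


def _noisy(rng: np.random.Generator, h: np.ndarray, sd: float) -> np.ndarray:
    if sd > 0:
        h = h + rng.normal(0.0, sd, size=h.shape)
    return np.clip(h, 0.0, None)


def make_micelle(spec: SyntheticSpec) -> StructureModel:
    """Globular micelle-like unit: Gaussian cloud, density-proportional H."""
    if spec.kind != "micelle":
        raise ValueError("spec.kind must be 'micelle'")
    rng = np.random.default_rng(spec.seed)
    s = spec.radius / 3.0
    pos = rng.normal(0.0, s, size=(spec.n_residues, 3))
    h = np.exp(-np.sum(pos**2, axis=1) / (2.0 * s * s))
    return _to_model(spec, pos, _noisy(rng, h, spec.noise_sd))


def make_channel(spec: SyntheticSpec) -> StructureModel:
    """Channel-like unit: a globular cloud with an axial polar channel.

    Points follow the same isotropic Gaussian density as a globule (scale
    radius/3) but are restricted to the cylindrical shell
    channel_radius < rho < radius at heights within +-radius (total height
    2x radius) — a protein wall around a central lumen, densest at
    mid-height and thinning outward like a real residue cloud rather than a
    uniform slab.  Intrinsic hydrophobicity rises monotonically with rho as
    the cube root of the normalized radial depth: the lumen lining is polar
    and the wall is hydrophobic nearly throughout, as in a membrane-buried
    channel wall.
    """
    if spec.kind != "channel":
        raise ValueError("spec.kind must be 'channel'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    s = spec.radius / 3.0
    pos = np.empty((0, 3))
    for _ in range(1000):
        cand = rng.normal(0.0, s, size=(4 * n, 3))
        rho_c = np.hypot(cand[:, 0], cand[:, 1])
        keep = (
            (rho_c > spec.channel_radius)
            & (rho_c < spec.radius)
            & (np.abs(cand[:, 2]) < spec.radius)
        )
        pos = np.vstack([pos, cand[keep]])
        if len(pos) >= n:
            break
    else:
        raise ValueError("channel shell acceptance region too small to sample")
    pos = pos[:n]
    rho = np.hypot(pos[:, 0], pos[:, 1])
    depth = (rho - spec.channel_radius) / (spec.radius - spec.channel_radius)
    h = depth ** (1.0 / 3.0)
    return _to_model(spec, pos, _noisy(rng, h, spec.noise_sd))


def make_uniform(spec: SyntheticSpec) -> StructureModel:
    """Unordered unit: uniform ball, flat intrinsic hydrophobicity (0.5)."""
    if spec.kind != "uniform":
        raise ValueError("spec.kind must be 'uniform'")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_residues
    direction = rng.normal(size=(n, 3))
    direction /= np.linalg.norm(direction, axis=1, keepdims=True)
    r = spec.radius * rng.uniform(0.0, 1.0, size=n) ** (1.0 / 3.0)
    pos = direction * r[:, None]
    h = np.full(n, 0.5)
    return _to_model(spec, pos, _noisy(rng, h, spec.noise_sd))


_MAKERS = {"micelle": make_micelle, "channel": make_channel, "uniform": make_uniform}


def make(spec: SyntheticSpec) -> StructureModel:
    """Dispatch to the generator matching ``spec.kind``."""
    return _MAKERS[spec.kind](spec)


def write_fixture(model: StructureModel, pdb_path: str | Path) -> tuple[Path, Path]:
    """Emit a minimal single-chain PDB plus a sidecar TSV of intrinsic_h.

    The PDB holds one pseudo-atom (CA) per residue at the effective-atom
    position; the sidecar keys intrinsic hydrophobicities by chain and
    residue number.  Output is deterministic, so reruns are byte-identical.
    Returns (pdb_path, sidecar_path).
    """
    pdb_path = Path(pdb_path)
    sidecar = pdb_path.with_suffix(".hydro.tsv")
    with open(pdb_path, "w") as fh:
        for i, p in enumerate(model.points, start=1):
            x, y, z = p.position
            fh.write(
                f"ATOM  {i:5d}  CA  {p.residue_name:>3s} {p.chain_id}"
                f"{p.residue_number:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}           C\n"
            )
        fh.write("END\n")
    with open(sidecar, "w") as fh:
        fh.write("chain\tresidue_number\tintrinsic_h\n")
        for p in model.points:
            fh.write(f"{p.chain_id}\t{p.residue_number}\t{p.intrinsic_h!r}\n")
    return pdb_path, sidecar


def read_sidecar(model: StructureModel, sidecar_path: str | Path) -> StructureModel:
    """Assign intrinsic_h values from a fixture sidecar table onto a model."""
    table: dict[tuple[str, int], float] = {}
    with open(sidecar_path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["chain", "residue_number", "intrinsic_h"]:
            raise ValueError(f"unexpected sidecar header in {sidecar_path}")
        for line in fh:
            chain, num, h = line.rstrip("\n").split("\t")
            table[(chain, int(num))] = float(h)
    for p in model.points:
        key = (p.chain_id, p.residue_number)
        if key in table:
            p.intrinsic_h = table[key]
    return model
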