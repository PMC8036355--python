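"""The 3D Gaussian hydrophobicity field and the T, O, R, M distributions.

The model pictures a water-soluble globular protein as a fuzzy oil drop: the
expected (theoretical) hydrophobicity density is a 3D Gaussian centered on the
molecule, highest in the core and vanishing at the surface.  Four per-residue
distributions are compared, all normalized to sum to 1 over the unit:

T   theoretical — the Gaussian evaluated at each effective atom;
O   observed    — pairwise Levitt-weighted sums of intrinsic hydrophobicities;
R   uniform     — 1/N everywhere, the no-core reference;
M   membrane    — T plus K times the normalized inverted field (Tmax - T)_n,
                  flattening the core and raising the rim, as expected for a
                  protein whose surface faces lipid and whose center is a
                  polar channel.

The Gaussian's sigmas are adjusted to the size of the molecule: along each
principal axis of the residue point cloud, sigma is one third of the maximal
absolute extent (plus an optional margin), so the unit sits within 3 sigma.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateProfileError, FieldFitError
from .structure import ResidueID, ResiduePoint

#: Default Levitt cutoff distance (angstrom) for pairwise hydrophobic contact.
DEFAULT_CUTOFF = 9.0


@dataclass
class GaussianField:
    """Fitted 3D Gaussian: center, principal-axis rotation and per-axis sigmas."""

    center: np.ndarray          # (3,) geometric center, angstrom
    rotation: np.ndarray        # (3, 3) rows are principal axes
    sigmas: np.ndarray          # (3,) strictly positive, angstrom

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.any(self.sigmas <= 0):
            raise ValueError("sigmas must be strictly positive")

    def transform(self, positions: np.ndarray) -> np.ndarray:
        """Map world coordinates into the field's principal-axis frame."""
        return (np.asarray(positions, dtype=float) - self.center) @ self.rotation.T


@dataclass
class HydroProfile:
    """Aligned, normalized T/O/R/M vectors over one structural unit."""

    unit_name: str
    residue_ids: list[ResidueID]
    T: np.ndarray
    O: np.ndarray
    R: np.ndarray
    M: np.ndarray
    T_max: float
    K: float

    def __post_init__(self) -> None:
        n = len(self.residue_ids)
        for name in ("T", "O", "R", "M"):
            v = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, v)
            if v.shape != (n,):
                raise ValueError(f"{name} has length {v.shape}, expected ({n},)")
            if np.any(v < 0):
                raise ValueError(f"{name} has negative entries")
            if abs(v.sum() - 1.0) > 1e-9:
                raise ValueError(f"{name} does not sum to 1 (sum={v.sum()!r})")

    @property
    def n(self) -> int:
        return len(self.residue_ids)


def _positions(unit: Sequence[ResiduePoint]) -> np.ndarray:
    return np.array([p.position for p in unit], dtype=float)


def fit_gaussian(unit: Sequence[ResiduePoint], margin: float = 0.0) -> GaussianField:
    """Fit the molecule-sized 3D Gaussian to a structural unit.

    center = mean effective-atom position; axes = principal components of the
    centered cloud in descending variance; sigma_a = (max |coordinate along
    axis a| + margin) / 3.  Axis signs are fixed deterministically: each axis
    keeps a non-negative dot product with the matching global axis (+x, +y,
    +z); an exactly perpendicular axis has its first non-zero component made
    positive.  If the resulting frame is left-handed the last axis is flipped
    back so the rotation has determinant +1.
    """
    pos = _positions(unit)
    if len(pos) < 3:
        raise FieldFitError(f"need at least 3 residues to fit a field, got {len(pos)}")
    center = pos.mean(axis=0)
    centered = pos - center
    cov = centered.T @ centered / len(pos)
    evals, evecs = np.linalg.eigh(cov)          # ascending
    order = np.argsort(evals)[::-1]
    axes = evecs[:, order].T                    # rows, descending variance
    for a in range(3):
        d = axes[a, a]
        if d < 0:
            axes[a] = -axes[a]
        elif d == 0:
            nz = np.nonzero(axes[a])[0]
            if nz.size and axes[a, nz[0]] < 0:
                axes[a] = -axes[a]
    if np.linalg.det(axes) < 0:
        axes[2] = -axes[2]
    local = centered @ axes.T
    extents = np.abs(local).max(axis=0) + margin
    if np.any(extents <= 0):
        raise FieldFitError(
            "degenerate unit: zero extent along a principal axis (collinear or "
            "coincident residues); a positive margin may be supplied"
        )
    return GaussianField(center=center, rotation=axes, sigmas=extents / 3.0)


def theoretical_profile(
    unit: Sequence[ResiduePoint], gfield: GaussianField
) -> np.ndarray:
    """Normalized 3D Gaussian evaluated at the unit's effective atoms (T)."""
    local = gfield.transform(_positions(unit))
    expo = -0.5 * np.sum((local / gfield.sigmas) ** 2, axis=1)
    raw = np.exp(expo)
    total = raw.sum()
    if total <= 0:
        raise DegenerateProfileError("theoretical profile sums to zero")
    return raw / total


def levitt_weight(r, c: float = DEFAULT_CUTOFF):
    """Levitt's smooth contact function on inter-residue distance r.

    1 - 1/2 (7 t^2 - 9 t^4 + 5 t^6 - t^8) with t = r/c for r <= c, and 0
    beyond the cutoff; equals 1 at r = 0 and falls smoothly to 0 at r = c.
    Accepts scalars or arrays.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distance r must be non-negative")
    if c <= 0:
        raise ValueError("cutoff c must be positive")
    t2 = (r / c) ** 2
    w = 1.0 - 0.5 * (7.0 * t2 - 9.0 * t2**2 + 5.0 * t2**3 - t2**4)
    w = np.where(r <= c, w, 0.0)
    return float(w) if w.ndim == 0 else w


def observed_profile(unit: Sequence[ResiduePoint], c: float = DEFAULT_CUTOFF) -> np.ndarray:
    """Observed hydrophobicity O from pairwise Levitt-weighted interactions.

    O~_i = sum_{j != i} (H_i + H_j) w(d_ij, c), normalized to a simplex
    vector.  Residue pairs farther apart than the cutoff contribute nothing.
    """
    h = np.array([p.intrinsic_h for p in unit], dtype=float)
    if np.any([p.intrinsic_h is None for p in unit]):
        raise ValueError("intrinsic_h must be assigned to every residue")
    if np.any(h < 0):
        raise ValueError("intrinsic hydrophobicities must be non-negative")
    pos = _positions(unit)
    if len(pos) == 1:
        raise DegenerateProfileError("observed profile undefined for a single residue")
    w = squareform(levitt_weight(pdist(pos), c))       # zero diagonal: j != i
    pair_h = h[:, None] + h[None, :]
    raw = (pair_h * w).sum(axis=1)
    total = raw.sum()
    if total <= 0:
        raise DegenerateProfileError(
            "observed profile is all zero (no contacts within the cutoff or all "
            "intrinsic hydrophobicities zero)"
        )
    return raw / total


def uniform_profile(n: int) -> np.ndarray:
    """The no-core reference R: hydrophobicity 1/N at every residue."""
    if n < 1:
        raise ValueError("uniform profile needs at least one residue")
    return np.full(n, 1.0 / n)


def membrane_profile(T: np.ndarray, K: float = 1.0) -> np.ndarray:
    """Membrane-environment reference M = [T + K (Tmax - T)_n]_n.

    The inverted field Tmax - T is normalized first (subscript n), scaled by
    the environment coefficient K, added to T, and the sum renormalized.
    K = 0 reduces exactly to T (purely polar surroundings); K = 1 is the
    membrane-channel setting, an equal-weight consensus of T and its inverse.
    """
    T = np.asarray(T, dtype=float)
    if K < 0:
        raise ValueError("K must be non-negative")
    if abs(T.sum() - 1.0) > 1e-9:
        raise ValueError("T must be normalized before building M")
    if K == 0:
        return T.copy()
    inv = T.max() - T
    inv_total = inv.sum()
    if inv_total <= 0:
        raise DegenerateProfileError(
            "inverted field is all zero (T is exactly uniform); M undefined for K > 0"
        )
    raw = T + K * inv / inv_total
    return raw / raw.sum()


def unit_profile(
    unit: Sequence[ResiduePoint],
    K: float = 1.0,
    c: float = DEFAULT_CUTOFF,
    margin: float = 0.0,
    unit_name: str = "unit",
    gfield: GaussianField | None = None,
) -> tuple[HydroProfile, GaussianField]:
    """Compute all four distributions for a unit; fit the field unless given."""
    if gfield is None:
        gfield = fit_gaussian(unit, margin=margin)
    T = theoretical_profile(unit, gfield)
    O = observed_profile(unit, c=c)
    profile = HydroProfile(
        unit_name=unit_name,
        residue_ids=[p.residue_id for p in unit],
        T=T,
        O=O,
        R=uniform_profile(len(unit)),
        M=membrane_profile(T, K),
        T_max=float(T.max()),
        K=K,
    )
    return profile, gfield
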