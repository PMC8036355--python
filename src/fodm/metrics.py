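"""RD statistics: Kullback-Leibler comparison of observed vs reference fields.

The observed distribution O is compared against the theoretical Gaussian T
and against a second reference — either the uniform no-core distribution R or
the membrane field M.  Because a raw D_KL value has no absolute meaning, the
relative distance

    RD = D_KL(O||T) / (D_KL(O||T) + D_KL(O||Ref))

places O on a 0..1 axis between the two references.  RD < 0.5 for the T-O-R
relation means O is closer to the Gaussian than to uniform: a hydrophobic
core is present.  RD_{T-O-M} > RD_{T-O-R} means O is closer to the membrane
field than to uniform — the signature of a membrane-adapted unit.

A unit may be scored with its own fitted field ("individual") or as a
fragment of a larger parent ("in_parent"): the parent's T/O/M values at the
fragment's residues are renormalized over the fragment, so no new field is
fitted.  Residue elimination works the same way — the field of the full unit
stands while the profiles are restricted and renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .errors import SelectionError, SupportError, UndefinedRDError
from .field import (
    DEFAULT_CUTOFF,
    GaussianField,
    HydroProfile,
    uniform_profile,
    unit_profile,
)
from .structure import ResidueID, ResiduePoint, StructureModel

CORE_PRESENT = "core_present"
NO_CORE = "no_core"
MEMBRANE_LIKE = "membrane_like"


@dataclass
class FODResult:
    """Divergences, RD statistics and classification for one structural unit."""

    unit_name: str
    N: int
    dkl_OT: float       # bits
    dkl_OR: float
    dkl_OM: float
    rd_TOR: float
    rd_TOM: float
    K: float
    classification: str
    eliminated: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "unit": self.unit_name,
            "N": self.N,
            "dkl_OT_bits": self.dkl_OT,
            "dkl_OR_bits": self.dkl_OR,
            "dkl_OM_bits": self.dkl_OM,
            "rd_TOR": self.rd_TOR,
            "rd_TOM": self.rd_TOM,
            "K": self.K,
            "classification": self.classification,
            "eliminated": list(self.eliminated),
        }


def kl_divergence(P: np.ndarray, Q: np.ndarray) -> float:
    """D_KL(P||Q) in bits, with the convention 0 * log(0/q) = 0.

    No epsilon smoothing is applied: mass of P on a zero of Q raises
    :class:`SupportError` rather than silently producing a finite number.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise ValueError("P and Q must have equal length")
    mask = P > 0
    if np.any(Q[mask] <= 0):
        raise SupportError("P places mass where Q is zero; D_KL undefined")
    return float(np.sum(P[mask] * np.log2(P[mask] / Q[mask])))


def rd(O: np.ndarray, T: np.ndarray, Ref: np.ndarray) -> float:
    """Relative distance of O between T and a second reference distribution."""
    d_ot = kl_divergence(O, T)
    d_or = kl_divergence(O, Ref)
    total = d_ot + d_or
    if total == 0:
        raise UndefinedRDError("O equals both references; RD is 0/0")
    return d_ot / total


def classify(rd_TOR: float, rd_TOM: float) -> str:
    """Label a unit from its two RD statistics.

    RD_{T-O-R} strictly below 0.5 means a hydrophobic core is present.  At or
    above 0.5 the unit has no core; if additionally O sits closer to the
    membrane field than to uniform (RD_{T-O-M} > RD_{T-O-R}) the unit is
    reported as membrane-like.
    """
    if rd_TOR < 0.5:
        return CORE_PRESENT
    if rd_TOM > rd_TOR:
        return MEMBRANE_LIKE
    return NO_CORE


def _result_from_vectors(
    unit_name: str,
    ids: Sequence[ResidueID],
    T: np.ndarray,
    O: np.ndarray,
    M: np.ndarray,
    K: float,
    eliminated: Sequence[ResidueID] = (),
) -> FODResult:
    R = uniform_profile(len(ids))
    dkl_OT = kl_divergence(O, T)
    dkl_OR = kl_divergence(O, R)
    dkl_OM = kl_divergence(O, M)
    if dkl_OT + dkl_OR == 0:
        raise UndefinedRDError("O equals both T and R; RD is 0/0")
    if dkl_OT + dkl_OM == 0:
        raise UndefinedRDError("O equals both T and M; RD is 0/0")
    rd_TOR = dkl_OT / (dkl_OT + dkl_OR)
    rd_TOM = dkl_OT / (dkl_OT + dkl_OM)
    return FODResult(
        unit_name=unit_name,
        N=len(ids),
        dkl_OT=dkl_OT,
        dkl_OR=dkl_OR,
        dkl_OM=dkl_OM,
        rd_TOR=rd_TOR,
        rd_TOM=rd_TOM,
        K=K,
        classification=classify(rd_TOR, rd_TOM),
        eliminated=[str(r) for r in eliminated],
    )


def _renorm(v: np.ndarray) -> np.ndarray:
    total = v.sum()
    if total <= 0:
        raise UndefinedRDError("fragment carries zero mass; cannot renormalize")
    return v / total


def fragment_profile(parent: HydroProfile, ids: Sequence[ResidueID], unit_name: str) -> HydroProfile:
    """Restrict a parent profile to a fragment and renormalize T, O and M.

    The uniform reference is rebuilt as 1/n over the fragment.  Restricting to
    the full parent is the identity.
    """
    index = {rid: i for i, rid in enumerate(parent.residue_ids)}
    try:
        idx = np.array([index[rid] for rid in ids], dtype=int)
    except KeyError as exc:
        raise SelectionError(f"residue {exc.args[0]} not part of the parent unit") from None
    if idx.size == 0:
        raise SelectionError("empty fragment")
    T = _renorm(parent.T[idx])
    return HydroProfile(
        unit_name=unit_name,
        residue_ids=list(ids),
        T=T,
        O=_renorm(parent.O[idx]),
        R=uniform_profile(idx.size),
        M=_renorm(parent.M[idx]),
        T_max=float(T.max()),
        K=parent.K,
    )


def unit_status(
    unit: Sequence[ResiduePoint],
    K: float = 1.0,
    mode: str = "individual",
    parent: HydroProfile | None = None,
    c: float = DEFAULT_CUTOFF,
    margin: float = 0.0,
    unit_name: str = "unit",
    gfield: GaussianField | None = None,
) -> FODResult:
    """Score one structural unit.

    ``individual`` fits a fresh field on the unit and computes T/O/R/M there;
    ``in_parent`` takes the parent profile's values at the unit's residues and
    renormalizes each over the unit, so the parent's field stands.
    """
    if mode == "individual":
        profile, _ = unit_profile(
            unit, K=K, c=c, margin=margin, unit_name=unit_name, gfield=gfield
        )
    elif mode == "in_parent":
        if parent is None:
            raise ValueError("in_parent mode requires the parent HydroProfile")
        profile = fragment_profile(parent, [p.residue_id for p in unit], unit_name)
        K = parent.K
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return _result_from_vectors(
        unit_name, profile.residue_ids, profile.T, profile.O, profile.M, K
    )


def status_from_profile(profile: HydroProfile) -> FODResult:
    """FODResult for an already-computed profile (no re-fitting)."""
    return _result_from_vectors(
        profile.unit_name, profile.residue_ids, profile.T, profile.O, profile.M, profile.K
    )


def parse_residue_id(text: str) -> ResidueID:
    """Parse ``"A:35"`` (optionally with an insertion code, ``"A:35B"``)."""
    chain, _, rest = text.strip().partition(":")
    if not chain or not rest:
        raise ValueError(f"malformed residue id {text!r}; expected CHAIN:NUMBER")
    num = rest
    icode = ""
    if rest and rest[-1].isalpha():
        num, icode = rest[:-1], rest[-1]
    return ResidueID(chain, int(num), icode)


def eliminate_residues(
    unit: Sequence[ResiduePoint],
    exclude: Iterable[ResidueID | str],
    K: float = 1.0,
    c: float = DEFAULT_CUTOFF,
    margin: float = 0.0,
    unit_name: str = "unit",
) -> FODResult:
    """Score a unit with selected residues removed from the comparison.

    The field fitted on the full unit stands; T, O and M are restricted to the
    remaining residues and renormalized, R is rebuilt as 1/n.  Used to probe
    whether a few discordant residues (catalytic sites, interface patches)
    carry the whole mismatch.
    """
    excl = {e if isinstance(e, ResidueID) else parse_residue_id(e) for e in exclude}
    members = {p.residue_id for p in unit}
    missing = excl - members
    if missing:
        raise SelectionError(
            f"excluded residues not in unit: {sorted(str(r) for r in missing)}"
        )
    keep = [p.residue_id for p in unit if p.residue_id not in excl]
    if not keep:
        raise SelectionError("cannot eliminate every residue of the unit")
    full, _ = unit_profile(unit, K=K, c=c, margin=margin, unit_name=unit_name)
    frag = fragment_profile(full, keep, unit_name)
    result = _result_from_vectors(unit_name, keep, frag.T, frag.O, frag.M, K,
                                  eliminated=sorted(excl, key=str))
    return result


@dataclass
class DiscordanceRecord:
    """One residue's T/O mismatch, signed: O above T is a hydrophobicity excess."""

    residue_id: ResidueID
    T: float
    O: float
    delta: float        # O - T
    label: str          # excess / deficiency / accordant


def rank_discordance(profile: HydroProfile) -> list[DiscordanceRecord]:
    """Residues ordered by |T - O| descending (the elimination candidates).

    Ties broken by O - T descending (excess first), then by residue order.
    """
    delta = profile.O - profile.T
    order = sorted(
        range(profile.n), key=lambda i: (-abs(delta[i]), -delta[i], i)
    )
    records = []
    for i in order:
        d = float(delta[i])
        label = "accordant" if d == 0 else ("excess" if d > 0 else "deficiency")
        records.append(
            DiscordanceRecord(
                residue_id=profile.residue_ids[i],
                T=float(profile.T[i]),
                O=float(profile.O[i]),
                delta=d,
                label=label,
            )
        )
    return records


def interface_residues(
    model: StructureModel,
    unit_chains: str | Sequence[str],
    other_chains: str | Sequence[str],
    cutoff: float = DEFAULT_CUTOFF,
) -> set[ResidueID]:
    """Residues of ``unit_chains`` whose effective atom lies within ``cutoff``
    of any effective atom of ``other_chains`` (inter-chain contact set)."""
    if isinstance(unit_chains, str):
        unit_chains = [unit_chains]
    if isinstance(other_chains, str):
        other_chains = [other_chains]
    unit_pts = [p for p in model.points if p.chain_id in set(unit_chains)]
    other_pts = [p for p in model.points if p.chain_id in set(other_chains)]
    if not unit_pts or not other_pts:
        raise SelectionError("interface query needs non-empty chain sets on both sides")
    tree = cKDTree(np.array([p.position for p in other_pts]))
    hits = tree.query_ball_point(np.array([p.position for p in unit_pts]), r=cutoff)
    return {p.residue_id for p, h in zip(unit_pts, hits) if h}
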