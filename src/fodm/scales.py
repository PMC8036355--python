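"""Intrinsic residue hydrophobicity scales.

The observed hydrophobicity distribution O is built from pairwise Levitt-weighted
sums of per-residue intrinsic hydrophobicities H^r.  The literature on
hydrophobicity-distribution scoring does not agree on a single canonical scale,
so two named scales are bundled, both mapped onto [0, 1] so that every residue
contributes a non-negative weight:

``kyte_doolittle``
    The Kyte-Doolittle hydropathy index, affinely rescaled from its native
    range [-4.5, 4.5] to [0, 1].

``aggregate`` (default)
    The per-residue mean of three classical scales (Kyte-Doolittle hydropathy,
    the Eisenberg consensus scale, and the Fauchere-Pliska octanol partition
    scale), each min-max normalized to [0, 1] before averaging.  Averaging
    damps the idiosyncrasies of any single experimental scale.

The scale in use is recorded in every report so results are reproducible.
"""

from __future__ import annotations

AMINO_ACIDS = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

# Kyte & Doolittle hydropathy index (native units).
_KYTE_DOOLITTLE = {
    "ALA": 1.8, "ARG": -4.5, "ASN": -3.5, "ASP": -3.5, "CYS": 2.5,
    "GLN": -3.5, "GLU": -3.5, "GLY": -0.4, "HIS": -3.2, "ILE": 4.5,
    "LEU": 3.8, "LYS": -3.9, "MET": 1.9, "PHE": 2.8, "PRO": -1.6,
    "SER": -0.8, "THR": -0.7, "TRP": -0.9, "TYR": -1.3, "VAL": 4.2,
}

# Eisenberg consensus scale.
_EISENBERG = {
    "ALA": 0.62, "ARG": -2.53, "ASN": -0.78, "ASP": -0.90, "CYS": 0.29,
    "GLN": -0.85, "GLU": -0.74, "GLY": 0.48, "HIS": -0.40, "ILE": 1.38,
    "LEU": 1.06, "LYS": -1.50, "MET": 0.64, "PHE": 1.19, "PRO": 0.12,
    "SER": -0.18, "THR": -0.05, "TRP": 0.81, "TYR": 0.26, "VAL": 1.08,
}

# Fauchere & Pliska octanol/water partition (pi) scale.
_FAUCHERE_PLISKA = {
    "ALA": 0.31, "ARG": -1.01, "ASN": -0.60, "ASP": -0.77, "CYS": 1.54,
    "GLN": -0.22, "GLU": -0.64, "GLY": 0.00, "HIS": 0.13, "ILE": 1.80,
    "LEU": 1.70, "LYS": -0.99, "MET": 1.23, "PHE": 1.79, "PRO": 0.72,
    "SER": -0.04, "THR": 0.26, "TRP": 2.25, "TYR": 0.96, "VAL": 1.22,
}


def _minmax(raw: dict[str, float]) -> dict[str, float]:
    lo = min(raw.values())
    hi = max(raw.values())
    return {aa: (v - lo) / (hi - lo) for aa, v in raw.items()}


def _aggregate() -> dict[str, float]:
    parts = [_minmax(_KYTE_DOOLITTLE), _minmax(_EISENBERG), _minmax(_FAUCHERE_PLISKA)]
    return {aa: sum(p[aa] for p in parts) / len(parts) for aa in AMINO_ACIDS}


SCALES: dict[str, dict[str, float]] = {
    "kyte_doolittle": _minmax(_KYTE_DOOLITTLE),
    "aggregate": _aggregate(),
}

DEFAULT_SCALE = "aggregate"


def get_scale(name: str = DEFAULT_SCALE) -> dict[str, float]:
    """Return the named scale as a residue-name -> H^r mapping in [0, 1]."""
    try:
        return dict(SCALES[name])
    except KeyError:
        raise KeyError(
            f"unknown hydrophobicity scale {name!r}; available: {sorted(SCALES)}"
        ) from None
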