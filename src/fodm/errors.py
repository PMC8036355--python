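"""Exception hierarchy for structure handling and profile computation."""


class FodmError(Exception):
    """Base class for all package-specific errors."""


class StructureFormatError(FodmError):
    """The input file could not be parsed in the requested format."""


class EmptyModelError(FodmError):
    """No standard amino-acid residues could be extracted from the input."""


class SelectionError(FodmError):
    """A unit selection resolved to nothing or referenced a missing chain."""


class FieldFitError(FodmError):
    """The 3D Gaussian field cannot be fitted (too few or degenerate points)."""


class DegenerateProfileError(FodmError):
    """A profile collapsed to all zeros and cannot be normalized."""


class SupportError(FodmError):
    """Kullback-Leibler divergence undefined: P places mass where Q has none."""


class UndefinedRDError(FodmError):
    """RD is 0/0: the observed distribution equals both references."""
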