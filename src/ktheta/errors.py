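"""Exception hierarchy for the ktheta package."""


class KThetaError(Exception):
    """Base class for all package-specific failures."""


class AlignmentError(KThetaError, ValueError):
    """Malformed alignment: ragged rows, duplicate ids, empty input, bad window."""


class NoComparableSitesError(KThetaError, ValueError):
    """A sequence pair shares no sites with unambiguous bases on both rows."""


class SaturationError(KThetaError, ArithmeticError):
    """A distance correction hit the boundary of its domain (log argument <= 0).

    The observed substitution proportions are too large for the model; the
    pair is effectively saturated and its corrected distance is undefined.
    """


class TreeError(KThetaError, ValueError):
    """Invalid tree operation (too few taxa, asymmetric input matrix, ...)."""


class OutgroupError(TreeError):
    """The requested outgroup is empty, covers all leaves, or is not monophyletic."""


class ConfigError(KThetaError, ValueError):
    """Invalid or incomplete run configuration."""
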