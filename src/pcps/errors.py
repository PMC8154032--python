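"""Exception types shared across the package."""


class PcpsError(ValueError):
    """Base class for all domain errors."""


class InvalidCoordinateError(PcpsError):
    """A fragment coordinate falls outside the substrate or violates i <= j."""


class ParameterError(PcpsError):
    """An enumeration or tolerance parameter violates its invariants."""


class UnknownResidueError(PcpsError):
    """A sequence contains a character outside the 20-letter amino-acid alphabet."""


class InvalidChargeError(PcpsError):
    """A charge state outside the supported positive range was requested."""


class ModificationCountError(PcpsError):
    """More copies of a chemical modification than its per-peptide maximum."""


class DataError(PcpsError):
    """Malformed external data (peak lists, profiles, affinity tables)."""
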