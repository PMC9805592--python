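"""Exception hierarchy shared across grappi modules."""


class GrappiError(Exception):
    """Base class for all grappi errors."""


class ChainNotFoundError(GrappiError):
    """A requested chain id does not occur in the coordinate file."""


class ParseError(GrappiError):
    """A coordinate or PSSM file could not be parsed."""


class NoInterfaceError(GrappiError):
    """No cross-chain residue pair falls within the interface cutoff."""


class PssmError(GrappiError):
    """A PSSM profile is missing, misaligned or malformed."""


class SchemaError(GrappiError):
    """An HDF5 group does not conform to the graph storage schema."""
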