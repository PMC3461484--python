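"""Exception hierarchy.

The CLI maps these onto distinct exit codes (see ``topoconv.cli``), so the
split between parse errors (malformed text), structural errors (well-formed
text describing an inconsistent system), geometry, parameter and
external-tool failures is part of the public contract.
"""


class TopoconvError(Exception):
    """Base class for all package errors."""


class ParseError(TopoconvError):
    """Input text could not be tokenised/interpreted."""


class StructuralError(TopoconvError):
    """Input parsed but describes an inconsistent system."""


class GeometryError(TopoconvError):
    """Covalent geometry failed the distance sanity filter."""


class MissingParameterError(TopoconvError):
    """A bonded/nonbonded parameter was not found in any source."""


class NetChargeError(TopoconvError):
    """Partial charges do not sum to an acceptable integer."""


class ExternalToolError(TopoconvError):
    """An optional external binary failed."""


class ExternalToolMissingError(ExternalToolError):
    """The requested external binary is not installed/discoverable."""


class ExternalToolTimeoutError(ExternalToolError):
    """The external binary exceeded its wall-clock limit."""
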