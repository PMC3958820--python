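"""Exception hierarchy."""


class LipidMCError(Exception):
    """Base class for all package errors."""


class ParameterFileError(LipidMCError):
    """Malformed parameter file; message names the offending line."""


class TopologyError(LipidMCError):
    """Bond graph is not a tree, or indices are inconsistent."""


class ConfigurationError(LipidMCError):
    """A start structure cannot be built (missing equilibrium values, overlaps)."""


class PlanError(LipidMCError):
    """Move-plan entry is invalid for the given topology."""


class GeometryError(LipidMCError):
    """Undefined internal coordinate (collinear angle, coincident axis atoms)."""


class OverlapError(LipidMCError):
    """Two non-bonded atoms closer than the hard-core limit."""


class MappingError(LipidMCError):
    """Structure file does not match the topology."""


class AnalysisError(LipidMCError):
    """Observable undefined for the given trajectory."""
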