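"""Exception hierarchy shared across the pipeline."""


class OtudelimError(Exception):
    """Base class for all package errors."""


class InputError(OtudelimError):
    """Malformed or inconsistent user input (files, tables, labels)."""


class AlignmentError(InputError):
    """Alignment-specific input problem (ragged records, illegal characters)."""


class UndefinedDistanceError(OtudelimError):
    """A pairwise distance cannot be computed (zero comparable sites)."""


class SaturationError(OtudelimError):
    """Observed divergence outside the domain of the distance correction."""


class TreeError(OtudelimError):
    """Tree input or structural problem (duplicate tips, unknown labels)."""


class UltrametricError(TreeError):
    """Tree violates the ultrametricity requirement beyond tolerance."""


class OptimizationError(OtudelimError):
    """Likelihood optimizer failed to converge."""


class PartitionError(OtudelimError):
    """Partition is inconsistent with the sample set it should cover."""
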