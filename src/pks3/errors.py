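"""Exception hierarchy."""


class Pks3Error(Exception):
    """Base class for all pks3 errors."""


class EmptyInputError(Pks3Error):
    """An input file or sequence set contained no usable records."""


class InvalidResidueError(Pks3Error):
    """A sequence contained a character outside the amino-acid alphabet."""


class AnnotationError(Pks3Error):
    """A reference profile annotation is out of range or self-inconsistent."""


class DuplicateIdError(Pks3Error):
    """Two records or table rows share a sequence id."""


class AlignmentError(Pks3Error):
    """Pairwise or multiple alignment could not be computed or validated."""


class DistanceError(Pks3Error):
    """An evolutionary distance could not be estimated."""


class NoDomainError(Pks3Error):
    """No type III PKS domain could be located in a fusion sequence."""


class TreeError(Pks3Error):
    """A tree operation received an invalid tree or unknown taxon."""
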