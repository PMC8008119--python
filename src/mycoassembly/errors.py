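"""Exception hierarchy.

Every contract violation raises a distinct, named error so callers (and the
pipeline driver) can report which stage and which datum failed.
"""


class MycoassemblyError(Exception):
    """Base class for all package errors."""


class DuplicateIdError(MycoassemblyError):
    """Sample or OTU identifiers are not unique."""


class RaggedTableError(MycoassemblyError):
    """A tabular input has rows of unequal length."""


class NegativeCountError(MycoassemblyError):
    """A count cell is negative."""


class NonIntegerCountError(MycoassemblyError):
    """A count cell is not an integer (read counts are integral)."""


class NewickError(MycoassemblyError):
    """Malformed Newick string or missing branch lengths."""


class MissingTaxonError(MycoassemblyError):
    """An OTU in the table is absent from the phylogeny."""


class DegenerateInputError(MycoassemblyError):
    """Input is structurally valid but the statistic is undefined on it
    (e.g. all-zero sample pair in Bray-Curtis, constant variable in envfit)."""


class NotRarefiedError(MycoassemblyError):
    """Row sums are unequal where a rarefied table is required."""


class CoordinateError(MycoassemblyError):
    """Latitude/longitude out of range."""


class ConfigError(MycoassemblyError):
    """Invalid run or simulation configuration."""
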