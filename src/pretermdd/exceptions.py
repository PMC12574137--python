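"""Exception hierarchy shared across the package.

Two broad failure classes are distinguished because the command-line
interface maps them to different exit codes: configuration problems
(exit 2) and data problems (exit 3).
"""


class PretermDDError(Exception):
    """Base class for all package errors."""


class ConfigurationError(PretermDDError, ValueError):
    """A simulation or pipeline configuration is invalid."""


class DataError(PretermDDError, ValueError):
    """Input data violate a precondition (bad values, missing columns...)."""


class DegenerateModelError(DataError):
    """A model cannot be estimated at all (e.g. constant outcome)."""


class OntologyLookupError(PretermDDError, KeyError):
    """A term is absent from the ontology graph."""
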