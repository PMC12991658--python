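"""Exception hierarchy used across the package."""


class FinestabError(Exception):
    """Base class for all package-specific errors."""


class ParseError(FinestabError):
    """A genotype/phenotype/label/annotation file could not be parsed."""


class EmptyInputError(FinestabError):
    """An operation received (or produced) zero variants or zero samples."""


class ParameterError(FinestabError, ValueError):
    """An invalid parameter value was supplied."""


class DegenerateInputError(FinestabError):
    """Input is degenerate for the requested statistic (e.g. constant phenotype)."""


class DegenerateSignalError(DegenerateInputError):
    """The genetic signal X @ b is constant, so no noise scale achieves the target phi."""


class LabelError(FinestabError):
    """Population labels are missing or inconsistent with the requested scenario."""


class ConfigError(FinestabError):
    """A run configuration failed schema validation."""
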