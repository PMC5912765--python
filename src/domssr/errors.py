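"""Exception taxonomy shared across the package."""


class DomssrError(Exception):
    """Base class for all domssr errors."""


class BandFormatError(DomssrError, ValueError):
    """A band label does not follow the PRIMER.SIZE convention."""


class LoadError(DomssrError, ValueError):
    """A genotype or metadata table violates its contract at load time."""


class CoverageError(DomssrError, ValueError):
    """A partition does not cover the matrix individuals exactly once."""


class ContractError(DomssrError, ValueError):
    """An in-memory object handed to an operation violates a precondition."""


class InsufficientDataError(DomssrError, ValueError):
    """Not enough non-missing calls to evaluate a statistic."""


class UndefinedPairError(DomssrError, ValueError):
    """A pairwise comparison has no informative bands (a + b + c = 0)."""


class GroupNameError(DomssrError, KeyError):
    """A named group does not exist in the partition."""


class ConfigError(DomssrError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class SizeError(DomssrError, ValueError):
    """An input is too small for the requested operation."""


class FitError(DomssrError, ValueError):
    """A curve fit cannot be performed on the available points."""


class NoCrossingError(DomssrError, ValueError):
    """A fitted decay curve never crosses the requested threshold."""
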