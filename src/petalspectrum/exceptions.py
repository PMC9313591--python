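"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`PetalSpectrumError`,
so pipeline callers can catch one base class.
"""


class PetalSpectrumError(Exception):
    """Base class for all package errors."""


class InputError(PetalSpectrumError, ValueError):
    """Invalid argument values or parameter combinations."""


class FormatError(PetalSpectrumError, ValueError):
    """Malformed tabular/newick/raster input; carries a row or path context."""


class DegeneracyError(PetalSpectrumError, ValueError):
    """Geometrically or numerically degenerate configuration."""


class MappingError(PetalSpectrumError, KeyError):
    """Identifier present in one table but missing from its companion."""


class CollinearityError(PetalSpectrumError, ValueError):
    """Singular regression design (e.g. a shift edge confounded with the intercept)."""


class InsufficientBlocksError(PetalSpectrumError, ValueError):
    """Fewer than two usable jackknife blocks."""


class ValidationError(PetalSpectrumError, ValueError):
    """Aggregated configuration-validation failure (lists every violation)."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("configuration invalid:\n" + "\n".join(f"- {p}" for p in self.problems))
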