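"""Exception hierarchy for the xmapqc package.

``XmapError`` is the common base; the CLI maps subclasses onto exit codes
(config/usage problems -> 1, data/format problems -> 2).
"""


class XmapError(Exception):
    """Base class for all xmapqc errors."""


class FormatError(XmapError):
    """A run workbook (or other input file) violates the expected dialect."""


class MergeError(XmapError):
    """Run-file fragments cannot be combined into one run."""


class ConfigError(XmapError):
    """Invalid or inconsistent configuration / options."""


class FitError(XmapError):
    """A titration cannot be fitted (e.g. under-determined)."""


class DomainError(XmapError):
    """An argument is outside the mathematical domain of an operation."""
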