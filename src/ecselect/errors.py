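"""Exception hierarchy.

``InputError`` maps to CLI exit code 2 (malformed or missing input),
``StatisticalError`` to exit code 3 (a statistical precondition such as a
minimum group size is not met).
"""


class EcSelectError(Exception):
    """Base class for all ecselect errors."""


class InputError(EcSelectError):
    """Malformed, inconsistent or missing input data."""


class StatisticalError(EcSelectError):
    """A statistical precondition is violated (e.g. too few samples per group)."""
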