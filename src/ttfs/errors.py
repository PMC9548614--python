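"""Exception hierarchy shared across the package.

``ValidationError`` signals bad user input (CLI exit code 2);
``GuardError`` signals a refused exhaustive computation whose cost would
exceed the enumeration guard (CLI exit code 3).
"""


class ValidationError(ValueError):
    """Invalid parameter, pattern, or configuration."""


class GuardError(RuntimeError):
    """Exhaustive enumeration refused: the instance exceeds the size guard."""
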