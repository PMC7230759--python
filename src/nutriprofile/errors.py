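"""Exception hierarchy.

Distinct classes exist so the CLI can map input, configuration and
computation failures to distinct exit codes.
"""


class NutriProfileError(Exception):
    """Base class for all package errors."""


class FormatError(NutriProfileError):
    """A supply table is structurally malformed (e.g. a missing column)."""


class RowValidationError(NutriProfileError):
    """A single product row violates a panel or product invariant."""


class ConfigError(NutriProfileError):
    """A rule/point-table configuration is missing or inconsistent."""


class InputError(NutriProfileError):
    """Invalid arguments to a computation (wrong lengths, unknown model...)."""


class UndefinedProportionError(NutriProfileError):
    """A proportion was requested over an empty denominator."""
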