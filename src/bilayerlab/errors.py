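"""Exception types shared across the package.

Analysis stages distinguish *configuration* problems (caller gave an
impossible parameter set), *domain* problems (data outside the formula's
domain, e.g. a non-positive conductance handed to a log) and *schema*
problems (a table whose headers do not match the expected layout).
Fit failures on degenerate data are not exceptions: fitting routines
return result objects carrying a reason code so a pipeline run can record
the failure and continue.
"""


class ConfigurationError(ValueError):
    """A model/parameter set violates its invariants; names the offending field."""


class DomainError(ValueError):
    """Input values outside the mathematical domain of an operation."""


class SchemaError(ValueError):
    """A tabular input does not match the expected column schema."""
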