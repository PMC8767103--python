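"""Exception hierarchy shared across the pipeline stages."""


class RepnetError(Exception):
    """Base class for all package-specific errors."""


class FormatError(RepnetError, ValueError):
    """A file or table does not conform to the expected dialect."""


class IntegrityError(RepnetError, ValueError):
    """Inputs are well-formed but mutually inconsistent (e.g. duplicate keys,
    chain read counts exceeding the sample's total sequencing depth)."""


class ConfigError(RepnetError, ValueError):
    """A simulation or analysis configuration is infeasible."""
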