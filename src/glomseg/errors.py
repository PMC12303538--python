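"""Error taxonomy shared by the library and the CLI exit codes."""


class ConfigurationError(ValueError):
    """A run was requested with an inconsistent or unsatisfiable setup
    (CLI exit code 2)."""


class DataError(RuntimeError):
    """Input data is missing or unreadable (CLI exit code 3)."""
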