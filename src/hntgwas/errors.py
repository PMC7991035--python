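"""Exception types used across the pipeline."""


class ConfigurationError(ValueError):
    """A simulation or pipeline configuration is internally inconsistent."""


class ParseError(ValueError):
    """A malformed input file; carries file and line context."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        ctx = ""
        if path is not None:
            ctx = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + ctx)
        self.path = path
        self.line = line
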