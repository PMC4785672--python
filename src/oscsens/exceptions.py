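"""Exception hierarchy for oscsens."""


class OscsensError(Exception):
    """Base class for all oscsens errors."""


class ModelParseError(OscsensError, ValueError):
    """A model template could not be parsed."""


class ModelCompileError(OscsensError, ValueError):
    """A model specification could not be compiled to evaluable form."""


class SolverError(OscsensError, RuntimeError):
    """A trajectory, boundary-value, or variational solve failed."""


class AnalysisError(OscsensError, ValueError):
    """An analysis was requested that is undefined for the given solution kind."""
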