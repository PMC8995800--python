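"""Exception types shared across szlab."""


class SzlabError(Exception):
    """Base class for all szlab errors."""


class DomainError(SzlabError, ValueError):
    """A parameter or index is outside its documented domain."""


class ContractError(SzlabError, ValueError):
    """Inputs violate a structural contract (shape/length mismatch, empty split)."""


class InvalidWindowError(SzlabError, ValueError):
    """A window construction would retain no weights."""


class SolverError(SzlabError, RuntimeError):
    """A numerical solver could not bracket or converge on its target."""


class ResourceError(SzlabError, RuntimeError):
    """A request exceeds a configured size cap."""


class FormatError(SzlabError, ValueError):
    """A file does not conform to its binary/text format specification."""


class TrainingError(SzlabError, RuntimeError):
    """Training diverged (non-finite loss); carries the epoch index."""

    def __init__(self, message: str, epoch: int | None = None):
        super().__init__(message)
        self.epoch = epoch
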