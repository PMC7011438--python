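"""Exception hierarchy shared across the package.

Every error that crosses a module boundary derives from :class:`HaemodeskError`
so that callers (and the command-line frontend) can map failure classes to
distinct exit codes.
"""


class HaemodeskError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ValidationError(HaemodeskError):
    """Input failed validation against core data, a schema, or a precondition."""

    exit_code = 3


class AccessError(HaemodeskError):
    """The acting role lacks the required right on the object class."""

    exit_code = 4


class NotFoundError(HaemodeskError):
    """A record, pseudonym, model, or job does not exist."""

    exit_code = 5


class ConflictError(HaemodeskError):
    """A uniqueness or serialization contract was violated (duplicate core
    code, double delete, stale version, duplicate model registration)."""

    exit_code = 6


class InsufficientDataError(HaemodeskError):
    """Too few usable observations to run a fit."""

    exit_code = 7


class IntegrityError(HaemodeskError):
    """Stored provenance is missing or inconsistent with the audit chain."""

    exit_code = 8
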