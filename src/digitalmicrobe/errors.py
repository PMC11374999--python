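"""Exception hierarchy.

All domain failures derive from :class:`DigitalMicrobeError` so callers (and
the CLI, which maps them to exit code 1) can distinguish domain errors from
programming errors.
"""


class DigitalMicrobeError(Exception):
    """Base class for all domain errors raised by this package."""


class ValidationError(DigitalMicrobeError):
    """Input violates a precondition (bad value, malformed row, bad format)."""


class ConflictError(DigitalMicrobeError):
    """Attempt to register something that already exists (layer, sample)."""


class IntegrityError(DigitalMicrobeError):
    """Stored content disagrees with its recorded checksum, or is missing."""


class NotFoundError(DigitalMicrobeError):
    """A referenced entity (gene, contig, layer, sample) does not exist."""
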