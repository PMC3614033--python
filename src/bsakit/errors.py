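"""Exception types shared across the toolkit."""


class BsakitError(Exception):
    """Base class for all toolkit errors."""


class InvalidInputError(BsakitError, ValueError):
    """An argument violates a documented precondition."""


class RefMismatchError(BsakitError, ValueError):
    """A variant's reference allele disagrees with the genome sequence."""


class DataIntegrityError(BsakitError, ValueError):
    """Input data is internally inconsistent (conflicting duplicates, bad grids)."""


class MissingDataError(BsakitError, ValueError):
    """A quantity cannot be computed because required data is absent (e.g. zero reads)."""


class CorruptedFixtureError(BsakitError, RuntimeError):
    """The packaged worked-example fixture failed its checksum."""
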