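"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`RagvarError`, so callers (and the CLI) can distinguish expected
failure modes from bugs.
"""


class RagvarError(Exception):
    """Base class for all ragvar errors."""


class PhasedInputRequiredError(RagvarError):
    """An unphased genotype call was encountered where phased input is required."""


class ReferenceMismatchError(RagvarError):
    """A variant's REF allele disagrees with the reference genome."""


class CorruptStoreError(RagvarError):
    """An on-disk store file is missing, truncated, or inconsistent with its manifest."""


class UnsupportedVersionError(RagvarError):
    """The dataset manifest declares a format version this build cannot read."""


class InvalidInputError(RagvarError, ValueError):
    """User-supplied inputs violate a documented precondition."""
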