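"""Exception hierarchy shared across the package."""


class MsatuneError(Exception):
    """Base class for all package errors."""


class AlignmentFormatError(MsatuneError):
    """A sequence or alignment file violates its format contract."""


class InputMismatchError(MsatuneError):
    """Test and reference alignments disagree on ids or sequence content."""


class ScoringError(MsatuneError):
    """The reference defines no scorable residue pairs."""


class ConfigurationError(MsatuneError):
    """Invalid matrix name, grid, or aligner specification."""


class AlignerError(MsatuneError):
    """An external aligner run failed (nonzero exit, timeout, bad output)."""

    def __init__(self, message: str, stderr: str = ""):
        super().__init__(message)
        self.stderr = stderr


class AlignmentIntegrityError(AlignerError):
    """Aligner output does not reproduce the ungapped input sequences."""
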