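"""Exception hierarchy shared across the pipeline."""


class CwrError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(CwrError):
    """A configuration value violates its contract."""


class DataError(CwrError):
    """Input data are unusable (empty after cleaning, unparseable, mismatched)."""


class AlignmentError(DataError):
    """Two spatial layers or result tables do not share a common frame."""


class TreeError(DataError):
    """A phylogenetic tree violates a structural requirement."""
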