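"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``DataError`` to exit code 3.
"""


class TfnetError(Exception):
    """Base class for all tfnetminer errors."""


class ConfigError(TfnetError):
    """Invalid configuration: bad thresholds, unknown keys, unknown schemes."""


class DataError(TfnetError):
    """Invalid or inconsistent input data."""


class ThesaurusError(DataError):
    """Thesaurus load failure (e.g. a synonym mapped to two canonical ids)."""
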