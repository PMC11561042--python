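"""Exception hierarchy shared across the package.

Input-file problems split into two classes so callers (and the CLI exit
codes) can distinguish a malformed file from a structurally inconsistent
one: ``ParseError`` means a cell could not be read at all, ``SchemaError``
means the file parsed but violates the bundle/table contract.
"""


class MetnetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(MetnetError):
    """A file could not be parsed (non-numeric count, bad header, ...)."""


class SchemaError(MetnetError):
    """Parsed content violates a structural contract (duplicate IDs,
    dimension mismatch, dangling references, ...)."""
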