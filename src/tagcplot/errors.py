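"""Exception hierarchy shared across the package."""


class TagcError(Exception):
    """Base class for all pipeline errors."""


class FormatError(TagcError):
    """Malformed input file (bad record, unknown column, truncated read)."""


class StructuralError(TagcError):
    """Logically inconsistent data (orphan taxids, cycles, mismatched sets)."""
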