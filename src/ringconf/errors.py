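"""Exception hierarchy for ringconf."""


class RingconfError(Exception):
    """Base class for all ringconf errors."""


class ParseError(RingconfError):
    """A coordinate or dictionary file could not be parsed."""


class FormatError(RingconfError):
    """Unknown or unsupported file format."""


class MissingComponentError(RingconfError):
    """A component referenced by a structure is absent from the dictionary."""

    def __init__(self, component_ids):
        self.component_ids = sorted(set(component_ids))
        super().__init__(
            "component(s) missing from dictionary: " + ", ".join(self.component_ids)
        )


class DegenerateGeometryError(RingconfError):
    """Coordinates are too degenerate (collinear/coincident) for a plane or flap."""


class MapFormatError(RingconfError):
    """A density map file has a malformed or unsupported header."""


class OutOfBoundsError(RingconfError):
    """A position falls outside a non-periodic density map."""


class ResolutionTableError(RingconfError):
    """A resolution metadata table is malformed (e.g. duplicate entry ids)."""
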