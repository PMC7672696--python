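"""Exception hierarchy shared across the package."""


class HomreasonError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(HomreasonError, ValueError):
    """Malformed input: unknown relation keyword, bad column set, bad CURIE."""


class ReferenceError_(HomreasonError, KeyError):
    """A term, taxon, or individual id is not declared where it is used."""

    def __str__(self) -> str:  # KeyError quotes its args; keep messages readable
        return Exception.__str__(self)


class CycleError(HomreasonError, ValueError):
    """The is_a relation of a graph contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__("is_a cycle: " + " -> ".join(self.cycle + self.cycle[:1]))


class NegatedAssertionError(HomreasonError, ValueError):
    """A negated homology assertion was passed where only positive ones are legal."""


class UnsupportedModelError(HomreasonError, ValueError):
    """The requested operation is not defined under the given homology model."""
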