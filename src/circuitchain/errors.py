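"""Exception hierarchy for chain-string validation and conversion."""


class CircuitChainError(Exception):
    """Base class for all circuitchain errors."""


class NotationError(CircuitChainError):
    """A chain string violates the notation grammar or its invariants."""


class UnpairedContactError(NotationError):
    """A contact letter occurs a number of times other than exactly two."""


class SoftAttributeError(NotationError):
    """A soft-contact attribute is attached anywhere but the first occurrence,
    or attached twice."""


class UnknownThreadTargetError(NotationError):
    """A thread subscript references a contact that does not exist."""


class ConcertedOrderError(NotationError):
    """The written order of sites inside concerted groups puts two merged
    contacts in a cross arrangement, which the notation forbids."""


class UnknownContactError(CircuitChainError):
    """An operation referenced a contact name absent from the chain."""


class MatrixFormatError(CircuitChainError):
    """A connectivity matrix is not a symmetric 0/1 perfect-matching matrix."""


class KnotModelError(CircuitChainError):
    """A chain cannot be mapped to a knot diagram by this package
    (hard contacts, threads, or unsupported cross patterns present)."""
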