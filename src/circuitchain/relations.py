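"""Pairwise contact relations: series / parallel / cross classification,
configuration counting and enumeration, reversal-symmetry reduction, and
segment decomposition.

Restricting a chain string to the four sites of two contacts a, b leaves one
of three patterns: ``aabb`` (series, S), ``abba`` (parallel, P — b nested
inside a; the ordered query (b, a) answers P⁻¹), or ``abab`` (cross, X).
Contacts merged at a concerted site are never written in cross, so their
residual S or P pattern is reported as concerted series (CS) or concerted
parallel (CP).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator

from .errors import UnknownContactError
from .notation import (
    ChainString,
    Group,
    Site,
    Thread,
    _build_chain,
    canonical,
    canonical_key,
    name_for_index,
    parse_chain,
)

__all__ = [
    "RelationLabel",
    "classify_pair",
    "relation_matrix",
    "RelationSummary",
    "count_strings",
    "enumerate_strings",
    "reduce_by_reversal",
    "decompose_segments",
]

DEFAULT_ENUMERATION_BOUND = 7


class RelationLabel(str, Enum):
    S = "S"
    P = "P"
    Pinv = "P-1"
    X = "X"
    CS = "CS"
    CP = "CP"

    def unordered(self) -> "RelationLabel":
        """Collapse the container/contained distinction (P⁻¹ → P)."""
        return RelationLabel.P if self is RelationLabel.Pinv else self


def _share_group(chain: ChainString, a: str, b: str) -> bool:
    return any(
        isinstance(ev, Group) and a in ev.members and b in ev.members
        for ev in chain.events
    )


def classify_pair(chain: ChainString, a: str, b: str) -> RelationLabel:
    """Relation of contact ``b`` to contact ``a`` along the chain.

    Threads are invisible to the base classification; only the order of the
    four contact sites matters.  ``P`` means b is nested inside a; the
    swapped query returns ``Pinv``.
    """
    if a == b:
        raise UnknownContactError("classify_pair needs two distinct contacts")
    chain.contact(a)
    chain.contact(b)
    pattern = "".join(
        "a" if s == a else "b" for s in chain.site_sequence if s in (a, b)
    )
    concerted = _share_group(chain, a, b)
    if pattern in ("aabb", "bbaa"):
        label = RelationLabel.S
    elif pattern == "abba":
        label = RelationLabel.P
    elif pattern == "baab":
        label = RelationLabel.Pinv
    else:  # abab / baba
        label = RelationLabel.X
    if concerted:
        # merged sites are written in the non-cross resolution, so only S/P remain
        if label is RelationLabel.S:
            return RelationLabel.CS
        return RelationLabel.CP
    return label


@dataclass(frozen=True)
class RelationSummary:
    """All pairwise labels of a chain plus unordered-label frequencies."""

    labels: dict[tuple[str, str], RelationLabel]
    frequencies: dict[str, float]

    @property
    def n_pairs(self) -> int:
        return len(self.labels)


def relation_matrix(chain: ChainString) -> RelationSummary:
    """Classify every unordered contact pair; frequencies sum to 1.

    With fewer than two contacts the summary is empty.
    """
    names = chain.contact_names
    labels: dict[tuple[str, str], RelationLabel] = {}
    counts: dict[str, int] = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            lab = classify_pair(chain, a, b)
            labels[(a, b)] = lab
            key = lab.unordered().value
            counts[key] = counts.get(key, 0) + 1
    total = sum(counts.values())
    freqs = {k: v / total for k, v in counts.items()} if total else {}
    return RelationSummary(labels, freqs)


def count_strings(n: int) -> int:
    """Number of distinct strings of n binary contacts: (2n)! / (n! 2^n)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return math.factorial(2 * n) // (math.factorial(n) * 2 ** n)


def _matchings(slots: int) -> Iterator[tuple[int, ...]]:
    """Perfect matchings of ``slots`` ordered points as a partner array,
    generated in canonical (first-occurrence) order."""

    def rec(assigned: list[int | None]) -> Iterator[tuple[int, ...]]:
        try:
            first = assigned.index(None)
        except ValueError:
            yield tuple(assigned)  # type: ignore[arg-type]
            return
        for j in range(first + 1, slots):
            if assigned[j] is None:
                assigned[first] = j
                assigned[j] = first
                yield from rec(assigned)
                assigned[first] = None
                assigned[j] = None

    yield from rec([None] * slots)


def enumerate_strings(n: int, bound: int = DEFAULT_ENUMERATION_BOUND) -> list[ChainString]:
    """All canonical hard-contact strings with n contacts.

    Generated as perfect matchings of 2n ordered sites with letters assigned
    by first occurrence, so every string appears exactly once; the count is
    (2n−1)!! = count_strings(n).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if n > bound:
        raise ValueError(f"n={n} exceeds the enumeration bound {bound}")
    out = []
    for partners in _matchings(2 * n):
        names: dict[int, str] = {}
        events = []
        for i in range(2 * n):
            if i not in names:
                label = name_for_index(len(names) // 2)
                names[i] = names[partners[i]] = label
            events.append(Site(names[i]))
        out.append(_build_chain(events, {}))
    return out


def reduce_by_reversal(strings: Iterable[ChainString]) -> dict[str, list[ChainString]]:
    """Group strings equivalent under chain reversal (plus canonical
    renaming).  Keys are class representatives: the lexicographically smaller
    of the two canonical readings."""
    classes: dict[str, list[ChainString]] = {}
    for chain in strings:
        classes.setdefault(canonical_key(chain), []).append(chain)
    return classes


def decompose_segments(chain: ChainString) -> list[ChainString]:
    """Split a chain into maximal independent segments.

    A cut is legal where no contact pair and no thread reference spans it;
    contacts in different segments are therefore always in series.  The
    concatenation of the segments reproduces the chain.
    """
    events = chain.events
    if not events:
        return []
    # interval (in event indices) covered by each contact, widened by threads
    first: dict[str, int] = {}
    last: dict[str, int] = {}

    def touch(name: str, idx: int) -> None:
        first.setdefault(name, idx)
        last[name] = idx

    for idx, ev in enumerate(events):
        if isinstance(ev, Site):
            touch(ev.name, idx)
        elif isinstance(ev, Group):
            for m in ev.members:
                touch(m, idx)
        else:
            touch(ev.target, idx)

    segments: list[ChainString] = []
    start = 0
    reach = -1
    for idx, ev in enumerate(events):
        if isinstance(ev, Site):
            reach = max(reach, last[ev.name])
        elif isinstance(ev, Group):
            reach = max(reach, *(last[m] for m in ev.members))
        else:
            reach = max(reach, last[ev.target])
        if reach == idx:
            segments.append(_slice(chain, start, idx + 1, len(segments) == 0))
            start = idx + 1
    return segments


def _slice(chain: ChainString, lo: int, hi: int, is_first: bool) -> ChainString:
    soft_attrs = {
        rec.name: (rec.chirality, rec.parity)
        for rec in chain.contacts
        if rec.kind == "soft"
    }
    events = list(chain.events[lo:hi])
    present: set[str] = set()
    for ev in events:
        if isinstance(ev, Site):
            present.add(ev.name)
        elif isinstance(ev, Group):
            present.update(ev.members)
    attrs = {k: v for k, v in soft_attrs.items() if k in present}
    left = chain.termini[0] if is_first else None
    right = chain.termini[1] if hi == len(chain.events) else None
    return _build_chain(events, attrs, (left, right))
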