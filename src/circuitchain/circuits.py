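"""Circuits, size vectors, the circuit metric, and roughness.

A *circuit* is a contiguous segment of the site sequence that is
self-contained: every contact with a site in the segment has both sites in
it, every thread inside the segment passes through a contact inside it, and
no thread elsewhere on the chain passes through a contact of the segment.
Its *order* is the number of contact pairs it holds.  The collection of all
circuits (a sigma-algebra on the string) is summarised by the **size
vector** x, whose k-th entry counts circuits of order k; by convention it is
displayed from the highest order down, e.g. AABB -> [12].

Size vectors live in a weighted metric space with

    d(X, Y) = sqrt( sum_k k^2 (x_k - y_k)^2 )

so disagreements in large circuits weigh more.  The **roughness** of a chain
is its distance to the empty (disentangled) string, r(X) = d(X, 0).  The
squared variants d^2 and r^2 are the under-radical integers and match the
values a desk calculation tabulates for small chains (e.g. r^2 = 8 for
AABB, 34 for AABBCC).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

from .notation import ChainString, parse_chain

__all__ = [
    "CircuitSpan",
    "SizeVector",
    "find_circuits",
    "size_vector",
    "distance",
    "squared_distance",
    "roughness",
    "squared_roughness",
]


@dataclass(frozen=True)
class CircuitSpan:
    """One circuit: inclusive 1-based site range and its contact content."""

    start: int
    end: int
    contacts: frozenset[str]

    @property
    def order(self) -> int:
        return len(self.contacts)


@dataclass(frozen=True)
class SizeVector:
    """Circuit counts per order k = 1..n (``counts[k-1]`` is order k)."""

    counts: tuple[int, ...]

    @property
    def order(self) -> int:
        return len(self.counts)

    def digits(self) -> str:
        """Highest order leftmost, e.g. ``'123'`` for AABBCC."""
        return "".join(str(c) for c in reversed(self.counts))

    def __str__(self) -> str:
        return f"[{self.digits()}]"

    def padded(self, n: int) -> tuple[int, ...]:
        return self.counts + (0,) * (n - len(self.counts))


def _coerce(chain: ChainString | str) -> ChainString:
    return parse_chain(chain) if isinstance(chain, str) else chain


def find_circuits(chain: ChainString | str) -> list[CircuitSpan]:
    """All circuits of the chain, one span per closed contact set.

    Spans range over individual contact-site positions (sites merged in a
    concerted group keep their written order), so a circuit may well start or
    end inside a group.  For a valid chain the whole string is always a
    circuit; the empty circuit is left implicit.
    """
    chain = _coerce(chain)
    atoms = chain.atoms()
    sites = {rec.name: rec.sites for rec in chain.contacts}
    circuits: dict[frozenset[str], CircuitSpan] = {}
    L = len(atoms)
    for i in range(L):
        open_contacts: dict[str, int] = {}
        content: set[str] = set()
        inner_threads: list[str] = []
        for j in range(i, L):
            atom = atoms[j]
            if atom[0] == "site":
                name = atom[1]
                content.add(name)
                open_contacts[name] = open_contacts.get(name, 0) + 1
                if open_contacts[name] == 2:
                    del open_contacts[name]
            else:
                inner_threads.append(atom[2])
            if not open_contacts and content:
                # candidate span i..j: pairing closed; now check threads
                if all(t in content for t in inner_threads) and _no_outer_thread(
                    atoms, i, j, content
                ):
                    key = frozenset(content)
                    if key not in circuits:
                        start = min(sites[c][0] for c in key)
                        end = max(sites[c][1] for c in key)
                        circuits[key] = CircuitSpan(start, end, key)
    return sorted(circuits.values(), key=lambda c: (c.order, c.start))


def _no_outer_thread(atoms, i: int, j: int, content: set[str]) -> bool:
    for k, atom in enumerate(atoms):
        if i <= k <= j or atom[0] != "thread":
            continue
        if atom[2] in content:
            return False
    return True


def size_vector(chain: ChainString | str) -> SizeVector:
    """Count circuits per order; ``x_n = 1`` (the string itself)."""
    chain = _coerce(chain)
    n = chain.n_contacts
    counts = [0] * n
    for span in find_circuits(chain):
        counts[span.order - 1] += 1
    return SizeVector(tuple(counts))


def _as_counts(x: "SizeVector | Sequence[int]") -> tuple[int, ...]:
    """Accept a SizeVector or a plain sequence written in display order
    (highest circuit order first, the way sizes are printed)."""
    if isinstance(x, SizeVector):
        counts = x.counts
    else:
        counts = tuple(reversed(tuple(x)))
    if any(c < 0 for c in counts):
        raise ValueError("size-vector counts must be nonnegative")
    return counts


def squared_distance(x, y) -> int:
    """Under-radical circuit metric: sum_k k^2 (x_k - y_k)^2 (exact integer)."""
    xc, yc = _as_counts(x), _as_counts(y)
    n = max(len(xc), len(yc))
    xc += (0,) * (n - len(xc))
    yc += (0,) * (n - len(yc))
    return sum((k + 1) ** 2 * (a - b) ** 2 for k, (a, b) in enumerate(zip(xc, yc)))


def distance(x, y) -> float:
    """Circuit metric d(X, Y) = sqrt(sum_k k^2 (x_k - y_k)^2)."""
    return math.sqrt(squared_distance(x, y))


def squared_roughness(chain_or_size) -> int:
    """Under-radical roughness: sum_k k^2 x_k^2."""
    x = _to_size(chain_or_size)
    return squared_distance(x, ())


def roughness(chain_or_size) -> float:
    """Roughness r(X) = d(X, 0); 0 for a disentangled (contact-free) chain."""
    return math.sqrt(squared_roughness(chain_or_size))


def _to_size(obj) -> SizeVector:
    if isinstance(obj, SizeVector):
        return obj
    if isinstance(obj, (ChainString, str)):
        return size_vector(obj)
    return SizeVector(_as_counts(obj))
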