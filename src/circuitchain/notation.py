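"""Chain-string notation: parsing, validation, serialization, conversions.

A folded linear chain is written as an ordered sequence of *events* along the
chain:

* a **contact site** — an alphanumeric token (``A``, ``B1``); each contact
  name occurs exactly twice,
* a **soft attribute** ``^{+e}``/``^{-o}`` on the *first* occurrence of a
  contact, marking it as a soft (entanglement) contact with a chirality
  (``+``/``-``, right-hand rule) and a parity (``e``ven/``o``dd hooking),
* a **thread** ``_{+A}`` — a chain segment passing through contact ``A``'s
  loop in the signed direction,
* a **concerted group** ``(A B)`` — sites of different contacts merged at one
  chain location,
* optional **termini** labels (``Nt``/``Ct``) at either end.

Tokens may be whitespace-separated or written compactly (``AABB``,
``NtABDBADCt``); both dialects parse identically.  A contact is *soft* iff it
carries a ``^{...}`` attribute anywhere, otherwise it is *hard* (a bond).
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import (
    ConcertedOrderError,
    MatrixFormatError,
    NotationError,
    SoftAttributeError,
    UnknownContactError,
    UnknownThreadTargetError,
    UnpairedContactError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Site",
    "Thread",
    "Group",
    "ContactRecord",
    "ChainString",
    "parse_chain",
    "serialize_chain",
    "reverse_chain",
    "canonical",
    "canonical_key",
    "to_connectivity_matrix",
    "from_connectivity_matrix",
    "break_contact",
    "merge_chains",
    "chain_to_json",
    "chain_from_json",
    "read_ctstr",
    "write_ctstr",
    "read_matrix_tsv",
    "write_matrix_tsv",
    "name_for_index",
]


# --------------------------------------------------------------------------
# events and records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Site:
    """One contact site occurring on the chain."""

    name: str


@dataclass(frozen=True)
class Thread:
    """A chain segment passing through an existing contact's loop."""

    sign: str  # '+' or '-'
    target: str


@dataclass(frozen=True)
class Group:
    """Concerted sites sharing one merged chain location (written order kept)."""

    members: tuple[str, ...]


Event = Site | Thread | Group


@dataclass(frozen=True)
class ContactRecord:
    """One named contact: kind, soft attributes, and its two site indices.

    ``sites`` are 1-based positions in the contact-site sequence (threads and
    group parentheses do not consume positions), so a chain with *n* contacts
    has sites 1..2n.
    """

    name: str
    kind: str  # 'hard' | 'soft'
    chirality: str | None  # '+' | '-' | None
    parity: str | None  # 'even' | 'odd' | None
    sites: tuple[int, int]

    def __post_init__(self) -> None:
        if self.kind == "soft":
            if self.chirality not in "+-" or self.parity not in ("even", "odd"):
                raise NotationError(
                    f"soft contact {self.name!r} needs chirality and parity"
                )
        elif self.kind == "hard":
            if self.chirality is not None or self.parity is not None:
                raise NotationError(
                    f"hard contact {self.name!r} cannot carry soft attributes"
                )
        else:
            raise NotationError(f"unknown contact kind {self.kind!r}")
        if self.sites[0] >= self.sites[1]:
            raise NotationError(f"contact {self.name!r} sites must be ordered")

    @property
    def type_code(self) -> str | None:
        """Soft-contact type as ``'+e'``/``'-o'`` etc., ``None`` for hard."""
        if self.kind != "soft":
            return None
        return self.chirality + self.parity[0]


@dataclass(frozen=True)
class ChainString:
    """An ordered event sequence describing one folded chain."""

    events: tuple[Event, ...]
    contacts: tuple[ContactRecord, ...]  # ordered by first site
    termini: tuple[str | None, str | None] = (None, None)

    # -- basic views -------------------------------------------------------

    @property
    def n_contacts(self) -> int:
        return len(self.contacts)

    def contact(self, name: str) -> ContactRecord:
        for rec in self.contacts:
            if rec.name == name:
                return rec
        raise UnknownContactError(f"no contact named {name!r}")

    @property
    def contact_names(self) -> tuple[str, ...]:
        return tuple(rec.name for rec in self.contacts)

    @property
    def site_sequence(self) -> tuple[str, ...]:
        """Contact names in site order (group members expanded in order)."""
        out: list[str] = []
        for ev in self.events:
            if isinstance(ev, Site):
                out.append(ev.name)
            elif isinstance(ev, Group):
                out.extend(ev.members)
        return tuple(out)

    @property
    def threads(self) -> tuple[Thread, ...]:
        return tuple(ev for ev in self.events if isinstance(ev, Thread))

    def atoms(self) -> list[tuple]:
        """Flattened per-site sequence interleaved with threads.

        Returns a list of ``('site', name, index)`` and
        ``('thread', sign, target)`` entries; the basis for circuit spans,
        where merged group members count as individual consecutive sites.
        """
        out: list[tuple] = []
        idx = 0
        for ev in self.events:
            if isinstance(ev, Site):
                idx += 1
                out.append(("site", ev.name, idx))
            elif isinstance(ev, Group):
                for name in ev.members:
                    idx += 1
                    out.append(("site", name, idx))
            else:
                out.append(("thread", ev.sign, ev.target))
        return out

    def __str__(self) -> str:
        return serialize_chain(self)


# --------------------------------------------------------------------------
# construction and validation
# --------------------------------------------------------------------------

def _build_chain(
    events: Sequence[Event],
    soft_attrs: dict[str, tuple[str, str]],
    termini: tuple[str | None, str | None] = (None, None),
    *,
    attr_occurrence: dict[str, int] | None = None,
) -> ChainString:
    """Assemble and validate a :class:`ChainString` from raw parsed pieces.

    ``soft_attrs`` maps contact name -> (chirality, parity); if
    ``attr_occurrence`` is given it records on which occurrence (1 or 2) the
    attribute was written, enforcing first-occurrence attachment.
    """
    # site occurrences
    positions: dict[str, list[int]] = {}
    idx = 0
    for ev in events:
        if isinstance(ev, Site):
            idx += 1
            positions.setdefault(ev.name, []).append(idx)
        elif isinstance(ev, Group):
            seen_in_group: set[str] = set()
            for name in ev.members:
                if name in seen_in_group:
                    raise NotationError(
                        f"concerted group contains contact {name!r} twice"
                    )
                seen_in_group.add(name)
                idx += 1
                positions.setdefault(name, []).append(idx)

    for name, occ in positions.items():
        if len(occ) != 2:
            raise UnpairedContactError(
                f"contact {name!r} occurs {len(occ)} time(s); expected exactly 2"
            )
    for name in soft_attrs:
        if name not in positions:
            raise UnpairedContactError(
                f"soft attribute on {name!r} but no such contact site"
            )
    if attr_occurrence:
        for name, occ in attr_occurrence.items():
            if occ != 1:
                raise SoftAttributeError(
                    f"soft attribute on {name!r} must sit on its first occurrence"
                )

    # thread targets
    for ev in events:
        if isinstance(ev, Thread) and ev.target not in positions:
            raise UnknownThreadTargetError(
                f"thread references unknown contact {ev.target!r}"
            )

    records = []
    for name, occ in sorted(positions.items(), key=lambda kv: kv[1][0]):
        if name in soft_attrs:
            chirality, parity = soft_attrs[name]
            records.append(
                ContactRecord(name, "soft", chirality, parity, (occ[0], occ[1]))
            )
        else:
            records.append(ContactRecord(name, "hard", None, None, (occ[0], occ[1])))

    chain = ChainString(tuple(events), tuple(records), termini)
    _check_group_order(chain)
    _warn_orphan_threads(chain)
    return chain


def _pattern(chain_sites: Sequence[str], a: str, b: str) -> str:
    """Restriction of the site order to contacts a, b as 'a'/'b' letters."""
    return "".join("a" if s == a else "b" for s in chain_sites if s in (a, b))


def _check_group_order(chain: ChainString) -> None:
    """Merged contacts must never be written in a cross arrangement."""
    sites = chain.site_sequence
    grouped: dict[str, set[str]] = {}
    for ev in chain.events:
        if isinstance(ev, Group):
            for name in ev.members:
                grouped.setdefault(name, set()).update(ev.members)
    seen: set[tuple[str, str]] = set()
    for a, partners in grouped.items():
        for b in partners:
            if a == b or (min(a, b), max(a, b)) in seen:
                continue
            seen.add((min(a, b), max(a, b)))
            pat = _pattern(sites, a, b)
            if pat in ("abab", "baba"):
                raise ConcertedOrderError(
                    f"concerted contacts {a!r}/{b!r} are written in cross order"
                )


def _warn_orphan_threads(chain: ChainString) -> None:
    """Warn about threads outside every contact span away from chain ends."""
    atoms = chain.atoms()
    n_sites = sum(1 for a in atoms if a[0] == "site")
    spans = {rec.name: rec.sites for rec in chain.contacts}
    before = 0
    for a in atoms:
        if a[0] == "site":
            before = a[2]
            continue
        if before == 0 or before == n_sites:
            continue  # dangling at a chain end: permitted and preserved
        inside_any = any(lo <= before < hi for lo, hi in spans.values())
        if not inside_any:
            logger.warning(
                "thread _{%s%s} lies outside every contact span", a[1], a[2]
            )


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

_SITE_RE = re.compile(r"[A-Z][0-9]*")
_TERM_RE = re.compile(r"[A-Z][a-z][a-z0-9]*")
_SUP_RE = re.compile(r"\^\{([+-])([eo])\}")
_SUB_RE = re.compile(r"_\{([+-])([A-Z][0-9]*)\}")


def parse_chain(text: str) -> ChainString:
    """Parse chain-string notation into a validated :class:`ChainString`.

    Accepts both the whitespace-separated and the compact dialect, e.g.
    ``"A^{+o} A _{+A}"`` (a slip-knot) or ``"NtABDBADCt"``.
    """
    events: list[Event] = []
    soft_attrs: dict[str, tuple[str, str]] = {}
    attr_occurrence: dict[str, int] = {}
    occurrences: dict[str, int] = {}
    termini: list[str | None] = [None, None]

    pos = 0
    n = len(text)
    group: list[str] | None = None
    last_site: str | None = None

    def fail(msg: str) -> NotationError:
        return NotationError(f"{msg} at position {pos} in {text!r}")

    while pos < n:
        ch = text[pos]
        if ch.isspace():
            pos += 1  # whitespace does not detach attributes
            continue
        if ch == "(":
            if group is not None:
                raise fail("nested concerted group")
            group = []
            pos += 1
            continue
        if ch == ")":
            if group is None:
                raise fail("unmatched ')'")
            if len(group) < 2:
                raise fail("concerted group needs at least 2 members")
            events.append(Group(tuple(group)))
            group = None
            pos += 1
            continue
        if ch == "^":
            m = _SUP_RE.match(text, pos)
            if not m:
                raise fail("malformed soft attribute (expected ^{+e}, ^{-o}, ...)")
            if last_site is None:
                raise fail("soft attribute without a preceding contact site")
            if last_site in soft_attrs:
                raise SoftAttributeError(
                    f"contact {last_site!r} carries two soft attributes"
                )
            soft_attrs[last_site] = (m.group(1), "even" if m.group(2) == "e" else "odd")
            attr_occurrence[last_site] = occurrences[last_site]
            pos = m.end()
            continue
        if ch == "_":
            m = _SUB_RE.match(text, pos)
            if not m:
                raise fail("malformed thread (expected _{+A} style)")
            if group is not None:
                raise fail("thread inside a concerted group")
            events.append(Thread(m.group(1), m.group(2)))
            last_site = None
            pos = m.end()
            continue
        m = _TERM_RE.match(text, pos)
        if m:
            label = m.group(0)
            rest = text[m.end():]
            if not events and group is None and termini[0] is None:
                termini[0] = label
            elif rest.strip() == "":
                termini[1] = label
            else:
                raise fail(f"terminus label {label!r} away from a chain end")
            last_site = None
            pos = m.end()
            continue
        m = _SITE_RE.match(text, pos)
        if m:
            name = m.group(0)
            occurrences[name] = occurrences.get(name, 0) + 1
            if group is not None:
                group.append(name)
            else:
                events.append(Site(name))
            last_site = name
            pos = m.end()
            continue
        raise fail(f"unexpected character {ch!r}")

    if group is not None:
        raise fail("unclosed concerted group")

    return _build_chain(
        events, soft_attrs, (termini[0], termini[1]), attr_occurrence=attr_occurrence
    )


# --------------------------------------------------------------------------
# serialization
# --------------------------------------------------------------------------

def _attr_token(rec: ContactRecord) -> str:
    return f"^{{{rec.chirality}{rec.parity[0]}}}"


def serialize_chain(chain: ChainString, direction: str = "forward") -> str:
    """Write a chain back to notation text.

    ``direction='reverse'`` emits the string read from the other chain end,
    with soft attributes re-attached to the new first occurrences (thread
    signs and chirality are orientation-independent and stay unchanged).
    Plain hard-contact chains with single-letter names come out compact
    (``AABB``); anything carrying attributes, threads, or groups is emitted
    as whitespace-separated tokens.
    """
    if direction == "reverse":
        chain = reverse_chain(chain)
    elif direction != "forward":
        raise ValueError("direction must be 'forward' or 'reverse'")

    soft = {rec.name: rec for rec in chain.contacts if rec.kind == "soft"}
    plain = (
        not soft
        and all(isinstance(ev, Site) for ev in chain.events)
        and all(len(rec.name) == 1 for rec in chain.contacts)
    )
    if plain:
        body = "".join(ev.name for ev in chain.events)  # type: ignore[union-attr]
        left = chain.termini[0] or ""
        right = chain.termini[1] or ""
        return f"{left}{body}{right}"

    seen: set[str] = set()

    def site_token(name: str) -> str:
        tok = name
        if name in soft and name not in seen:
            tok += _attr_token(soft[name])
        seen.add(name)
        return tok

    tokens: list[str] = []
    if chain.termini[0]:
        tokens.append(chain.termini[0])
    for ev in chain.events:
        if isinstance(ev, Site):
            tokens.append(site_token(ev.name))
        elif isinstance(ev, Thread):
            tokens.append(f"_{{{ev.sign}{ev.target}}}")
        else:
            tokens.append("(" + " ".join(site_token(m) for m in ev.members) + ")")
    if chain.termini[1]:
        tokens.append(chain.termini[1])
    return " ".join(tokens)


def reverse_chain(chain: ChainString) -> ChainString:
    """The same chain read from the other end."""
    events: list[Event] = []
    for ev in reversed(chain.events):
        if isinstance(ev, Group):
            events.append(Group(tuple(reversed(ev.members))))
        else:
            events.append(ev)
    soft_attrs = {
        rec.name: (rec.chirality, rec.parity)
        for rec in chain.contacts
        if rec.kind == "soft"
    }
    return _build_chain(events, soft_attrs, (chain.termini[1], chain.termini[0]))


def name_for_index(i: int) -> str:
    """Canonical contact names: A..Z, A1..Z1, A2.. — always valid site tokens."""
    letter = chr(ord("A") + i % 26)
    round_ = i // 26
    return letter if round_ == 0 else f"{letter}{round_}"


def canonical(chain: ChainString) -> ChainString:
    """Rename contacts A, B, C, ... in order of first occurrence."""
    mapping: dict[str, str] = {}
    for name in chain.site_sequence:
        if name not in mapping:
            mapping[name] = name_for_index(len(mapping))
    return _rename(chain, mapping)


def canonical_key(chain: ChainString) -> str:
    """Orientation-independent canonical form: the lexicographically smaller
    of the forward and reverse canonical serializations."""
    fwd = serialize_chain(canonical(chain))
    rev = serialize_chain(canonical(reverse_chain(chain)))
    return min(fwd, rev)


def _rename(chain: ChainString, mapping: dict[str, str]) -> ChainString:
    events: list[Event] = []
    for ev in chain.events:
        if isinstance(ev, Site):
            events.append(Site(mapping[ev.name]))
        elif isinstance(ev, Thread):
            events.append(Thread(ev.sign, mapping[ev.target]))
        else:
            events.append(Group(tuple(mapping[m] for m in ev.members)))
    soft_attrs = {
        mapping[rec.name]: (rec.chirality, rec.parity)
        for rec in chain.contacts
        if rec.kind == "soft"
    }
    return _build_chain(events, soft_attrs, chain.termini)


# --------------------------------------------------------------------------
# connectivity matrices
# --------------------------------------------------------------------------

def to_connectivity_matrix(chain: ChainString) -> np.ndarray:
    """The symmetric 0/1 connectivity matrix S (2n x 2n), S_kl = 1 iff sites
    k and l belong to the same contact.

    Soft attributes, threads, and group structure do not fit in a plain 0/1
    matrix; they are dropped with a warning (use :func:`chain_to_json` as a
    lossless sidecar).
    """
    lossy = (
        any(rec.kind == "soft" for rec in chain.contacts)
        or any(not isinstance(ev, Site) for ev in chain.events)
    )
    if lossy:
        logger.warning(
            "connectivity matrix drops soft attributes, threads, and groups"
        )
    n2 = 2 * chain.n_contacts
    S = np.zeros((n2, n2), dtype=int)
    for rec in chain.contacts:
        i, j = rec.sites[0] - 1, rec.sites[1] - 1
        S[i, j] = S[j, i] = 1
    return S


def from_connectivity_matrix(S: np.ndarray) -> ChainString:
    """Rebuild a (hard-contact) chain from a connectivity matrix.

    Letters are assigned A, B, C, ... in order of first occurrence, so
    ``to_connectivity_matrix(from_connectivity_matrix(S)) == S`` exactly.
    """
    S = np.asarray(S)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise MatrixFormatError("connectivity matrix must be square")
    if not np.isin(S, (0, 1)).all():
        raise MatrixFormatError("entries must be 0 or 1")
    if np.any(np.diag(S) != 0):
        raise MatrixFormatError("diagonal must be zero")
    if not np.array_equal(S, S.T):
        raise MatrixFormatError("matrix must be symmetric")
    if not np.all(S.sum(axis=1) == 1):
        raise MatrixFormatError("each row must contain exactly one 1")

    partner = {i: int(np.flatnonzero(S[i])[0]) for i in range(S.shape[0])}
    names: dict[int, str] = {}
    events: list[Event] = []
    for i in range(S.shape[0]):
        if i not in names:
            label = name_for_index(len(names) // 2)
            names[i] = names[partner[i]] = label
        events.append(Site(names[i]))
    return _build_chain(events, {})


def read_matrix_tsv(path) -> np.ndarray:
    """Read a square 0/1 connectivity matrix from headerless TSV."""
    S = np.loadtxt(path, dtype=int, delimiter="\t", ndmin=2)
    return S


def write_matrix_tsv(path, chain: ChainString, sidecar: bool = True) -> None:
    """Write the connectivity matrix as TSV; a ``.json`` sidecar keeps the
    soft attributes and threads the matrix cannot hold."""
    S = to_connectivity_matrix(chain)
    np.savetxt(path, S, fmt="%d", delimiter="\t")
    if sidecar:
        with open(f"{path}.json", "w") as fh:
            json.dump(chain_to_json(chain), fh, indent=1)


# --------------------------------------------------------------------------
# editing operations
# --------------------------------------------------------------------------

def break_contact(chain: ChainString, name: str) -> ChainString:
    """Remove a contact: its letter disappears from the string, together with
    every thread passing through it; remaining site indices close ranks."""
    chain.contact(name)  # raises UnknownContactError
    events: list[Event] = []
    for ev in chain.events:
        if isinstance(ev, Site):
            if ev.name != name:
                events.append(ev)
        elif isinstance(ev, Thread):
            if ev.target != name:
                events.append(ev)
        else:
            members = tuple(m for m in ev.members if m != name)
            if len(members) >= 2:
                events.append(Group(members))
            elif len(members) == 1:
                events.append(Site(members[0]))
    soft_attrs = {
        rec.name: (rec.chirality, rec.parity)
        for rec in chain.contacts
        if rec.kind == "soft" and rec.name != name
    }
    return _build_chain(events, soft_attrs, chain.termini)


def merge_chains(a: ChainString, b: ChainString) -> ChainString:
    """Concatenate two chains; colliding contact names in ``b`` are renamed
    to fresh letters before the strings merge."""
    taken = set(a.contact_names)
    mapping: dict[str, str] = {}
    fresh = 0
    for name in b.contact_names:
        if name in taken:
            while name_for_index(fresh) in taken or name_for_index(fresh) in b.contact_names:
                fresh += 1
            mapping[name] = name_for_index(fresh)
            taken.add(name_for_index(fresh))
        else:
            mapping[name] = name
            taken.add(name)
    b2 = _rename(b, mapping)
    soft_attrs = {
        rec.name: (rec.chirality, rec.parity)
        for c in (a, b2)
        for rec in c.contacts
        if rec.kind == "soft"
    }
    termini = (a.termini[0], b2.termini[1])
    return _build_chain(list(a.events) + list(b2.events), soft_attrs, termini)


# --------------------------------------------------------------------------
# JSON / file round trips
# --------------------------------------------------------------------------

def chain_to_json(chain: ChainString) -> dict:
    """Lossless JSON event-list representation."""
    events = []
    for ev in chain.events:
        if isinstance(ev, Site):
            events.append({"type": "site", "name": ev.name})
        elif isinstance(ev, Thread):
            events.append({"type": "thread", "sign": ev.sign, "target": ev.target})
        else:
            events.append({"type": "group", "members": list(ev.members)})
    contacts = {
        rec.name: {
            "kind": rec.kind,
            "chirality": rec.chirality,
            "parity": rec.parity,
            "sites": list(rec.sites),
        }
        for rec in chain.contacts
    }
    return {"events": events, "contacts": contacts, "termini": list(chain.termini)}


def chain_from_json(obj: dict) -> ChainString:
    """Rebuild and re-validate a chain from its JSON event list."""
    events: list[Event] = []
    for ev in obj["events"]:
        if ev["type"] == "site":
            events.append(Site(ev["name"]))
        elif ev["type"] == "thread":
            events.append(Thread(ev["sign"], ev["target"]))
        elif ev["type"] == "group":
            events.append(Group(tuple(ev["members"])))
        else:
            raise NotationError(f"unknown event type {ev['type']!r}")
    soft_attrs = {
        name: (c["chirality"], c["parity"])
        for name, c in obj.get("contacts", {}).items()
        if c["kind"] == "soft"
    }
    termini = tuple(obj.get("termini", [None, None]))
    return _build_chain(events, soft_attrs, (termini[0], termini[1]))


def read_ctstr(path) -> list[ChainString]:
    """Read a ``.ctstr`` file: one chain per line, ``#`` comments allowed."""
    chains = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                chains.append(parse_chain(line))
    return chains


def write_ctstr(path, chains: Iterable[ChainString]) -> None:
    with open(path, "w") as fh:
        for chain in chains:
            fh.write(serialize_chain(chain) + "\n")
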