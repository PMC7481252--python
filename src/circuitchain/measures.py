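"""Positional chain measures: contact order and homogeneity.

These measures need more than the topology: each contact site must carry a
coordinate along the chain (residue number, monomer index), and the chain a
total length L.  *Contact order* is the mean sequence separation of contact
sites normalised by L — defined classically for bonded (hard) contacts and
extended here to entanglement (soft) contacts, whose sites can slide, so a
change in soft contact order reports chain deformation.  *Homogeneity*
compares the product of the 2n+1 gaps between consecutive sites (chain ends
included) with its equal-spacing maximum (L/(2n+1))^(2n+1); it is 1 for
perfectly even spacing and falls towards 0 as contacts cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .notation import ChainString, parse_chain

__all__ = ["PositionedChain", "contact_order", "delta_contact_order", "homogeneity",
           "read_positions_tsv"]


@dataclass(frozen=True)
class PositionedChain:
    """A chain whose 2n sites carry coordinates along [0, L].

    ``positions[k]`` is the coordinate of site k+1 (site order of the
    string).  Positions never decrease with site index; sites merged in a
    concerted group share one coordinate.
    """

    chain: ChainString
    positions: tuple[float, ...]
    length: float

    def __post_init__(self) -> None:
        n_sites = 2 * self.chain.n_contacts
        if len(self.positions) != n_sites:
            raise ValueError(
                f"need {n_sites} site positions, got {len(self.positions)}"
            )
        if self.length <= 0:
            raise ValueError("chain length must be positive")
        last = None
        for p in self.positions:
            if not (0 <= p <= self.length):
                raise ValueError(f"position {p} outside [0, L={self.length}]")
            if last is not None and p < last:
                raise ValueError("positions must not decrease along the chain")
            last = p

    @classmethod
    def from_table(cls, chain: ChainString | str, table, length: float) -> "PositionedChain":
        """Build from a (site_token, coordinate) mapping or DataFrame.

        Each contact name maps to its two coordinates in site order; a
        single number per name is rejected.
        """
        if isinstance(chain, str):
            chain = parse_chain(chain)
        if isinstance(table, pd.DataFrame):
            pairs: dict[str, list[float]] = {}
            for name, coord in zip(table.iloc[:, 0], table.iloc[:, 1]):
                pairs.setdefault(str(name), []).append(float(coord))
        else:
            pairs = {k: list(v) for k, v in table.items()}
        used = {name: 0 for name in pairs}
        positions = []
        for name in chain.site_sequence:
            if name not in pairs or used[name] >= len(pairs[name]):
                raise ValueError(f"missing coordinate for a site of {name!r}")
            positions.append(pairs[name][used[name]])
            used[name] += 1
        return cls(chain, tuple(positions), float(length))

    def reversed(self) -> "PositionedChain":
        """The same chain read from the other end (p -> L - p)."""
        from .notation import reverse_chain

        pos = tuple(self.length - p for p in reversed(self.positions))
        return PositionedChain(reverse_chain(self.chain), pos, self.length)


def _selected(pc: PositionedChain, kind: str) -> list[tuple[float, float]]:
    if kind not in ("hard", "soft", "both"):
        raise ValueError("kind must be 'hard', 'soft', or 'both'")
    out = []
    for rec in pc.chain.contacts:
        if kind != "both" and rec.kind != kind:
            continue
        p1 = pc.positions[rec.sites[0] - 1]
        p2 = pc.positions[rec.sites[1] - 1]
        out.append((p1, p2))
    return out


def contact_order(pc: PositionedChain, kind: str = "both") -> float:
    """CO = (1 / (m L)) * sum_i |p2_i - p1_i| over the m selected contacts."""
    pairs = _selected(pc, kind)
    if not pairs:
        raise ValueError(f"no {kind} contacts to average over")
    return sum(abs(b - a) for a, b in pairs) / (len(pairs) * pc.length)


def delta_contact_order(before: PositionedChain, after: PositionedChain,
                        kind: str = "soft") -> float:
    """Change in contact order between two positionings of the same chain —
    a topology-preserving deformation measure (soft sites slide freely)."""
    if before.chain.contact_names != after.chain.contact_names:
        raise ValueError("chains must share the same contacts")
    return contact_order(after, kind) - contact_order(before, kind)


def homogeneity(pc: PositionedChain, kind: str = "both") -> float:
    """Normalised product of the 2n+1 consecutive gaps (chain ends included).

    Equal spacing gives 1 (the product is maximal by AM-GM); clustered or
    coincident sites drive the value towards 0.  Sites merged in a concerted
    group share one coordinate and contribute a single gap boundary, not a
    structural zero.  All selected coordinates must lie strictly inside
    (0, L).
    """
    pairs = _selected(pc, kind)
    if not pairs:
        raise ValueError(f"no {kind} contacts")
    coords = sorted(c for pair in pairs for c in pair)
    if coords[0] <= 0 or coords[-1] >= pc.length:
        raise ValueError("site coordinates must lie strictly inside (0, L)")
    # merged concerted sites: one boundary per distinct coordinate *per group
    # location*; duplicates from distinct locations are genuine zero gaps
    merged: list[float] = []
    group_coords = _group_locations(pc)
    i = 0
    while i < len(coords):
        c = coords[i]
        j = i
        while j + 1 < len(coords) and coords[j + 1] == c:
            j += 1
        copies = j - i + 1
        in_group = group_coords.get(c, 0)
        # collapse at most the group's members into one boundary
        keep = copies - max(0, min(in_group, copies) - 1)
        merged.extend([c] * keep)
        i = j + 1
    bounds = [0.0, *merged, pc.length]
    gaps = [b - a for a, b in zip(bounds, bounds[1:])]
    m = len(gaps)
    norm = (pc.length / m) ** m
    prod = 1.0
    for g in gaps:
        prod *= g
    return prod / norm


def _group_locations(pc: PositionedChain) -> dict[float, int]:
    """Coordinate -> number of sites sharing it through a concerted group."""
    from .notation import Group

    out: dict[float, int] = {}
    idx = 0
    for ev in pc.chain.events:
        if isinstance(ev, Group):
            coords = pc.positions[idx: idx + len(ev.members)]
            for c in set(coords):
                out[c] = max(out.get(c, 0), coords.count(c))
            idx += len(ev.members)
        elif hasattr(ev, "name"):
            idx += 1
    return out


def read_positions_tsv(path) -> pd.DataFrame:
    """Read a (site_token, coordinate) table from TSV."""
    return pd.read_csv(path, sep="\t", header=None, names=["site", "coordinate"],
                       comment="#")
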