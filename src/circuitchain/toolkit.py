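"""Random-chain generation and batch comparison utilities."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .circuits import size_vector, squared_distance, distance, squared_roughness
from .notation import (
    ChainString,
    Site,
    Thread,
    _build_chain,
    name_for_index,
    parse_chain,
)
from .relations import relation_matrix

__all__ = ["GeneratorSpec", "random_chain", "random_chains", "compare_set"]

_SOFT_TYPES = ("+e", "+o", "-e", "-o")


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible random-chain recipe.

    A chain is drawn as a uniformly random perfect matching of the
    2(n_hard + n_soft) contact sites; a random subset of contacts becomes
    soft with types drawn from ``soft_type_weights``; ``n_threads`` thread
    events are then placed strictly inside randomly chosen contact spans
    with coin-flip signs.  The same spec and seed always give the same
    chain.
    """

    n_hard: int = 3
    n_soft: int = 0
    n_threads: int = 0
    seed: int = 0
    soft_type_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        if self.n_hard < 0 or self.n_soft < 0 or self.n_threads < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_hard + self.n_soft < 1:
            raise ValueError("need at least one contact")


def random_chain(spec: GeneratorSpec, rng: np.random.Generator | None = None) -> ChainString:
    """Draw one chain according to ``spec`` (uniform over matchings)."""
    rng = np.random.default_rng(spec.seed) if rng is None else rng
    n = spec.n_hard + spec.n_soft
    slots = 2 * n

    # uniform perfect matching: pair a random permutation two by two
    perm = rng.permutation(slots)
    partner = {}
    for k in range(n):
        a, b = int(perm[2 * k]), int(perm[2 * k + 1])
        partner[a] = b
        partner[b] = a

    names: dict[int, str] = {}
    order: list[str] = []
    for i in range(slots):
        if i not in names:
            label = name_for_index(len(order))
            names[i] = names[partner[i]] = label
            order.append(label)

    soft_names = set(
        order[i] for i in rng.choice(n, size=spec.n_soft, replace=False)
    )
    weights = np.asarray(spec.soft_type_weights, dtype=float)
    weights = weights / weights.sum()
    soft_attrs = {}
    for name in sorted(soft_names):
        code = _SOFT_TYPES[int(rng.choice(4, p=weights))]
        soft_attrs[name] = (code[0], "even" if code[1] == "e" else "odd")

    events: list = [Site(names[i]) for i in range(slots)]

    # threads go strictly inside the span of an existing contact
    for _ in range(spec.n_threads):
        target = order[int(rng.integers(n))]
        lo = min(i for i, ev in enumerate(events) if isinstance(ev, Site) and ev.name == target)
        hi = max(i for i, ev in enumerate(events) if isinstance(ev, Site) and ev.name == target)
        at = int(rng.integers(lo + 1, hi + 1))
        sign = "+" if rng.random() < 0.5 else "-"
        events.insert(at, Thread(sign, order[int(rng.integers(n))]))

    return _build_chain(events, soft_attrs)


def random_chains(spec: GeneratorSpec, count: int) -> list[ChainString]:
    """A reproducible stream of ``count`` chains from one seeded generator."""
    rng = np.random.default_rng(spec.seed)
    return [random_chain(spec, rng) for _ in range(count)]


def compare_set(chains: list[ChainString | str], squared: bool = False):
    """Pairwise circuit-metric distance matrix plus a per-chain report.

    Returns ``(matrix, report)`` where ``matrix`` is a symmetric numpy array
    of distances (or squared distances) between size vectors, and ``report``
    is a JSON-ready dict with each chain's size vector, squared roughness,
    and relation frequencies.
    """
    if len(chains) < 2:
        raise ValueError("need at least two chains to compare")
    parsed = [parse_chain(c) if isinstance(c, str) else c for c in chains]
    sizes = [size_vector(c) for c in parsed]
    m = len(parsed)
    D = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            d = squared_distance(sizes[i], sizes[j]) if squared else distance(
                sizes[i], sizes[j]
            )
            D[i, j] = D[j, i] = d
    report = {
        "chains": [
            {
                "string": str(c),
                "size": list(sizes[i].counts),
                "size_display": sizes[i].digits(),
                "squared_roughness": squared_roughness(sizes[i]),
                "relation_frequencies": relation_matrix(c).frequencies
                if c.n_contacts >= 2
                else {},
            }
            for i, c in enumerate(parsed)
        ],
        "squared": squared,
        "distance_matrix": D.tolist(),
    }
    return D, report
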