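"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: family components are
computed by naive transitive closure instead of graph traversal, and
hypergeometric tails by exhaustive enumeration of all draws instead of the
combinatorial formula.
"""

from __future__ import annotations

import itertools
from typing import Hashable, Iterable


def brute_force_components(
    pairs: Iterable[tuple[Hashable, Hashable]],
) -> set[frozenset]:
    """Connected components by repeated transitive closure over all pairs."""
    pairs = list(pairs)
    comp: dict[Hashable, set] = {}
    for a, b in pairs:
        comp.setdefault(a, {a})
        comp.setdefault(b, {b})
    changed = True
    while changed:
        changed = False
        for a, b in pairs:
            union = comp[a] | comp[b]
            if union != comp[a] or union != comp[b]:
                for node in union:
                    comp[node] = union
                changed = True
    return {frozenset(c) for c in comp.values()}


def enum_hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) by enumerating every size-n draw from an N-unit population
    with K hits.  Only feasible for small N."""
    population = [1] * K + [0] * (N - K)
    total = 0
    at_least_k = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(population[i] for i in draw) >= k:
            at_least_k += 1
    return at_least_k / total
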