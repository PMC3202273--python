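"""Per-family over-representation analysis (ORA).

For each family the engine asks, separately for each of the two compared
objects and for each direction of differential expression, whether the family
contains more significant units than expected from the genome-wide rate.  The
test is the one-sided upper tail of the hypergeometric distribution (the
classical Fisher enrichment convention, equivalent to R's
``phyper(k-1, K, N-K, n, lower.tail=FALSE)``), computed exactly with integer
combinatorics — no normal approximation.

The population background is the number of *all* units at the user-selected
annotation level (all genes, by default), not only those assigned to a
family.  Every family therefore yields exactly four p-values:
(object 1, up), (object 1, down), (object 2, up), (object 2, down).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Mapping, Set

DIRECTIONS = ("up", "down")


def hypergeom_tail(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k), inclusive at k.

    X counts hits when drawing ``n`` units without replacement from a
    population of ``N`` containing ``K`` hits.  Exact integer computation:
    sum_{i=k}^{min(K,n)} C(K,i) C(N-K,n-i) / C(N,n).
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if not isinstance(v, int) or v < 0:
            raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")
    if K > N or n > N:
        raise ValueError(f"require K <= N and n <= N; got K={K}, n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"require k <= min(K, n); got k={k}, K={K}, n={n}")
    if k == 0:
        return 1.0
    numerator = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(K, n) + 1))
    return numerator / comb(N, n)


@dataclass(frozen=True)
class ORAResult:
    """Exactly four p-values for one family, with the (N, K, n, k) counts that
    produced them, keyed by (object_label, direction)."""

    family_id: str
    p_values: dict[tuple[str, str], float]
    counts: dict[tuple[str, str], tuple[int, int, int, int]]

    def __post_init__(self) -> None:
        if len(self.p_values) != 4:
            raise ValueError(
                f"family {self.family_id!r}: expected exactly four p-values, "
                f"got {len(self.p_values)}"
            )
        for key, p in self.p_values.items():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"p-value out of [0,1] for {key}: {p}")

    def relabel(self, mapping: Mapping[str, str]) -> "ORAResult":
        """Rename object labels (used when a matrix is transposed)."""
        return ORAResult(
            self.family_id,
            {(mapping.get(o, o), d): p for (o, d), p in self.p_values.items()},
            {(mapping.get(o, o), d): c for (o, d), c in self.counts.items()},
        )


def ora_family(
    family_id: str,
    family_units: Mapping[str, Set[str]],
    calls: Mapping[str, Mapping[str, str]],
    population: Mapping[str, int],
) -> ORAResult:
    """Four-way ORA for one family.

    ``family_units`` gives the family's units per object label at the counting
    level (genes, proteins, or probes, collapsed per unit beforehand);
    ``calls`` the genome-wide unit -> {'up','down','ns'} calls per object;
    ``population`` the background size N per object.  Units of the family
    absent from the data reduce the draw ``n``; a family with no units in the
    data gets p = 1 in all four directions.
    """
    labels = tuple(family_units)
    if len(labels) != 2 or set(labels) != set(calls) or set(labels) != set(population):
        raise ValueError(
            "family_units, calls and population must share the same two "
            f"object labels; got {sorted(family_units)}, {sorted(calls)}, "
            f"{sorted(population)}"
        )
    p_values: dict[tuple[str, str], float] = {}
    counts: dict[tuple[str, str], tuple[int, int, int, int]] = {}
    for label in labels:
        N = population[label]
        if N <= 0:
            raise ValueError(f"empty population for object {label!r}")
        obj_calls = calls[label]
        in_data = {u for u in family_units[label] if u in obj_calls}
        n = len(in_data)
        for direction in DIRECTIONS:
            K = sum(1 for c in obj_calls.values() if c == direction)
            k = sum(1 for u in in_data if obj_calls[u] == direction)
            p_values[(label, direction)] = hypergeom_tail(k, K, n, N)
            counts[(label, direction)] = (N, K, n, k)
    return ORAResult(family_id, p_values, counts)


def bh_qvalues(p_values: Mapping, alpha: float = 0.05) -> dict:
    """Optional Benjamini–Hochberg q-values over a collection of p-values.

    Off by default in the pipeline: the engine reports raw per-family
    p-values; multiple-testing adjustment is offered behind a flag.
    """
    from statsmodels.stats.multitest import multipletests

    keys = list(p_values)
    if not keys:
        return {}
    _, q, _, _ = multipletests(
        [p_values[k] for k in keys], alpha=alpha, method="fdr_bh"
    )
    return dict(zip(keys, q.tolist()))
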