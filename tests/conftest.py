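"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately re-derive results by enumeration (multiset
counting, union-find, spanning-tree enumeration) and never call the code
paths they check.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np
import pytest

from clonekit.model import MISSING, GenotypeTable, Locus, LocusKind


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def snp_loci(m: int) -> list[Locus]:
    return [
        Locus(id=f"L{j}", kind=LocusKind.SNP, contig=f"c{j}", position=j + 1,
              alleles=("A", "T"))
        for j in range(m)
    ]


def ssr_loci(m: int, n_alleles: int = 6, start: int = 8) -> list[Locus]:
    return [
        Locus(id=f"S{j}", kind=LocusKind.SSR,
              alleles=tuple(range(start, start + n_alleles)))
        for j in range(m)
    ]


def random_snp_table(rng, n: int, m: int, missing_rate: float = 0.1) -> GenotypeTable:
    calls = rng.integers(0, 2, size=(n, m, 2)).astype(np.int16)
    miss = rng.random((n, m)) < missing_rate
    calls[miss] = MISSING
    return GenotypeTable([f"s{i}" for i in range(n)], snp_loci(m), calls)


def random_ssr_table(rng, n: int, m: int, missing_rate: float = 0.1) -> GenotypeTable:
    loci = ssr_loci(m)
    calls = rng.integers(8, 14, size=(n, m, 2)).astype(np.int16)
    miss = rng.random((n, m)) < missing_rate
    calls[miss] = MISSING
    return GenotypeTable([f"s{i}" for i in range(n)], loci, calls)


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def oracle_iam(calls_a, calls_b) -> int:
    """Unmatched allele copies, counted with explicit multisets."""
    total = 0
    for (a1, a2), (b1, b2) in zip(calls_a, calls_b):
        if MISSING in (a1, a2, b1, b2):
            continue
        shared = sum((Counter([a1, a2]) & Counter([b1, b2])).values())
        total += 2 - shared
    return total


def oracle_stepwise(calls_a, calls_b) -> int:
    """Minimum over explicit allele pairings of squared repeat differences."""
    total = 0
    for (a1, a2), (b1, b2) in zip(calls_a, calls_b):
        if MISSING in (a1, a2, b1, b2):
            continue
        total += min(
            (a1 - b1) ** 2 + (a2 - b2) ** 2,
            (a1 - b2) ** 2 + (a2 - b1) ** 2,
        )
    return total


def oracle_union_find(n: int, values: np.ndarray, threshold: float) -> list[int]:
    """Cluster labels from union-find over all pairs with d <= threshold."""
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i in range(n):
        for j in range(i + 1, n):
            if values[i, j] <= threshold:
                parent[find(i)] = find(j)
    return [find(i) for i in range(n)]


def oracle_mst_weight(n: int, values: np.ndarray) -> float:
    """Minimum spanning tree weight by exhaustive enumeration (n <= 7)."""
    edges = [(i, j) for i in range(n) for j in range(i + 1, n)]
    best = np.inf
    for combo in itertools.combinations(edges, n - 1):
        labels = oracle_union_find(
            n,
            np.where(
                np.isin(np.arange(n)[:, None] * n + np.arange(n)[None, :],
                        [i * n + j for i, j in combo] + [j * n + i for i, j in combo]),
                0.0,
                np.inf,
            ),
            0.0,
        )
        if len(set(labels)) == 1:  # spanning
            best = min(best, sum(values[i, j] for i, j in combo))
    return best


def random_distance_matrix(rng, n: int, integer: bool = True) -> np.ndarray:
    """Random symmetric non-negative matrix with zero diagonal (not
    necessarily metric — the clustering contracts don't require it)."""
    v = rng.integers(0, 30, size=(n, n)) if integer else rng.random((n, n)) * 30
    v = np.triu(v, 1)
    v = v + v.T
    return v.astype(float)
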