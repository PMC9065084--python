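"""Induced-edge enrichment of a candidate set in a background network.

Called interactors that already interact with each other in a reference
protein–protein interaction network suggest the pulldown captured
functional complexes rather than random proteins.  This module tests
that claim with a permutation null: the observed number of edges among
the candidates is compared with the edge counts of uniformly drawn
same-size node subsets of the universe.

The null is uniform node sampling, not degree-preserving; the reported
p-value is the add-one-smoothed empirical tail, so it is floored at
1/(1 + n_permutations) and is this package's own statistic, not a
reproduction of any web resource's internal model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .errors import ContainmentError, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EdgeEnrichment:
    """Permutation-test summary for one candidate set."""

    node_set_size: int
    observed_edges: int
    null_mean: float
    null_sd: float
    empirical_p: float
    n_permutations: int
    seed: int


def normalize_edges(edges: Iterable[tuple[str, str]]) -> set[frozenset[str]]:
    """Undirected, de-duplicated edge set; self-loops dropped with a warning."""
    out: set[frozenset[str]] = set()
    n_loops = 0
    for a, b in edges:
        if a == b:
            n_loops += 1
            continue
        out.add(frozenset((a, b)))
    if n_loops:
        logger.warning("dropped %d self-loop(s) from edge list", n_loops)
    return out


def induced_edge_count(edges: Iterable[tuple[str, str]], nodes: Iterable[str]) -> int:
    """Number of unique edges with both endpoints in ``nodes``."""
    node_set = set(nodes)
    return sum(1 for e in normalize_edges(edges) if e <= node_set)


def permutation_edge_test(
    edges: Iterable[tuple[str, str]],
    candidate_nodes: Iterable[str],
    universe: Iterable[str],
    n_permutations: int = 10_000,
    seed: int = 0,
) -> EdgeEnrichment:
    """Test whether the candidates' induced edge count beats random sets.

    Null draws are uniform subsets of ``universe`` of the candidate
    set's size; ``empirical_p = (1 + #{null >= observed}) / (1 + B)``.
    Deterministic for a fixed seed.
    """
    if n_permutations < 100:
        raise ValidationError("n_permutations must be >= 100")
    candidates = sorted(set(candidate_nodes))
    universe_sorted = sorted(set(universe))
    stray = set(candidates) - set(universe_sorted)
    if stray:
        raise ContainmentError(f"candidates not in universe: {sorted(stray)[:10]}")

    edge_set = normalize_edges(edges)
    # adjacency over integer-indexed universe for fast subset counting
    index = {node: i for i, node in enumerate(universe_sorted)}
    pairs = [
        tuple(sorted(index[x] for x in e))
        for e in edge_set
        if all(x in index for x in e)
    ]
    adj: dict[int, set[int]] = {}
    for a, b in pairs:
        adj.setdefault(a, set()).add(b)

    def count(nodes_idx: np.ndarray) -> int:
        members = set(int(i) for i in nodes_idx)
        return sum(len(adj.get(i, set()) & members) for i in members)

    observed = count(np.array([index[c] for c in candidates], dtype=int))
    rng = np.random.default_rng(seed)
    size = len(candidates)
    null = np.empty(n_permutations, dtype=int)
    n_universe = len(universe_sorted)
    for b in range(n_permutations):
        null[b] = count(rng.choice(n_universe, size=size, replace=False))
    p = (1 + int(np.sum(null >= observed))) / (1 + n_permutations)
    return EdgeEnrichment(
        node_set_size=size,
        observed_edges=observed,
        null_mean=float(null.mean()),
        null_sd=float(null.std(ddof=1)) if n_permutations > 1 else 0.0,
        empirical_p=p,
        n_permutations=n_permutations,
        seed=seed,
    )
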