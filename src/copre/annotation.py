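"""Annotation-term over-representation with BH multiple-testing control.

Tests whether annotation terms (GO terms, RNA-binding domains, ...) are
over-represented among called interactors relative to a background
protein universe, using the exact hypergeometric upper tail, and
adjusts the resulting p-values with the Benjamini–Hochberg step-up
procedure across exactly the tested terms.

The background defaults to every protein in the annotation map; a
domain-restricted background (e.g. all proteins carrying the same
RNA-binding domain) is supported by passing it explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .errors import ContainmentError, ValidationError


@dataclass(frozen=True)
class EnrichmentTestResult:
    """One term's over-representation test.

    k of n foreground proteins carry the term; K of N background
    proteins do.
    """

    term_id: str
    k: int
    n: int
    K: int
    N: int
    p_value: float
    p_adjusted: float


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed exactly.

    The urn model: N background proteins of which K carry the term;
    drawing the n-protein foreground without replacement, the chance of
    seeing k or more term carriers.
    """
    if not (0 <= k <= min(n, K) and n <= N and K <= N):
        raise ValidationError(f"invalid bounds: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); exact, not normal-approximated
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini–Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return [float(x) for x in multipletests(p, method="fdr_bh")[1]]


def enrich_terms(
    foreground: Iterable[str],
    background: Iterable[str],
    annotations: Mapping[str, Iterable[str]],
    min_term_size: int = 2,
) -> list[EnrichmentTestResult]:
    """Over-representation tests for every term with >= min_term_size
    background carriers; results sorted by p-value then term id.

    BH adjustment runs across exactly the tested terms, so the
    multiplicity burden reflects what was actually tested.
    """
    fg = set(foreground)
    bg = set(background)
    stray = fg - bg
    if stray:
        raise ContainmentError(
            f"foreground proteins not in background: {sorted(stray)[:10]}"
        )
    if not fg:
        return []

    term_bg: dict[str, set[str]] = {}
    for pid in bg:
        for term in annotations.get(pid, ()):
            term_bg.setdefault(term, set()).add(pid)

    tested = sorted(t for t, carriers in term_bg.items() if len(carriers) >= min_term_size)
    N, n = len(bg), len(fg)
    raw = []
    for term in tested:
        K = len(term_bg[term])
        k = len(term_bg[term] & fg)
        raw.append((term, k, K, hypergeom_upper_tail(k, n, K, N)))
    adjusted = bh_adjust([p for *_, p in raw])
    results = [
        EnrichmentTestResult(term_id=t, k=k, n=n, K=K, N=N, p_value=p, p_adjusted=q)
        for (t, k, K, p), q in zip(raw, adjusted)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results
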