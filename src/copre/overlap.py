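"""Cross-dataset membership, Venn patterns and overlap percentages.

A protein called an interactor in several pulldown/IP datasets is a
candidate general co-factor of miRNA-centered complexes; this module
turns per-dataset interactor sets into the membership matrix behind
that argument and computes the pattern counts, at-least-k tallies and
overlap percentages reported from it.

Percentages round half-away-from-zero to one decimal, matching how the
published figures print values like 18.5% and 29.4%.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .errors import UndefinedPercentageError, ValidationError

#: Named membership patterns of the published Venn-diagram legend:
#: each maps a category symbol to the datasets a protein must occupy.
CATEGORY_PATTERNS: dict[str, frozenset[str]] = {
    "dagger": frozenset({"alg1_ip", "let7_pd", "mir58_pd", "mir2_pd"}),
    "double_dagger": frozenset({"alg1_ip", "let7_pd", "mir58_pd"}),
    "section": frozenset({"let7_pd", "mir58_pd", "mir2_pd"}),
    "pilcrow": frozenset({"alg1_ip", "mir58_pd", "mir2_pd"}),
}


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half-away-from-zero (the convention of printed percentages)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class MembershipMatrix:
    """Protein × dataset boolean presence."""

    dataset_ids: tuple[str, ...]
    present: dict[str, frozenset[str]]  # protein_id -> datasets containing it

    def union_size(self) -> int:
        return len(self.present)

    def members(self, dataset_id: str) -> set[str]:
        if dataset_id not in self.dataset_ids:
            raise ValidationError(f"unknown dataset id {dataset_id!r}")
        return {p for p, ds in self.present.items() if dataset_id in ds}


@dataclass
class OverlapSummary:
    """Exhaustive pattern counts plus named category counts."""

    pattern_counts: dict[frozenset[str], int]
    union_size: int
    category_counts: dict[str, int]


def build_membership(calls_by_dataset: Mapping[str, Iterable[str]]) -> MembershipMatrix:
    """Invert per-dataset protein sets into a membership matrix."""
    dataset_ids = tuple(calls_by_dataset)
    if any(not d for d in dataset_ids):
        raise ValidationError("dataset ids must be non-empty strings")
    if len(set(dataset_ids)) != len(dataset_ids):
        raise ValidationError("dataset ids must be unique")
    present: dict[str, set[str]] = {}
    for d, proteins in calls_by_dataset.items():
        for p in proteins:
            present.setdefault(p, set()).add(d)
    return MembershipMatrix(
        dataset_ids=dataset_ids,
        present={p: frozenset(ds) for p, ds in present.items()},
    )


def count_at_least_k(matrix: MembershipMatrix, k: int) -> int:
    """Number of proteins present in at least k datasets."""
    if k < 1:
        raise ValidationError("k must be >= 1")
    return sum(1 for ds in matrix.present.values() if len(ds) >= k)


def count_pattern(
    matrix: MembershipMatrix,
    required: Iterable[str] = (),
    forbidden: Iterable[str] = (),
) -> int:
    """Proteins present in every required dataset and no forbidden one."""
    required = frozenset(required)
    forbidden = frozenset(forbidden)
    if required & forbidden:
        raise ValidationError("required and forbidden sets overlap")
    known = set(matrix.dataset_ids)
    unknown = (required | forbidden) - known
    if unknown:
        raise ValidationError(f"unknown dataset ids: {sorted(unknown)}")
    return sum(
        1
        for ds in matrix.present.values()
        if required <= ds and not (forbidden & ds)
    )


def pattern_counts(matrix: MembershipMatrix) -> dict[frozenset[str], int]:
    """Exact-pattern counts; every protein contributes to exactly one."""
    out: dict[frozenset[str], int] = {}
    for ds in matrix.present.values():
        out[ds] = out.get(ds, 0) + 1
    return out


def summarize_overlap(matrix: MembershipMatrix) -> OverlapSummary:
    """Pattern counts plus the named Venn-legend category counts."""
    return OverlapSummary(
        pattern_counts=pattern_counts(matrix),
        union_size=matrix.union_size(),
        category_counts={
            name: count_pattern(matrix, required=pattern)
            for name, pattern in CATEGORY_PATTERNS.items()
            if set(pattern) <= set(matrix.dataset_ids)
        },
    )


def pairwise_overlap_percent(
    matrix: MembershipMatrix,
    dataset_a: str,
    dataset_b: str,
    denominator: str = "dataset_a",
    custom_total: int | None = None,
) -> float:
    """100 × |A ∩ B| / denominator, to one decimal.

    ``denominator`` is ``dataset_a`` (|A|), ``union`` (|A ∪ B|) or
    ``custom_total`` (an externally fixed tally passed explicitly, as
    when percentages are quoted against a cross-dataset total).
    """
    a = matrix.members(dataset_a)
    b = matrix.members(dataset_b)
    if denominator == "dataset_a":
        denom = len(a)
    elif denominator == "union":
        denom = len(a | b)
    elif denominator == "custom_total":
        if custom_total is None:
            raise ValidationError("custom_total denominator requires custom_total")
        denom = custom_total
    else:
        raise ValidationError(f"unknown denominator {denominator!r}")
    return percent(len(a & b), denom)


def percent(numerator: int, denominator: int) -> float:
    """One-decimal percentage with half-away-from-zero rounding."""
    if denominator == 0:
        raise UndefinedPercentageError("zero denominator")
    return round_half_up(100.0 * numerator / denominator, 1)


@dataclass(frozen=True)
class BackgroundComparison:
    """Three-way partition of two interactor sets with union percentages."""

    shared: int
    wt_only: int
    mutant_only: int
    shared_pct: float
    wt_only_pct: float
    mutant_only_pct: float


def background_comparison(wt_set: Iterable[str], mutant_set: Iterable[str]) -> BackgroundComparison:
    """Partition two call sets (e.g. wild-type vs mutant-background
    pulldowns of the same bait) into shared / wt-only / mutant-only,
    with percentages of the union."""
    wt = set(wt_set)
    mut = set(mutant_set)
    shared = len(wt & mut)
    wt_only = len(wt - mut)
    mut_only = len(mut - wt)
    union = shared + wt_only + mut_only
    if union == 0:
        return BackgroundComparison(0, 0, 0, 0.0, 0.0, 0.0)
    return BackgroundComparison(
        shared=shared,
        wt_only=wt_only,
        mutant_only=mut_only,
        shared_pct=percent(shared, union),
        wt_only_pct=percent(wt_only, union),
        mutant_only_pct=percent(mut_only, union),
    )


def partition_percentages(shared: int, mutant_only: int, wt_only: int) -> tuple[float, float, float]:
    """Percentages of the union for an already-counted partition."""
    union = shared + mutant_only + wt_only
    return (
        percent(shared, union),
        percent(mutant_only, union),
        percent(wt_only, union),
    )
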