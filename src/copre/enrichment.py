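"""NSAF normalization and interactor calling.

The calling rule turns raw spectral counts into putative physical
interactors of a bait in three deterministic steps:

1. **Identification filter** — a protein must be seen with at least
   ``min_unique_peptides`` unique peptides and a spectral abundance of
   at least ``min_spectral_abundance`` in every pulldown replicate.
2. **NSAF normalization** — within each sample, a protein's spectral
   count S is divided by its length L and normalized to the sample sum,
   NSAF_i = (S_i/L_i) / Σ_j (S_j/L_j), then multiplied by ``scale``
   (default 1e5) so that thresholds are expressed on a convenient unit.
3. **Enrichment thresholds** — the pulldown/control NSAF ratio must be
   ≥ ``ratio_threshold`` in every replicate pair (a zero control NSAF
   is replaced by ``zero_replacement`` before dividing), and the
   pulldown NSAF itself must be ≥ ``min_nsaf`` in every replicate.

All three NSAF-scale parameters (``scale``, ``zero_replacement``,
``min_nsaf``) live on the same unit; co-scaling them leaves the calls
unchanged.  Ties at every threshold are inclusive (≥).  Proteins seen
only in the control are never reported — the rule calls enrichment,
not depletion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .errors import (
    DegenerateSampleError,
    MissingLengthError,
    PairingError,
    ValidationError,
)
from .io_tables import ExperimentTable


@dataclass(frozen=True)
class CallingParams:
    """Thresholds of the identification and enrichment criteria."""

    min_unique_peptides: int = 2
    min_spectral_abundance: float = 4.0
    ratio_threshold: float = 4.0
    zero_replacement: float = 1.0  # on the NSAF scale
    min_nsaf: float = 4.0  # on the NSAF scale
    scale: float = 1e5
    require_all_replicates: bool = True

    def __post_init__(self) -> None:
        for name in ("min_spectral_abundance", "ratio_threshold",
                     "zero_replacement", "min_nsaf", "scale"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_unique_peptides < 1:
            raise ValidationError("min_unique_peptides must be >= 1")


@dataclass
class NSAFProfile:
    """Scaled NSAF values of one sample; values sum to ``scale``."""

    sample_id: str
    nsaf: dict[str, float]
    scale: float = 1e5


@dataclass(frozen=True)
class EnrichmentCall:
    """Per-protein verdict of the calling rule for one bait."""

    protein_id: str
    bait_id: str
    per_replicate_ratio: tuple[float, ...]
    avg_ratio: float
    per_replicate_nsaf: tuple[float, ...]
    passed_identification: bool
    passed_ratio: bool
    passed_min_nsaf: bool
    is_interactor: bool


def compute_nsaf(
    counts: Mapping[str, float],
    lengths: Mapping[str, int],
    scale: float = 1e5,
    sample_id: str = "",
) -> NSAFProfile:
    """Length-normalize spectral counts to NSAF on the given scale.

    NSAF_i = (S_i / L_i) / Σ_j (S_j / L_j) × scale.  NSAF is zero
    exactly where the count is zero, the values sum to ``scale``, and
    multiplying every count by a constant leaves the profile unchanged.
    """
    if scale <= 0:
        raise ValidationError("scale must be > 0")
    saf: dict[str, float] = {}
    for pid, s in counts.items():
        if s < 0:
            raise ValidationError(f"negative count for {pid!r}")
        if s > 0 and pid not in lengths:
            raise MissingLengthError(f"no length for counted protein {pid!r}")
        saf[pid] = s / lengths[pid] if s > 0 else 0.0
    total = sum(saf.values())
    if total == 0:
        raise DegenerateSampleError(
            f"sample {sample_id!r} has no nonzero spectral counts"
        )
    return NSAFProfile(
        sample_id=sample_id,
        nsaf={pid: v / total * scale for pid, v in saf.items()},
        scale=scale,
    )


def identification_filter(
    table: ExperimentTable, params: CallingParams = CallingParams()
) -> set[str]:
    """Proteins identified confidently in every pulldown replicate.

    Requires ``min_unique_peptides`` unique peptides and a summed
    spectral abundance of at least ``min_spectral_abundance`` in each
    pulldown replicate.
    """
    pulldowns = table.samples_of("pulldown")
    if params.require_all_replicates and len(pulldowns) < 2:
        raise ValidationError("need >= 2 pulldown replicates")
    kept: set[str] = set()
    for pid in table.protein_ids():
        ok = all(
            table.peptide(pid, s.sample_id) >= params.min_unique_peptides
            and table.count(pid, s.sample_id) >= params.min_spectral_abundance
            for s in pulldowns
        )
        if ok:
            kept.add(pid)
    return kept


def enrichment_ratio(
    pd_nsaf: float, ctrl_nsaf: float, zero_replacement: float = 1.0
) -> float:
    """Pulldown/control NSAF ratio with zero-control replacement.

    A control NSAF of exactly zero is replaced by ``zero_replacement``
    (same NSAF scale) so the ratio stays finite for proteins absent
    from the scrambled control.
    """
    if pd_nsaf < 0 or ctrl_nsaf < 0:
        raise ValidationError("NSAF values must be non-negative")
    if zero_replacement <= 0:
        raise ValidationError("zero_replacement must be > 0")
    denom = ctrl_nsaf if ctrl_nsaf > 0 else zero_replacement
    return pd_nsaf / denom


def call_interactors(
    table: ExperimentTable,
    lengths: Mapping[str, int],
    params: CallingParams = CallingParams(),
) -> list[EnrichmentCall]:
    """Apply the full calling rule to one bait experiment.

    Pulldown replicate k is paired with control replicate k; an
    unpaired replicate index is an error.  One call is emitted per
    protein passing the identification filter, sorted by protein id.
    """
    pulldowns = table.samples_of("pulldown")
    controls = {s.replicate: s for s in table.samples_of("control")}
    for s in pulldowns:
        if s.replicate not in controls:
            raise PairingError(f"no control replicate {s.replicate} to pair with pulldown")

    identified = identification_filter(table, params)
    if not identified:
        return []

    profiles: dict[str, NSAFProfile] = {}
    for s in table.samples:
        sample_counts = {pid: table.count(pid, s.sample_id) for pid in table.protein_ids()}
        profiles[s.sample_id] = compute_nsaf(
            sample_counts, lengths, scale=params.scale, sample_id=s.sample_id
        )
    calls: list[EnrichmentCall] = []
    for pid in sorted(identified):
        ratios: list[float] = []
        pd_nsafs: list[float] = []
        for s in pulldowns:
            pd_val = profiles[s.sample_id].nsaf.get(pid, 0.0)
            ctrl_val = profiles[controls[s.replicate].sample_id].nsaf.get(pid, 0.0)
            ratios.append(enrichment_ratio(pd_val, ctrl_val, params.zero_replacement))
            pd_nsafs.append(pd_val)
        passed_ratio = all(r >= params.ratio_threshold for r in ratios)
        passed_min_nsaf = all(v >= params.min_nsaf for v in pd_nsafs)
        calls.append(
            EnrichmentCall(
                protein_id=pid,
                bait_id=table.bait_id,
                per_replicate_ratio=tuple(ratios),
                avg_ratio=sum(ratios) / len(ratios),
                per_replicate_nsaf=tuple(pd_nsafs),
                passed_identification=True,
                passed_ratio=passed_ratio,
                passed_min_nsaf=passed_min_nsaf,
                is_interactor=passed_ratio and passed_min_nsaf,
            )
        )
    return calls


def interactor_set(calls: list[EnrichmentCall]) -> set[str]:
    """Protein ids with a positive final verdict."""
    return {c.protein_id for c in calls if c.is_interactor}
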