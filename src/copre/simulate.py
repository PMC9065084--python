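"""Synthetic pulldown/control spectral-count experiments with known truth.

The generator emulates the statistical skeleton of a 2'O-methyl oligo
pulldown experiment read out by shotgun proteomics:

* protein lengths are log-normal (longer proteins yield more peptides,
  hence more spectra — which is exactly what NSAF corrects for);
* each protein carries a log-normal background binding propensity
  (nonspecific stickiness toward the beads/oligo), making counts
  marginally over-dispersed relative to Poisson;
* control counts are Poisson with rates proportional to
  depth × propensity × length, normalized so a sample's expected total
  equals the sequencing depth;
* pulldown counts use the same rates except that a chosen set of true
  interactors has its rate multiplied by ``fold_enrichment``;
* unique peptides follow the spectral count through a saturating link,
  ``min(floor(length/20), 1 + floor(peptide_rate × count / 100))``,
  zero when the count is zero — so the identification filter has bite
  at low depth.

Everything is driven by one integer seed through numpy's SeedSequence,
so a config is byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .enrichment import EnrichmentCall
from .errors import ValidationError
from .io_tables import ExperimentTable, ProteinRecord, SampleColumn


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults are the reference study conditions."""

    n_proteins: int = 500
    n_true_interactors: int = 20
    fold_enrichment: float = 20.0
    sequencing_depth: int = 50_000  # expected total spectra per sample
    length_log_mean: float = 6.0  # log-aa; exp(6) ≈ 400 aa median
    length_log_sd: float = 0.4
    background_concentration_sd: float = 1.0  # log-space propensity spread
    n_replicates: int = 2
    peptide_rate: float = 10.0  # expected unique peptides per 100 spectra
    seed: int = 0
    #: protein ids guaranteed to be true interactors (e.g. a complex core
    #: shared across baits); the rest are drawn uniformly.
    forced_true_interactors: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_true_interactors > self.n_proteins:
            raise ValidationError("n_true_interactors cannot exceed n_proteins")
        if len(self.forced_true_interactors) > self.n_true_interactors:
            raise ValidationError(
                "forced_true_interactors cannot exceed n_true_interactors"
            )
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValidationError("n_proteins and n_replicates must be >= 1")
        if self.fold_enrichment <= 0 or self.peptide_rate <= 0:
            raise ValidationError("fold_enrichment and peptide_rate must be > 0")
        if self.sequencing_depth < 0:
            raise ValidationError("sequencing_depth must be >= 0")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth emitted alongside a simulated experiment."""

    true_interactors: frozenset[str]
    realized_fold: Mapping[str, float]
    config: SimConfig


@dataclass(frozen=True)
class CallingEvaluation:
    """Sensitivity and false-discovery proportion of a call set vs truth."""

    sensitivity: float
    false_discovery_proportion: float
    n_called: int


def _protein_id(i: int) -> str:
    return f"SIM{i:05d}"


def simulate_experiment(
    config: SimConfig,
) -> tuple[ExperimentTable, list[ProteinRecord], SimTruth]:
    """Draw one pulldown+control experiment from the generative model."""
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_proteins
    ids = [_protein_id(i) for i in range(n)]

    lengths = np.maximum(
        50, np.rint(rng.lognormal(config.length_log_mean, config.length_log_sd, n))
    ).astype(int)
    propensity = rng.lognormal(0.0, config.background_concentration_sd, n)

    forced_idx = []
    for pid in config.forced_true_interactors:
        if pid not in ids:
            raise ValidationError(f"forced interactor {pid!r} outside the proteome")
        forced_idx.append(ids.index(pid))
    n_free = config.n_true_interactors - len(forced_idx)
    free_pool = np.array([i for i in range(n) if i not in set(forced_idx)])
    true_idx = np.concatenate(
        [np.array(forced_idx, dtype=int),
         rng.choice(free_pool, size=n_free, replace=False)]
    ).astype(int)
    fold = np.ones(n)
    fold[true_idx] = config.fold_enrichment

    weight = propensity * lengths
    ctrl_rate = config.sequencing_depth * weight / weight.sum()
    pd_rate = ctrl_rate * fold

    caps = np.maximum(1, lengths // 20)
    samples: list[SampleColumn] = []
    counts: dict[tuple[str, str], int] = {}
    peptides: dict[tuple[str, str], int] = {}
    for condition, rate in (("pulldown", pd_rate), ("control", ctrl_rate)):
        for rep in range(1, config.n_replicates + 1):
            sid = f"{condition}_{rep}"
            samples.append(SampleColumn(sid, condition, rep))
            c = rng.poisson(rate)
            pep = np.where(
                c > 0,
                np.minimum(caps, 1 + (config.peptide_rate * c / 100).astype(int)),
                0,
            )
            for i, pid in enumerate(ids):
                if c[i] > 0:
                    counts[(pid, sid)] = int(c[i])
                    peptides[(pid, sid)] = int(pep[i])

    records = [
        ProteinRecord(protein_id=pid, length_aa=int(L)) for pid, L in zip(ids, lengths)
    ]
    truth = SimTruth(
        true_interactors=frozenset(ids[i] for i in true_idx),
        realized_fold={ids[i]: float(fold[i]) for i in true_idx},
        config=config,
    )
    table = ExperimentTable(
        bait_id=f"sim_seed{config.seed}", samples=samples, counts=counts, peptides=peptides
    )
    return table, records, truth


def evaluate_calls(calls: list[EnrichmentCall], truth: SimTruth) -> CallingEvaluation:
    """Score a call set against the simulator's ground truth."""
    called = {c.protein_id for c in calls if c.is_interactor}
    known = {_protein_id(i) for i in range(truth.config.n_proteins)}
    stray = called - known
    if stray:
        raise ValidationError(f"calls outside the simulated namespace: {sorted(stray)[:5]}")
    true = truth.true_interactors
    sens = len(called & true) / len(true) if true else 0.0
    fdp = len(called - true) / max(1, len(called))
    return CallingEvaluation(
        sensitivity=sens, false_discovery_proportion=fdp, n_called=len(called)
    )
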