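import pytest

from copre.io_tables import ExperimentTable, SampleColumn


def build_table(
    pd_reps,
    ctrl_reps,
    peptides=None,
    bait_id="bait",
):
    """Assemble an ExperimentTable from per-replicate count dicts.

    ``pd_reps`` / ``ctrl_reps`` are lists of {protein_id: count}, one per
    replicate.  ``peptides`` maps (protein_id, sample_id) to unique-peptide
    counts; by default every detected protein gets enough peptides to pass
    the identification filter (so tests exercise one criterion at a time).
    """
    samples = []
    counts = {}
    peps = {}
    for condition, reps in (("pulldown", pd_reps), ("control", ctrl_reps)):
        for k, rep_counts in enumerate(reps, start=1):
            sid = f"{condition}_{k}"
            samples.append(SampleColumn(sid, condition, k))
            for pid, c in rep_counts.items():
                counts[(pid, sid)] = c
                peps[(pid, sid)] = 99 if c > 0 else 0
    if peptides:
        peps.update(peptides)
    return ExperimentTable(bait_id=bait_id, samples=samples, counts=counts, peptides=peps)


@pytest.fixture
def two_rep_table():
    """Protein X enriched in pulldown, Y a background protein.

    With unit lengths and scale 10: X pulldown NSAF (8, 8), control
    NSAF (0, 2) — the worked enrichment example.
    """
    return build_table(
        pd_reps=[{"X": 8, "Y": 2}, {"X": 8, "Y": 2}],
        ctrl_reps=[{"Y": 10}, {"X": 2, "Y": 8}],
    )


@pytest.fixture
def unit_lengths():
    return {"X": 1, "Y": 1}
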