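import math

import pytest
from hypothesis import given, settings, strategies as st

from conftest import build_table
from copre.enrichment import (
    CallingParams,
    call_interactors,
    compute_nsaf,
    enrichment_ratio,
    identification_filter,
    interactor_set,
)
from copre.errors import (
    DegenerateSampleError,
    MissingLengthError,
    PairingError,
    ValidationError,
)


class TestComputeNSAF:
    def test_single_protein_carries_the_whole_scale(self):
        prof = compute_nsaf({"A": 17}, {"A": 123}, scale=1.0)
        assert prof.nsaf["A"] == pytest.approx(1.0)

    def test_equal_count_to_length_ratios_split_evenly(self):
        prof = compute_nsaf({"A": 10, "B": 30}, {"A": 100, "B": 300}, scale=1.0)
        assert prof.nsaf["A"] == pytest.approx(0.5)
        assert prof.nsaf["B"] == pytest.approx(0.5)

    def test_hand_evaluated_closed_form(self):
        # S/L: A -> 8/2 = 4, B -> 2/1 = 2; shares 4/6 and 2/6 of 1e5
        prof = compute_nsaf({"A": 8, "B": 2}, {"A": 2, "B": 1}, scale=1e5)
        assert prof.nsaf["A"] == pytest.approx(400000 / 6)
        assert prof.nsaf["B"] == pytest.approx(200000 / 6)

    def test_zero_count_gives_zero_nsaf_without_needing_length(self):
        prof = compute_nsaf({"A": 5, "B": 0}, {"A": 10}, scale=1.0)
        assert prof.nsaf["B"] == 0.0

    def test_counted_protein_without_length_is_an_error(self):
        with pytest.raises(MissingLengthError):
            compute_nsaf({"A": 5}, {}, scale=1.0)

    def test_all_zero_sample_is_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            compute_nsaf({"A": 0, "B": 0}, {"A": 10, "B": 10})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.dictionaries(
            st.text(st.characters(categories=("Lu",)), min_size=1, max_size=3),
            st.integers(min_value=0, max_value=10_000),
            min_size=1,
            max_size=12,
        ),
        scale=st.floats(min_value=1e-3, max_value=1e9),
        multiplier=st.integers(min_value=1, max_value=50),
    )
    def test_conservation_and_proportional_invariance(self, counts, scale, multiplier):
        if sum(counts.values()) == 0:
            counts[next(iter(counts))] = 1
        lengths = {pid: 37 + 11 * i for i, pid in enumerate(sorted(counts))}
        prof = compute_nsaf(counts, lengths, scale=scale)
        assert math.isclose(sum(prof.nsaf.values()), scale, rel_tol=1e-9)
        scaled = compute_nsaf(
            {p: c * multiplier for p, c in counts.items()}, lengths, scale=scale
        )
        for pid in counts:
            assert math.isclose(prof.nsaf[pid], scaled.nsaf[pid], rel_tol=1e-9)


class TestIdentificationFilter:
    def make(self, peptides_by_rep, counts_by_rep):
        peps = {
            ("P", f"pulldown_{k}"): p for k, p in enumerate(peptides_by_rep, start=1)
        }
        return build_table(
            pd_reps=[{"P": c} for c in counts_by_rep],
            ctrl_reps=[{"P": 1}, {"P": 1}],
            peptides=peps,
        )

    def test_boundary_of_the_criterion_is_inclusive(self):
        table = self.make([2, 2], [4, 4])
        assert identification_filter(table) == {"P"}

    def test_one_replicate_below_peptide_floor_rejects(self):
        table = self.make([2, 1], [10, 10])
        assert identification_filter(table) == set()

    def test_one_replicate_below_abundance_floor_rejects(self):
        table = self.make([5, 5], [4, 3])
        assert identification_filter(table) == set()

    def test_requires_two_pulldown_replicates(self):
        table = build_table(pd_reps=[{"P": 9}], ctrl_reps=[{"P": 1}])
        with pytest.raises(ValidationError):
            identification_filter(table)


class TestEnrichmentRatio:
    @pytest.mark.parametrize(
        "pd_val, ctrl, zr, expected",
        [
            (8.0, 2.0, 1.0, 4.0),  # plain division at the threshold boundary
            (7.0, 0.0, 1.0, 7.0),  # zero control replaced before dividing
            (0.0, 5.0, 1.0, 0.0),  # absent in pulldown
            (6.0, 0.0, 2.0, 3.0),  # replacement value is configurable
        ],
    )
    def test_known_values(self, pd_val, ctrl, zr, expected):
        assert enrichment_ratio(pd_val, ctrl, zr) == pytest.approx(expected)

    def test_negative_input_rejected(self):
        with pytest.raises(ValidationError):
            enrichment_ratio(-1.0, 2.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        pd_val=st.floats(min_value=0, max_value=1e6),
        ctrl_lo=st.floats(min_value=0, max_value=1e6),
        delta=st.floats(min_value=0, max_value=1e6),
    )
    def test_monotone_in_both_arguments(self, pd_val, ctrl_lo, delta):
        zr = 1.0
        assert enrichment_ratio(pd_val + delta, ctrl_lo, zr) >= enrichment_ratio(
            pd_val, ctrl_lo, zr
        )
        if ctrl_lo > 0:  # monotone decreasing holds away from the replacement jump
            assert enrichment_ratio(pd_val, ctrl_lo + delta, zr) <= enrichment_ratio(
                pd_val, ctrl_lo, zr
            )


class TestCallInteractors:
    def params(self, **kw):
        defaults = dict(scale=10.0, zero_replacement=1.0, min_nsaf=4.0)
        defaults.update(kw)
        return CallingParams(**defaults)

    def test_hand_traced_two_replicate_call(self, two_rep_table, unit_lengths):
        # X: pulldown NSAF (8, 8), control NSAF (0, 2) on scale 10
        calls = call_interactors(two_rep_table, unit_lengths, self.params())
        (call_x,) = [c for c in calls if c.protein_id == "X"]
        assert call_x.per_replicate_ratio == pytest.approx((8.0, 4.0))
        assert call_x.avg_ratio == pytest.approx(6.0)
        assert call_x.is_interactor

    def test_ratio_must_hold_in_every_replicate(self, unit_lengths):
        # X rep1 ratio 10/1, rep2 ratio 39/10 = 3.9 < 4
        table = build_table(
            pd_reps=[{"X": 100, "Y": 0}, {"X": 39, "Y": 61}],
            ctrl_reps=[{"X": 10, "Y": 90}, {"X": 10, "Y": 90}],
        )
        calls = call_interactors(table, unit_lengths, self.params(scale=100.0, min_nsaf=1.0))
        (call_x,) = [c for c in calls if c.protein_id == "X"]
        assert call_x.per_replicate_ratio == pytest.approx((10.0, 3.9))
        assert not call_x.passed_ratio
        assert not call_x.is_interactor

    def test_min_nsaf_criterion_can_fail_alone(self, unit_lengths):
        table = build_table(
            pd_reps=[{"X": 4, "Y": 96}, {"X": 4, "Y": 96}],
            ctrl_reps=[{"Y": 100}, {"Y": 100}],
        )
        # X pulldown NSAF = 0.4 on scale 10 < min_nsaf 4, but ratio passes via zero control
        calls = call_interactors(table, unit_lengths, self.params(zero_replacement=0.01))
        (call_x,) = [c for c in calls if c.protein_id == "X"]
        assert call_x.passed_ratio
        assert not call_x.passed_min_nsaf
        assert not call_x.is_interactor

    def test_empty_table_gives_empty_call_set(self, unit_lengths):
        table = build_table(pd_reps=[{}, {}], ctrl_reps=[{"Y": 5}, {"Y": 5}])
        assert call_interactors(table, unit_lengths, self.params()) == []

    def test_unpaired_replicate_is_an_error(self, unit_lengths):
        table = build_table(pd_reps=[{"X": 8}, {"X": 8}], ctrl_reps=[{"X": 1}])
        with pytest.raises(PairingError):
            call_interactors(table, unit_lengths, self.params())

    def test_scale_equivariance_of_calls(self, two_rep_table, unit_lengths):
        base = call_interactors(two_rep_table, unit_lengths, self.params())
        for factor in (10.0, 1e4):
            co = call_interactors(
                two_rep_table,
                unit_lengths,
                self.params(
                    scale=10.0 * factor,
                    zero_replacement=1.0 * factor,
                    min_nsaf=4.0 * factor,
                ),
            )
            assert interactor_set(co) == interactor_set(base)
            for a, b in zip(base, co):
                assert a.per_replicate_ratio == pytest.approx(b.per_replicate_ratio)

    def test_raising_ratio_threshold_never_adds_interactors(self):
        lengths = {"X": 1, "Y": 1, "Z": 1}
        table = build_table(
            pd_reps=[{"X": 8, "Y": 2, "Z": 40}, {"X": 8, "Y": 2, "Z": 40}],
            ctrl_reps=[{"Y": 10, "Z": 10}, {"X": 2, "Y": 8, "Z": 10}],
        )
        previous = None
        for thr in (1.0, 2.0, 4.0, 8.0, 100.0):
            current = interactor_set(
                call_interactors(table, lengths, self.params(ratio_threshold=thr))
            )
            if previous is not None:
                assert current <= previous
            previous = current

    def test_rerun_is_identical(self, two_rep_table, unit_lengths):
        a = call_interactors(two_rep_table, unit_lengths, self.params())
        b = call_interactors(two_rep_table, unit_lengths, self.params())
        assert a == b


def brute_force_verdicts(table, lengths, params):
    """Independent re-statement of the calling rule as one literal
    predicate per protein, evaluated without the pipeline machinery."""
    pulldowns = sorted(
        (s for s in table.samples if s.condition == "pulldown"), key=lambda s: s.replicate
    )
    controls = {
        s.replicate: s for s in table.samples if s.condition == "control"
    }
    # per-sample NSAF, written out longhand
    nsaf = {}
    for s in table.samples:
        denom = sum(
            table.count(p, s.sample_id) / lengths[p]
            for p in table.protein_ids()
            if table.count(p, s.sample_id) > 0
        )
        for p in table.protein_ids():
            c = table.count(p, s.sample_id)
            nsaf[(p, s.sample_id)] = (c / lengths[p]) / denom * params.scale if c else 0.0

    verdicts = {}
    for p in table.protein_ids():
        identified = all(
            table.peptide(p, s.sample_id) >= params.min_unique_peptides
            and table.count(p, s.sample_id) >= params.min_spectral_abundance
            for s in pulldowns
        )
        if not identified:
            continue
        ok = True
        for s in pulldowns:
            pd_val = nsaf[(p, s.sample_id)]
            ctrl_val = nsaf[(p, controls[s.replicate].sample_id)]
            ratio = pd_val / (ctrl_val if ctrl_val > 0 else params.zero_replacement)
            if ratio < params.ratio_threshold or pd_val < params.min_nsaf:
                ok = False
        verdicts[p] = ok
    return verdicts


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_calls_match_brute_force_oracle_on_small_tables(data):
    n = data.draw(st.integers(min_value=1, max_value=10))
    pids = [f"P{i}" for i in range(n)]
    lengths = {p: data.draw(st.integers(min_value=50, max_value=2000)) for p in pids}
    count = st.integers(min_value=0, max_value=60)
    pep = st.integers(min_value=0, max_value=8)
    pd_reps, peptides = [], {}
    for k in (1, 2):
        rep = {}
        for p in pids:
            rep[p] = data.draw(count)
            peptides[(p, f"pulldown_{k}")] = data.draw(pep) if rep[p] else 0
        pd_reps.append(rep)
    ctrl_reps = [{p: data.draw(count) for p in pids} for _ in (1, 2)]
    # keep every sample non-degenerate
    for rep in pd_reps + ctrl_reps:
        if sum(rep.values()) == 0:
            rep[pids[0]] = 1
    table = build_table(pd_reps, ctrl_reps, peptides=peptides)
    params = CallingParams(scale=100.0, zero_replacement=0.5, min_nsaf=2.0)

    calls = call_interactors(table, lengths, params)
    expected = brute_force_verdicts(table, lengths, params)
    assert {c.protein_id: c.is_interactor for c in calls} == expected
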