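import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_consensus_pattern
from deduf.consensus import (
    Confidence,
    combine,
    regions_overlap,
    tally,
    tier,
)
from deduf.resolve import MethodAssignment, Status
from deduf.search_io import Method

METHODS = list(Method)


def make_assignment(
    method: Method,
    superfamily: str,
    region=(1, 80),
    query_id="DUF0001",
    status=Status.ASSIGNED,
) -> MethodAssignment:
    return MethodAssignment(
        query_id=query_id,
        method=method,
        region=region,
        superfamily_id=superfamily,
        n_support=1,
        best_score=1e-10,
        status=status,
        provenance=("h1",),
    )


class TestRegionsOverlap:
    def test_full_containment(self):
        assert regions_overlap((1, 100), (30, 90))  # 61/61 of the shorter

    def test_just_over_half_fails_the_sixty_percent_rule(self):
        # overlap 51 residues: 51 % of (1,100), ~50.5 % of (50,150)
        assert not regions_overlap((1, 100), (50, 150))

    def test_identity(self):
        assert regions_overlap((1, 100), (1, 100))

    def test_sixty_percent_of_either_region_suffices(self):
        # overlap 60 = 60 % of the 100-long region
        assert regions_overlap((1, 100), (41, 300))


class TestTier:
    @pytest.mark.parametrize(
        "n,expected",
        [
            (5, Confidence.HIGH),
            (4, Confidence.HIGH),
            (3, Confidence.MEDIUM),
            (2, Confidence.MEDIUM),
            (1, Confidence.LOW),
        ],
    )
    def test_tiering(self, n, expected):
        assert tier(n) is expected

    @pytest.mark.parametrize("n", [0, 6, -1])
    def test_out_of_range(self, n):
        with pytest.raises(ValueError):
            tier(n)


class TestCombine:
    def test_five_way_agreement_is_high_confidence(self):
        assignments = [make_assignment(m, "a.1.1") for m in METHODS]
        records, exclusions = combine(assignments)
        assert exclusions == []
        (rec,) = records
        assert rec.n_methods == 5 and rec.confidence is Confidence.HIGH
        assert rec.outvoted_method is None

    def test_four_against_one_keeps_majority_and_flags_dissenter(self):
        assignments = [make_assignment(m, "a.1.1") for m in METHODS[:4]]
        assignments.append(make_assignment(METHODS[4], "b.1.1"))
        records, exclusions = combine(assignments)
        assert exclusions == []
        (rec,) = records
        assert rec.superfamily_id == "a.1.1"
        assert rec.n_methods == 4 and rec.confidence is Confidence.HIGH
        assert rec.outvoted_method is METHODS[4]
        assert rec.fold_consistent_conflict is False

    def test_two_method_disagreement_excluded_with_fold_flag(self):
        assignments = [
            make_assignment(Method.NRICHD, "a.1.1"),
            make_assignment(Method.HHSEARCH, "a.1.2"),
        ]
        records, exclusions = combine(assignments)
        assert records == []
        (excl,) = exclusions
        assert excl.same_fold is True  # both superfamilies in fold a.1
        assert excl.superfamilies_in_conflict == ("a.1.1", "a.1.2")

    def test_three_against_one_is_excluded(self):
        # the 4-of-5 exception is the only tolerated disagreement
        assignments = [make_assignment(m, "a.1.1") for m in METHODS[:3]]
        assignments.append(make_assignment(METHODS[3], "b.1.1"))
        records, exclusions = combine(assignments)
        assert records == [] and len(exclusions) == 1

    def test_non_overlapping_regions_yield_independent_records(self):
        assignments = [
            make_assignment(Method.NRICHD, "a.1.1", region=(1, 100)),
            make_assignment(Method.HHSEARCH, "b.1.1", region=(150, 250)),
        ]
        records, exclusions = combine(assignments)
        assert len(records) == 2 and exclusions == []
        assert {r.superfamily_id for r in records} == {"a.1.1", "b.1.1"}

    def test_same_method_twice_in_one_region_is_an_error(self):
        assignments = [
            make_assignment(Method.NRICHD, "a.1.1"),
            make_assignment(Method.NRICHD, "a.1.1", region=(5, 85)),
        ]
        with pytest.raises(ValueError, match="two verdicts"):
            combine(assignments)

    def test_unresolved_assignments_are_ignored(self):
        unresolved = MethodAssignment(
            query_id="DUF0001",
            method=Method.NRICHD,
            region=(1, 80),
            superfamily_id=None,
            n_support=0,
            best_score=None,
            status=Status.UNRESOLVED,
        )
        records, exclusions = combine([unresolved])
        assert records == [] and exclusions == []

    def test_all_agreement_patterns_match_enumeration_oracle(self):
        """Exhaustive sweep over agreement patterns of 1–5 methods."""
        sf_options = ["a.1.1", "a.1.2", "b.1.1"]
        for n in range(1, 6):
            for sfs in itertools.product(sf_options, repeat=n):
                assignments = [
                    make_assignment(METHODS[i], sf) for i, sf in enumerate(sfs)
                ]
                records, exclusions = combine(assignments)
                expected = oracle_consensus_pattern(sfs)
                if expected == "consensus":
                    assert len(records) == 1 and not exclusions
                    assert records[0].n_methods == n
                    assert records[0].outvoted_method is None
                elif expected == "outvoted":
                    assert len(records) == 1 and not exclusions
                    assert records[0].n_methods == 4
                    assert records[0].outvoted_method is not None
                else:
                    assert not records and len(exclusions) == 1
                # partition: every assignment lands in exactly one outcome
                n_out = sum(r.n_methods for r in records) + sum(
                    1 for r in records if r.outvoted_method
                )
                n_out += sum(len(e.methods) for e in exclusions)
                assert n_out == n

    @settings(deadline=None, derandomize=True, max_examples=80)
    @given(
        sfs=st.lists(st.sampled_from(["a.1.1", "b.1.1", "c.1.1"]), min_size=1, max_size=5),
        order=st.randoms(use_true_random=False),
    )
    def test_combine_invariant_to_method_input_order(self, sfs, order):
        assignments = [make_assignment(METHODS[i], sf) for i, sf in enumerate(sfs)]
        shuffled = assignments[:]
        order.shuffle(shuffled)
        r1, e1 = combine(assignments)
        r2, e2 = combine(shuffled)
        assert [(r.superfamily_id, r.n_methods) for r in r1] == [
            (r.superfamily_id, r.n_methods) for r in r2
        ]
        assert len(e1) == len(e2)

    def test_dropping_a_method_never_raises_agreement(self):
        """Method removal monotonicity, with the 4v1 -> 3v1 flip asserted exactly."""
        full = [make_assignment(m, "a.1.1") for m in METHODS[:4]]
        full.append(make_assignment(METHODS[4], "b.1.1"))
        records_full, _ = combine(full)
        assert records_full[0].n_methods == 4
        for drop in range(5):
            reduced = [a for i, a in enumerate(full) if i != drop]
            records, exclusions = combine(reduced)
            if drop == 4:  # dissenter removed: clean 4-way agreement remains
                assert records[0].n_methods == 4 and not exclusions
            else:  # a majority member removed: 3v1 is no longer tolerated
                assert not records and len(exclusions) == 1


class TestTally:
    def test_headline_bookkeeping(self):
        records, _ = combine([make_assignment(m, "a.1.1") for m in METHODS])
        summary = tally(records, [])
        assert summary.total_families == 1
        assert summary.families_by_tier == {"high": 1, "medium": 0, "low": 0}
        assert summary.per_method["nrichd"]["n_retained"] == 1

    def test_retained_equals_assigned_minus_discarded(self):
        recs_a, excl_a = combine(
            [
                make_assignment(Method.NRICHD, "a.1.1", query_id="F1"),
                make_assignment(Method.HHSEARCH, "b.1.1", query_id="F1"),
            ]
        )
        recs_b, excl_b = combine([make_assignment(Method.NRICHD, "a.1.1", query_id="F2")])
        summary = tally(recs_a + recs_b, excl_a + excl_b)
        nr = summary.per_method["nrichd"]
        assert nr == {
            "n_assigned_pre_consensus": 2,
            "n_discarded_as_ambiguous": 1,
            "n_retained": 1,
        }
        assert summary.n_exclusion_regions == 1
        assert summary.n_exclusion_families == 1

    def test_empty_input_all_zero(self):
        summary = tally([], [])
        assert summary.total_families == 0
        assert summary.n_records == 0
        assert all(v == 0 for v in summary.families_by_tier.values())
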