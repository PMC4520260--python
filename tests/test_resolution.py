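import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _factories import make_hit
from _oracles import (
    oracle_evalue_tree,
    oracle_frequency,
    oracle_representative_evalue,
    oracle_zscore_tree,
)
from deduf.config import Thresholds
from deduf.resolve import (
    Status,
    derive_indirect,
    filter_hits,
    group_regions,
    passes_filter,
    query_coverage,
    resolve_evalue_tree,
    resolve_frequency,
    resolve_zscore_tree,
)
from deduf.search_io import FamilyLink, Method


class TestCoverageAndFilter:
    @pytest.mark.parametrize(
        "region,qlen,expected",
        [((1, 60), 100, 0.60), ((41, 100), 100, 0.60), ((1, 100), 100, 1.00)],
    )
    def test_query_coverage(self, region, qlen, expected):
        hit = make_hit("a.1.1.1", region=region, query_length=qlen)
        assert query_coverage(hit) == pytest.approx(expected)

    def test_strong_enriched_db_hit_passes(self):
        # magnitudes of a real accepted hit: E ~ 1e-62 at ~97 % coverage
        hit = make_hit("a.1.1.1", Method.NRICHD, score=3.1e-62, region=(1, 97))
        assert passes_filter(hit)

    def test_boundary_values_pass(self):
        assert passes_filter(make_hit("a.1.1.1", Method.NRICHD, score=1e-3, region=(1, 60)))
        assert passes_filter(
            make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=7.5, region=(1, 60))
        )
        assert passes_filter(make_hit("a.1.1.1", Method.PDOMTHREADER, score=1e-5))
        assert passes_filter(make_hit("a.1.1.1", Method.HHSEARCH, score=1e-3, region=(1, 10)))

    def test_failures(self):
        # E-value above cutoff fails despite near-total coverage
        assert not passes_filter(make_hit("a.1.1.1", Method.NRICHD, score=0.01, region=(1, 99)))
        # coverage below 60 % fails the enriched-db search despite tiny E
        assert not passes_filter(make_hit("a.1.1.1", Method.NRICHD, score=1e-40, region=(1, 59)))
        assert not passes_filter(make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=7.4, region=(1, 80)))
        # threading needs both P <= 1e-5 and the CERTAIN tag
        assert not passes_filter(
            make_hit("a.1.1.1", Method.PDOMTHREADER, score=1e-6, source_pass="GUESS")
        )
        assert not passes_filter(make_hit("a.1.1.1", Method.PDOMTHREADER, score=1e-4))

    def test_wrong_score_kind_is_an_error(self):
        hit = make_hit("a.1.1.1", Method.NRICHD)
        object.__setattr__(hit, "evalue", None)
        with pytest.raises(ValueError):
            passes_filter(hit)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(
        evalues=st.lists(
            st.floats(1e-40, 1.0, allow_nan=False), min_size=1, max_size=20
        ),
        tighter=st.floats(1e-6, 1e-3),
    )
    def test_filter_monotone_in_threshold(self, evalues, tighter):
        """Tightening the E-value cutoff never admits additional hits."""
        hits = [
            make_hit("a.1.1.1", Method.HHSEARCH, score=e, hit_id=f"h{i}")
            for i, e in enumerate(evalues)
        ]
        loose = set(
            h.hit_id for h in filter_hits(hits, Thresholds(evalue_max=1e-3))
        )
        tight = set(
            h.hit_id for h in filter_hits(hits, Thresholds(evalue_max=tighter))
        )
        assert tight <= loose


class TestRegionGrouping:
    def test_containment_links(self):
        hits = [make_hit("a.1.1.1", region=(1, 100)), make_hit("a.1.1.1", region=(30, 90))]
        assert len(group_regions(hits)) == 1

    def test_disjoint_regions_stay_apart(self):
        hits = [
            make_hit("a.1.1.1", region=(1, 100), query_length=300),
            make_hit("a.1.1.1", region=(120, 200), query_length=300),
        ]
        assert len(group_regions(hits)) == 2

    def test_chained_overlap_merges_transitively(self):
        hits = [
            make_hit("a.1.1.1", region=r, query_length=300, hit_id=f"h{i}")
            for i, r in enumerate([(1, 100), (40, 140), (80, 180)])
        ]
        groups = group_regions(hits)
        # brute-force connected components over the pairwise 60 % rule
        import networkx as nx

        from deduf.consensus import regions_overlap

        g = nx.Graph()
        g.add_nodes_from(range(3))
        for i, j in itertools.combinations(range(3), 2):
            if regions_overlap(hits[i].region, hits[j].region):
                g.add_edge(i, j)
        assert len(groups) == nx.number_connected_components(g)
        assert len(groups) == 1

    def test_envelope_is_min_start_max_end(self):
        hits = [make_hit("a.1.1.1", region=(5, 80)), make_hit("a.1.1.1", region=(1, 70))]
        a = resolve_evalue_tree(hits)
        assert a.region == (1, 80)


class TestEvalueTree:
    def test_unanimous_superfamily_takes_best_hit(self):
        hits = [
            make_hit("a.1.1.1", score=1e-10, region=(1, 80), hit_id="h1"),
            make_hit("a.1.1.2", score=1e-5, region=(1, 90), hit_id="h2"),
        ]
        a = resolve_evalue_tree(hits)
        assert a.status is Status.ASSIGNED
        assert a.superfamily_id == "a.1.1"
        assert a.best_score == 1e-10
        assert a.n_support == 2

    def test_same_fold_takes_modal_superfamily(self):
        hits = [make_hit("a.1.1.1", hit_id=f"a{i}") for i in range(3)]
        hits += [make_hit("a.1.2.1", hit_id="b0")]
        a = resolve_evalue_tree(hits)
        assert a.superfamily_id == "a.1.1"
        assert a.n_support == 3

    def test_cross_fold_needs_count_margin_above_ten(self):
        hits = [make_hit("a.1.1.1", hit_id=f"a{i}") for i in range(12)]
        hits += [make_hit("b.1.1.1", hit_id="b0")]
        assert resolve_evalue_tree(hits).superfamily_id == "a.1.1"  # margin 11 > 10
        hits = [make_hit("a.1.1.1", hit_id=f"a{i}") for i in range(5)]
        hits += [make_hit("b.1.1.1", hit_id=f"b{i}") for i in range(3)]
        assert resolve_evalue_tree(hits).status is Status.UNRESOLVED  # margin 2

    def test_margin_exactly_ten_is_not_enough(self):
        hits = [make_hit("a.1.1.1", hit_id=f"a{i}") for i in range(11)]
        hits += [make_hit("b.1.1.1", hit_id="b0")]
        assert resolve_evalue_tree(hits).status is Status.UNRESOLVED

    def test_representative_tiebreak_evalue_then_coverage(self):
        hits = [
            make_hit("a.1.1.1", score=1e-10, region=(1, 70), hit_id="h_narrow"),
            make_hit("a.1.1.1", score=1e-10, region=(1, 90), hit_id="h_wide"),
        ]
        a = resolve_evalue_tree(hits)
        rep = oracle_representative_evalue(hits)
        assert rep.hit_id == "h_wide"
        assert a.best_score == rep.evalue

    def test_empty_group_is_an_error(self):
        with pytest.raises(ValueError):
            resolve_evalue_tree([])


class TestZscoreTree:
    def test_unanimous_takes_highest_z(self):
        hits = [
            make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=9.0, hit_id="h1"),
            make_hit("a.1.1.2", Method.SUPFAM_PLUS, score=11.0, hit_id="h2"),
        ]
        a = resolve_zscore_tree(hits)
        assert a.superfamily_id == "a.1.1" and a.best_score == 11.0

    @pytest.mark.parametrize(
        "z_top,z_second,resolved",
        [(14.0, 7.6, True), (12.0, 7.6, False)],  # margins 6.4 and 4.4 vs >= 6
    )
    def test_cross_class_margin_six(self, z_top, z_second, resolved):
        hits = [
            make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=z_top, hit_id="h1"),
            make_hit("b.1.1.1", Method.SUPFAM_PLUS, score=z_second, hit_id="h2"),
        ]
        a = resolve_zscore_tree(hits)
        if resolved:
            assert a.superfamily_id == "a.1.1"
        else:
            assert a.status is Status.UNRESOLVED

    @pytest.mark.parametrize(
        "z_top,z_second,resolved", [(12.0, 8.0, True), (11.9, 8.0, False)]
    )
    def test_cross_fold_same_class_margin_four_inclusive(self, z_top, z_second, resolved):
        hits = [
            make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=z_top, hit_id="h1"),
            make_hit("a.2.1.1", Method.SUPFAM_PLUS, score=z_second, hit_id="h2"),
        ]
        a = resolve_zscore_tree(hits)
        assert (a.status is Status.ASSIGNED) == resolved

    def test_any_cross_class_pair_triggers_the_class_margin(self):
        # folds differ within class a, but a class-b hit is present:
        # the stricter >= 6 margin applies to the top two best-Z superfamilies
        hits = [
            make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=14.0, hit_id="h1"),
            make_hit("a.2.1.1", Method.SUPFAM_PLUS, score=8.0, hit_id="h2"),
            make_hit("b.1.1.1", Method.SUPFAM_PLUS, score=7.6, hit_id="h3"),
        ]
        a = resolve_zscore_tree(hits)  # lead 14 - 8 = 6 meets the class margin
        assert a.status is Status.ASSIGNED and a.superfamily_id == "a.1.1"
        # lead 13 - 8 = 5: enough for the within-class margin of 4, but the
        # cross-class hit demands 6, so the group stays unresolved
        hits[0] = make_hit("a.1.1.1", Method.SUPFAM_PLUS, score=13.0, hit_id="h1")
        assert resolve_zscore_tree(hits).status is Status.UNRESOLVED


class TestFrequencyRule:
    def test_modal_superfamily(self):
        hits = [make_hit("a.1.1.1", Method.PDOMTHREADER, hit_id=f"a{i}") for i in range(2)]
        hits += [make_hit("b.1.1.1", Method.PDOMTHREADER, hit_id="b0")]
        assert resolve_frequency(hits).superfamily_id == "a.1.1"

    def test_single_hit_assigns(self):
        (a,) = [resolve_frequency([make_hit("a.1.1.1", Method.PDOMTHREADER)])]
        assert a.superfamily_id == "a.1.1" and a.n_support == 1

    def test_tie_for_mode_is_unresolved(self):
        hits = [make_hit("a.1.1.1", Method.PDOMTHREADER, hit_id=f"a{i}") for i in range(2)]
        hits += [make_hit("b.1.1.1", Method.PDOMTHREADER, hit_id=f"b{i}") for i in range(2)]
        assert resolve_frequency(hits).status is Status.UNRESOLVED
        assert oracle_frequency(hits) is None


class TestTreeProperties:
    def _outcomes(self, group):
        impl = {
            "evalue": resolve_evalue_tree,
            "zscore": resolve_zscore_tree,
            "pvalue": lambda g: resolve_frequency(g),
        }[group[0].score_kind](group)
        oracle = {
            "evalue": oracle_evalue_tree,
            "zscore": oracle_zscore_tree,
            "pvalue": oracle_frequency,
        }[group[0].score_kind](group)
        return impl, oracle

    @settings(deadline=None, derandomize=True, max_examples=150)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["a.1.1.1", "a.1.2.1", "a.2.1.1", "b.1.1.1"]),
                st.floats(7.5, 30.0, allow_nan=False),
            ),
            min_size=1,
            max_size=12,
        ),
        kind=st.sampled_from(["evalue", "zscore", "pvalue"]),
    )
    def test_trees_match_oracle_and_are_permutation_invariant(self, data, kind):
        method = {
            "evalue": Method.NRICHD,
            "zscore": Method.SUPFAM_PLUS,
            "pvalue": Method.PDOMTHREADER,
        }[kind]
        group = [
            make_hit(
                sccs,
                method,
                score=(10.0 ** -z if kind != "zscore" else z),
                hit_id=f"h{i:02d}",
            )
            for i, (sccs, z) in enumerate(data)
        ]
        impl, oracle = self._outcomes(group)
        assert impl.superfamily_id == oracle
        assert (impl.status is Status.ASSIGNED) == (oracle is not None)
        if impl.status is Status.ASSIGNED:
            # no invented labels: winner must be a supporting hit's superfamily
            assert impl.superfamily_id in {h.lineage.superfamily_id for h in group}
            assert impl.n_support >= 1
        reversed_impl, _ = self._outcomes(list(reversed(group)))
        assert reversed_impl.superfamily_id == impl.superfamily_id
        assert reversed_impl.status == impl.status


class TestIndirectMapping:
    def test_one_hop_inheritance(self):
        links = [FamilyLink.canonical("A", "B", 9.5, 0.9, 0.85)]
        assert derive_indirect({"B": "a.1.1"}, links) == {"A": "a.1.1"}

    def test_boundary_link_qualifies(self):
        links = [FamilyLink.canonical("A", "B", 9.0, 0.80, 0.80)]
        assert derive_indirect({"B": "a.1.1"}, links) == {"A": "a.1.1"}

    @pytest.mark.parametrize(
        "z,ca,cb", [(8.9, 0.9, 0.9), (9.5, 0.79, 0.9), (9.5, 0.9, 0.79)]
    )
    def test_subthreshold_links_do_not_qualify(self, z, ca, cb):
        links = [FamilyLink.canonical("A", "B", z, ca, cb)]
        assert derive_indirect({"B": "a.1.1"}, links) == {}

    def test_conflicting_neighbours_block_assignment(self):
        # enumerate all 3-node link graphs A-{B,C} with B,C directly mapped
        for sf_b, sf_c in itertools.product(["a.1.1", "b.1.1"], repeat=2):
            links = [
                FamilyLink.canonical("A", "B", 10.0, 0.9, 0.9),
                FamilyLink.canonical("A", "C", 10.0, 0.9, 0.9),
            ]
            result = derive_indirect({"B": sf_b, "C": sf_c}, links)
            if sf_b == sf_c:
                assert result == {"A": sf_b}
            else:
                assert result == {}

    def test_no_transitive_chaining(self):
        # C-B qualifies and B-A qualifies, but C only reaches a mapped
        # family through B, which is itself indirect: no assignment for C
        links = [
            FamilyLink.canonical("A", "B", 10.0, 0.9, 0.9),
            FamilyLink.canonical("B", "C", 10.0, 0.9, 0.9),
        ]
        result = derive_indirect({"A": "a.1.1"}, links)
        assert result == {"B": "a.1.1"}  # C absent: one hop only

    def test_directly_mapped_families_not_reassigned(self):
        links = [FamilyLink.canonical("A", "B", 10.0, 0.9, 0.9)]
        assert derive_indirect({"A": "a.1.1", "B": "b.1.1"}, links) == {}
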