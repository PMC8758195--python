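"""Decision tree: distances, evidence counting, tiers and link classification."""

import dataclasses
import datetime as dt

import numpy as np
import pytest

from eggmatch.features import MatchGraph
from eggmatch.infer import (ClutchPairEvidence, NestRecord, TierParams,
                            classify_link, compute_pair_evidence,
                            find_symmetrical_matches, load_case_study,
                            nest_distance, parse_nest_date, report,
                            tier_screen, top_k_tally)
import pandas as pd


def graph_from_matrix(ids, mat):
    frame = pd.DataFrame(mat, index=ids, columns=ids)
    ranked = {}
    for i, egg in enumerate(ids):
        others = [(ids[j], float(mat[i][j])) for j in range(len(ids)) if j != i]
        others.sort(key=lambda t: (t[1], t[0]))
        ranked[egg] = others
    return MatchGraph(batch_label="test", egg_ids=list(ids),
                      dissimilarity=frame, ranked=ranked)


def nest(nid, year, x=0.0, y=0.0, first_egg=None, fate="H", last=None):
    return NestRecord(nest_id=nid, year=year, easting_m=x, northing_m=y,
                      first_egg_date=first_egg, last_active_date=last, fate=fate)


class TestNestDistance:
    def test_identical_coordinates(self):
        assert nest_distance(nest("a", 2020), nest("b", 2020)) == 0.0

    def test_three_four_five(self):
        assert nest_distance(nest("a", 2020), nest("b", 2020, 30, 40)) == 50.0

    def test_matches_planar_oracle(self, rng):
        for _ in range(20):
            xa, ya, xb, yb = rng.uniform(-5000, 5000, 4)
            got = nest_distance(nest("a", 2020, xa, ya), nest("b", 2020, xb, yb))
            assert got == pytest.approx(((xa - xb) ** 2 + (ya - yb) ** 2) ** 0.5)

    def test_missing_coordinates_rejected(self):
        a = NestRecord(nest_id="a", year=2020)
        with pytest.raises(ValueError):
            nest_distance(a, nest("b", 2020))


class TestSymmetricalMatches:
    def test_reciprocal_pair_counted_once(self):
        # A1<->B1 reciprocal; A2 chains to B2 whose best is B1 (no pair)
        ids = ["A1", "A2", "B1", "B2"]
        M = 9.0 * np.ones((4, 4))
        np.fill_diagonal(M, 0.0)
        M[0, 2] = M[2, 0] = 0.1  # A1-B1 mutual
        M[1, 3] = 0.2  # A2 -> B2
        M[3, 2] = 0.15  # B2 -> B1 (within clutch B)
        M[1, 0] = 5.0
        graph = graph_from_matrix(ids, M)
        clutch = {"A1": "A", "A2": "A", "B1": "B", "B2": "B"}
        counts = find_symmetrical_matches(graph, clutch)
        assert counts[frozenset(("A", "B"))] == 1

    def test_chain_contributes_nothing(self):
        # best(A1)=B1 but best(B1)=C1: no symmetrical pair for (A, B)
        ids = ["A1", "B1", "C1"]
        M = np.array([[0, 1.0, 2.0], [1.0, 0, 0.5], [2.0, 0.5, 0]])
        graph = graph_from_matrix(ids, M)
        clutch = {"A1": "A", "B1": "B", "C1": "C"}
        counts = find_symmetrical_matches(graph, clutch)
        assert counts[frozenset(("A", "B"))] == 0


class TestTopKTally:
    def test_absent_clutch_tallies_zero(self, population_graph, population):
        clutch_of = population.clutch_of
        clutches = sorted({clutch_of[e] for e in population_graph.egg_ids})
        t_eggs, t_total = top_k_tally(population_graph, clutch_of,
                                      clutches[0], "no-such-clutch", k=8)
        assert (t_eggs, t_total) == (0, 0)

    def test_matches_direct_recount(self, population_graph, population):
        clutch_of = population.clutch_of
        clutches = sorted({clutch_of[e] for e in population_graph.egg_ids})
        a, b = clutches[0], clutches[1]
        _, total = top_k_tally(population_graph, clutch_of, a, b, k=8)
        recount = 0
        for egg in population_graph.egg_ids:
            if clutch_of[egg] != a:
                continue
            top = [other for other, _ in population_graph.ranked[egg][:8]]
            recount += sum(clutch_of[o] == b for o in top)
        assert total == recount

    def test_k_exceeding_pool_errors(self, population_graph, population):
        clutch_of = population.clutch_of
        clutches = sorted({clutch_of[e] for e in population_graph.egg_ids})
        with pytest.raises(ValueError):
            top_k_tally(population_graph, clutch_of, clutches[0], clutches[1],
                        k=len(population_graph.egg_ids))


def evidence(n_sym=0, multi_ab=0, multi_ba=0, tally_ab=0, tally_ba=0,
             dist=1000.0, year_a=2020, year_b=2020, fe_a=None, fe_b=None,
             fate_a="H", fate_b="H"):
    return ClutchPairEvidence(
        nest_a="na", nest_b="nb", n_symmetrical=n_sym,
        n_multi_ab=multi_ab, n_multi_ba=multi_ba,
        tally_ab=tally_ab, tally_ba=tally_ba,
        eggs_with_hit_ab=multi_ab, eggs_with_hit_ba=multi_ba,
        distance_m=dist, year_a=year_a, year_b=year_b,
        first_egg_a=fe_a, first_egg_b=fe_b, fate_a=fate_a, fate_b=fate_b)


class TestTierScreen:
    def test_below_tally_threshold_is_no_candidate(self):
        ev = evidence(multi_ab=2, tally_ab=3)
        assert tier_screen([ev]) == []

    def test_tier_one_takes_precedence(self):
        ev = evidence(n_sym=1, multi_ab=3, tally_ab=8)
        results = tier_screen([ev])
        assert [r.tier for r in results] == ["I"]
        assert results[0].requires_visual_review

    def test_tier_two_splits_by_year(self):
        same = evidence(multi_ab=2, tally_ab=4)
        different = evidence(multi_ab=2, tally_ab=4, year_a=2019)
        tiers = {r.tier for r in tier_screen([same, different])}
        assert tiers == {"IIb", "IIa"}

    def test_directional_criteria_not_mixed_across_directions(self):
        # two multi one way, the tally the other way: not a Tier II candidate
        ev = evidence(multi_ab=2, tally_ba=6)
        assert tier_screen([ev]) == []

    def test_stringency_sweep_weakly_shrinks_candidates(self, population,
                                                        population_features):
        from eggmatch.features import build_match_graph
        graph = build_match_graph(population_features, "all")
        nests = {n.nest_id: n for n in population.nests}
        previous = None
        for k in (8, 7, 6, 5):
            ev = compute_pair_evidence(graph, population.clutch_of, nests, k=k)
            pairs = {r.pair for r in tier_screen(ev)}
            if previous is not None:
                assert pairs <= previous
            previous = pairs


class TestClassifyLink:
    def run(self, ev):
        (result,) = tier_screen([dataclasses.replace(ev)]) or [None]
        return classify_link(result)

    def test_different_years_imply_returning_breeder(self):
        ev = evidence(n_sym=1, multi_ab=2, year_a=2019, year_b=2020,
                      fe_a=dt.date(2019, 6, 3), fe_b=dt.date(2020, 4, 22),
                      dist=61.0)
        assert self.run(ev).inferred_link == "returning_breeder"

    def test_synchronous_same_season_implies_cbp(self):
        ev = evidence(n_sym=1, multi_ab=2, dist=91.0,
                      fe_a=dt.date(2020, 5, 4), fe_b=dt.date(2020, 5, 3))
        assert self.run(ev).inferred_link == "CBP"

    def test_long_gap_after_failed_nest_implies_renest(self):
        ev = evidence(multi_ab=2, tally_ab=4, dist=3305.0, fate_a="P",
                      fe_a=dt.date(2012, 4, 21), fe_b=dt.date(2012, 6, 23))
        assert self.run(ev).inferred_link == "renest"

    def test_boundary_gap_of_synchrony_window_is_cbp(self):
        ev = evidence(multi_ab=2, tally_ab=4,
                      fe_a=dt.date(2020, 5, 1), fe_b=dt.date(2020, 5, 22))
        assert self.run(ev).inferred_link == "CBP"

    def test_intermediate_gap_stays_unclassified(self):
        ev = evidence(multi_ab=2, tally_ab=4, fate_a="P",
                      fe_a=dt.date(2020, 5, 1), fe_b=dt.date(2020, 5, 31))
        res = self.run(ev)
        assert res.inferred_link == "unclassified"
        assert "gap_between_synchrony_and_renest_windows" in res.flags

    def test_long_gap_after_successful_nest_not_a_renest(self):
        ev = evidence(multi_ab=2, tally_ab=4, fate_a="H",
                      fe_a=dt.date(2020, 4, 1), fe_b=dt.date(2020, 6, 15))
        assert self.run(ev).inferred_link == "unclassified"

    def test_missing_dates_never_raise(self):
        ev = evidence(multi_ab=2, tally_ab=4)  # same season, no dates
        res = self.run(ev)
        assert res.inferred_link == "unclassified"
        assert "season_undetermined" in res.flags


class TestDateParsing:
    @pytest.mark.parametrize("text,expected,approx", [
        ("2020-05-04", dt.date(2020, 5, 4), False),
        ("5/4/2020", dt.date(2020, 5, 4), False),
        ("5/13-15/2012?", dt.date(2012, 5, 13), True),
        ("Early May", dt.date(2020, 5, 5), True),
        ("Mid June 2019", dt.date(2019, 6, 15), True),
        ("-", None, False),
        ("", None, False),
    ])
    def test_formats(self, text, expected, approx):
        got, got_approx = parse_nest_date(text, year_hint=2020)
        assert got == expected and got_approx == approx

    def test_unparseable_raises(self):
        with pytest.raises(ValueError):
            parse_nest_date("sometime in spring")

    def test_any_calendar_date_roundtrips_through_field_format(self):
        from hypothesis import given, settings
        from hypothesis import strategies as st

        @given(st.dates(min_value=dt.date(1990, 1, 1),
                        max_value=dt.date(2030, 12, 31)))
        @settings(max_examples=50, deadline=None)
        def roundtrip(d):
            text = f"{d.month}/{d.day}/{d.year}"
            got, approx = parse_nest_date(text)
            assert got == d and not approx

        roundtrip()


class TestCaseStudy:
    def test_published_pairs_reproduce_tiers_and_links(self):
        ev, expected = load_case_study()
        results = [classify_link(r) for r in tier_screen(ev)]
        assert len(results) == len(expected) == 9
        by_pair = {r.pair: r for r in results}
        for row in expected.itertuples(index=False):
            r = by_pair[(row.nest_a, row.nest_b)]
            assert r.tier == row.tier_published
            assert r.inferred_link == row.inferred_link_published

    def test_report_has_nine_rows_with_full_columns(self):
        ev, _ = load_case_study()
        rep = report([classify_link(r) for r in tier_screen(ev)])
        assert len(rep) == 9
        assert {"tier", "nest_a", "nest_b", "distance_m",
                "inferred_link"} <= set(rep.columns)

    def test_empty_results_give_header_only_table(self):
        rep = report([])
        assert len(rep) == 0 and "inferred_link" in rep.columns
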