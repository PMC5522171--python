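"""Link filtering, herb mapping and target-profile scoring."""

import random

import pytest

from herbnet.mapping import (
    apply_exclusions,
    build_target_profile,
    build_target_profiles,
    filter_links,
    group_summaries,
    map_compounds_to_herbs,
    rank_herbs,
    round_half_up,
)
from herbnet.types import ChemicalProteinLink, GeneRecord, HerbRecord


def link(c, p, conf):
    return ChemicalProteinLink(c, c, p, conf)


class TestFilterLinks:
    def test_boundary_inclusive_and_hub_restricted(self):
        links = [link("c1", "P1", 0.90), link("c1", "Q1", 0.95), link("c2", "P1", 0.89)]
        kept = filter_links(links, hubs={"P1"}, min_conf=0.9)
        assert kept == [links[0]]

    def test_idempotent(self):
        rng = random.Random(5)
        links = [
            link(f"c{i}", f"P{rng.randrange(20)}", round(rng.random(), 3))
            for i in range(200)
        ]
        hubs = {f"P{i}" for i in range(0, 20, 2)}
        once = filter_links(links, hubs)
        assert filter_links(once, hubs) == once

    def test_matches_exhaustive_scan(self):
        rng = random.Random(9)
        links = [
            link(f"c{rng.randrange(30)}", f"P{rng.randrange(25)}", round(rng.random(), 3))
            for _ in range(300)
        ]
        hubs = {f"P{i}" for i in range(12)}
        expected = [l for l in links if l.confidence >= 0.9 and l.protein in hubs]
        assert filter_links(links, hubs, 0.9) == expected


class TestCompoundHerbMapping:
    def test_unmatched_compound_absent(self):
        herbs = [HerbRecord("h1", "A", "a", 1, frozenset({"c1"}))]
        matched, cands = map_compounds_to_herbs([link("c9", "P", 0.95)], herbs)
        assert matched == frozenset() and cands == frozenset()

    def test_shared_compound_maps_to_all_holders(self):
        herbs = [
            HerbRecord(f"h{i}", f"L{i}", f"p{i}", 1, frozenset({"c1"})) for i in range(3)
        ]
        matched, cands = map_compounds_to_herbs([link("c1", "P", 0.95)], herbs)
        assert matched == frozenset({"c1"})
        assert cands == frozenset({"h0", "h1", "h2"})

    def test_matches_nested_loop_join(self):
        rng = random.Random(13)
        compounds = [f"c{i}" for i in range(40)]
        herbs = [
            HerbRecord(
                f"h{i}", f"L{i}", f"p{i}", 1,
                frozenset(rng.sample(compounds, rng.randrange(1, 8))),
            )
            for i in range(15)
        ]
        links = [link(rng.choice(compounds), "P", 0.95) for _ in range(25)]
        matched, cands = map_compounds_to_herbs(links, herbs)
        link_compounds = {l.compound_id for l in links}
        exp_matched = {
            c for c in link_compounds for h in herbs if c in h.ingredients
        }
        exp_cands = {
            h.herb_id for h in herbs for c in link_compounds if c in h.ingredients
        }
        assert matched == exp_matched and cands == exp_cands


class TestExclusions:
    def test_flagged_herbs_removed(self):
        herbs = [
            HerbRecord("h1", "Keep", "k", 1, frozenset({"c"})),
            HerbRecord("h2", "Unconv", "u", 8, frozenset({"c"}), True, "unconventional"),
            HerbRecord("h3", "Toxic", "t", 8, frozenset({"c"}), True, "toxic"),
        ]
        retained = apply_exclusions({"h1", "h2", "h3"}, herbs)
        assert [h.herb_id for h in retained] == ["h1"]

    def test_no_flags_is_identity(self):
        herbs = [HerbRecord(f"h{i}", f"L{i}", "", 1, frozenset({"c"})) for i in range(4)]
        retained = apply_exclusions({h.herb_id for h in herbs}, herbs)
        assert {h.herb_id for h in retained} == {h.herb_id for h in herbs}


class TestTargetProfile:
    DEGS = [GeneRecord("P1", "up"), GeneRecord("P2", "down"), GeneRecord("P3", "down")]

    def test_empty_when_no_matched_ingredients(self):
        herb = HerbRecord("h1", "A", "a", 1, frozenset({"nope"}))
        prof = build_target_profile(herb, [link("c1", "P1", 0.95)], self.DEGS)
        assert prof.n_targets == 0

    def test_same_protein_counted_once(self):
        herb = HerbRecord("h1", "A", "a", 1, frozenset({"c1", "c2"}))
        links = [link("c1", "P1", 0.95), link("c2", "P1", 0.95), link("c2", "P2", 0.95)]
        prof = build_target_profile(herb, links, self.DEGS)
        assert prof.targeted_degs == frozenset({"P1", "P2"})
        assert (prof.n_up, prof.n_down) == (1, 1)

    def test_up_down_split_sums(self):
        herb = HerbRecord("h1", "A", "a", 1, frozenset({"c1"}))
        links = [link("c1", p, 0.95) for p in ("P1", "P2", "P3")]
        prof = build_target_profile(herb, links, self.DEGS)
        assert prof.n_up + prof.n_down == prof.n_targets == 3

    def test_planted_flagship_profile(self, bundle, pipeline_result):
        """The planted top herb reaches exactly 83 DEG targets (37 up, 46 down)."""
        flagship = bundle.manifest["flagship_herb"]
        prof = pipeline_result.profiles[flagship]
        assert prof.n_targets == 83
        assert (prof.n_up, prof.n_down) == (37, 46)


class TestGroupSummaries:
    def test_mean_of_two_herbs(self):
        herbs = [
            HerbRecord("h1", "A", "a", 2, frozenset({"c1"})),
            HerbRecord("h2", "B", "b", 2, frozenset({"c2"})),
        ]
        degs = [GeneRecord(f"P{i}", "up") for i in range(30)]
        links = [link("c1", f"P{i}", 0.95) for i in range(10)]
        links += [link("c2", f"P{i}", 0.95) for i in range(20)]
        profiles = build_target_profiles(herbs, links, degs)
        (summary,) = group_summaries(profiles, herbs)
        assert summary.mean_targets == pytest.approx(15.0)
        assert summary.proportion == pytest.approx(1.0)

    def test_proportions_sum_to_one(self, bundle, pipeline_result):
        summaries = pipeline_result.summaries
        assert sum(s.proportion for s in summaries) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.n_herbs for s in summaries) == len(pipeline_result.retained_herbs)

    def test_means_match_independent_accumulation(self, pipeline_result):
        by_cat = {}
        cat_of = {h.herb_id: h.category for h in pipeline_result.retained_herbs}
        for hid, prof in pipeline_result.profiles.items():
            by_cat.setdefault(cat_of[hid], []).append(prof.n_targets)
        for summary in pipeline_result.summaries:
            vals = by_cat[summary.category]
            assert summary.mean_targets == pytest.approx(sum(vals) / len(vals))

    @pytest.mark.parametrize("value,expected", [(12.25, 12.3), (12.24, 12.2), (14.85, 14.9)])
    def test_reported_mean_rounds_half_up(self, value, expected):
        assert round_half_up(value, 1) == expected


def test_rank_herbs_ties_break_by_latin_name():
    herbs = [
        HerbRecord("h1", "Zebra", "z", 1, frozenset({"c1"})),
        HerbRecord("h2", "Alpha", "a", 1, frozenset({"c1"})),
    ]
    degs = [GeneRecord("P1", "up")]
    links = [link("c1", "P1", 0.95)]
    profiles = build_target_profiles(herbs, links, degs)
    ranked = rank_herbs(profiles, herbs)
    assert [p.herb_id for p in ranked] == ["h2", "h1"]
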