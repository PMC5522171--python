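"""SL filtering and coverage against brute-force witness-search oracles."""

import random
from itertools import combinations

import pytest

from herbnet.sl import (
    build_herb_reports,
    build_ingredient_target_map,
    drug_target_overlap,
    enumerate_herb_pairs,
    filter_sl_pairs,
    herb_pair_sl,
    herb_sl_coverage,
    select_hub_cms,
    side_effect_count,
)
from herbnet.types import (
    ChemicalProteinLink,
    HerbnetError,
    HerbRecord,
    SLPairRecord,
)


def herb(hid, ingredients, category=8):
    return HerbRecord(hid, hid, "", category, frozenset(ingredients))


def random_instance(seed, n_herbs=20, n_pairs=50, n_compounds=30, n_genes=25):
    rng = random.Random(seed)
    genes = [f"G{i}" for i in range(n_genes)]
    compounds = [f"c{i}" for i in range(n_compounds)]
    links = {
        c: frozenset(rng.sample(genes, rng.randrange(0, 4))) for c in compounds
    }
    herbs = [
        herb(f"h{i:02d}", rng.sample(compounds, rng.randrange(1, 6)), rng.randrange(1, 9))
        for i in range(n_herbs)
    ]
    pairs = []
    seen = set()
    while len(pairs) < n_pairs:
        a, b = rng.sample(genes, 2)
        key = tuple(sorted((a, b)))
        if key in seen:
            continue
        seen.add(key)
        pairs.append(
            SLPairRecord(a, b, round(rng.random(), 3),
                         frozenset({rng.choice(["AML", "BRCA", "LUAD"])}))
        )
    return herbs, links, pairs


def brute_single_coverage(h, links, pairs):
    """Oracle: triple loop over (pair, ingredient_i, ingredient_j)."""
    covered = set()
    for pair in pairs:
        for i in h.ingredients:
            for j in h.ingredients:
                if pair.gene_a in links.get(i, ()) and pair.gene_b in links.get(j, ()):
                    covered.add(pair.key)
    return covered


def brute_cross_coverage(a, b, links, pairs):
    covered = set()
    for pair in pairs:
        for i in a.ingredients:
            for j in b.ingredients:
                if pair.gene_a in links.get(i, ()) and pair.gene_b in links.get(j, ()):
                    covered.add(pair.key)
                if pair.gene_a in links.get(j, ()) and pair.gene_b in links.get(i, ()):
                    covered.add(pair.key)
    return covered


class TestFilterSLPairs:
    def test_strict_cutoff_on_fixture(self, t2):
        disease, all_pairs = filter_sl_pairs(t2.sl_pairs, min_conf=0.7, disease="AML")
        assert {(p.key, p.confidence) for p in disease} == {
            (("BRCA1", "TP53"), 0.82046875),
            (("CHEK1", "TP53"), 0.85),
        }
        assert len(all_pairs) == len(t2.sl_pairs)

    def test_min_conf_one_empty(self, t2):
        disease, _ = filter_sl_pairs(t2.sl_pairs, min_conf=1.0)
        assert disease == []

    def test_unknown_disease_warns_and_returns_empty(self, t2, caplog):
        with caplog.at_level("WARNING"):
            disease, _ = filter_sl_pairs(t2.sl_pairs, disease="NOSUCH")
        assert disease == []
        assert any("NOSUCH" in r.message for r in caplog.records)

    def test_matches_linear_scan(self):
        _, _, pairs = random_instance(2)
        disease, _ = filter_sl_pairs(pairs, min_conf=0.5, disease="AML")
        expected = [p for p in pairs if "AML" in p.diseases and p.confidence > 0.5]
        assert disease == expected


class TestSingleHerbCoverage:
    def test_one_ingredient_hitting_both_genes(self):
        h = herb("h1", {"atp"})
        links = {"atp": frozenset({"BRCA1", "TP53"})}
        pair = SLPairRecord("BRCA1", "TP53", 0.82)
        (rec,) = herb_sl_coverage(h, links, [pair])
        assert rec.ingredient_1 == rec.ingredient_2 == "atp"
        assert {rec.target_1, rec.target_2} == {"BRCA1", "TP53"}

    def test_one_sided_targeting_is_not_coverage(self):
        h = herb("h1", {"c1"})
        links = {"c1": frozenset({"BRCA1"})}
        assert herb_sl_coverage(h, links, [SLPairRecord("BRCA1", "TP53", 0.8)]) == []

    def test_canonical_witness_is_lexicographic_minimum(self):
        h = herb("h1", {"zz", "aa", "mm"})
        links = {
            "zz": frozenset({"GA", "GB"}),
            "aa": frozenset({"GB"}),
            "mm": frozenset({"GA"}),
        }
        (rec,) = herb_sl_coverage(h, links, [SLPairRecord("GA", "GB", 0.9)])
        assert (rec.ingredient_1, rec.ingredient_2) == ("mm", "aa")

    def test_all_witnesses_mode_superset(self):
        h = herb("h1", {"x", "y"})
        links = {"x": frozenset({"GA", "GB"}), "y": frozenset({"GB"})}
        pair = SLPairRecord("GA", "GB", 0.9)
        assert len(herb_sl_coverage(h, links, [pair], all_witnesses=True)) == 2
        assert len(herb_sl_coverage(h, links, [pair])) == 1

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_witness_search(self, seed):
        herbs, links, pairs = random_instance(seed)
        for h in herbs:
            got = {r.pair.key for r in herb_sl_coverage(h, links, pairs)}
            assert got == brute_single_coverage(h, links, pairs)


class TestHerbPairCoverage:
    def test_identical_herbs_rejected(self):
        h = herb("h1", {"c"})
        with pytest.raises(HerbnetError):
            herb_pair_sl(h, h, {}, [])

    def test_symmetry(self):
        herbs, links, pairs = random_instance(5, n_herbs=8)
        disease, all_pairs = filter_sl_pairs(pairs, min_conf=0.3)
        a, b = herbs[0], herbs[1]
        r1 = herb_pair_sl(a, b, links, disease, all_pairs=all_pairs)
        r2 = herb_pair_sl(b, a, links, disease, all_pairs=all_pairs)
        assert r1 == r2

    def test_both_herbs_on_same_gene_is_not_cross_coverage(self):
        a, b = herb("a", {"c1"}), herb("b", {"c2"})
        links = {"c1": frozenset({"GA"}), "c2": frozenset({"GA"})}
        rep = herb_pair_sl(a, b, links, [SLPairRecord("GA", "GB", 0.9)])
        assert rep.covered_aml_pairs == ()

    def test_cross_orientation_either_way(self):
        a, b = herb("a", {"c1"}), herb("b", {"c2"})
        links = {"c1": frozenset({"GB"}), "c2": frozenset({"GA"})}
        rep = herb_pair_sl(a, b, links, [SLPairRecord("GA", "GB", 0.9)])
        assert len(rep.covered_aml_pairs) == 1

    def test_without_cross_requirement_single_member_coverage_kept(self):
        herbs, links, pairs = random_instance(8, n_herbs=10)
        disease, _ = filter_sl_pairs(pairs, min_conf=0.2)
        for a, b in combinations(herbs[:6], 2):
            single = {r.pair.key for r in herb_sl_coverage(a, links, disease)}
            pooled = herb_pair_sl(a, b, links, disease, require_cross=False)
            assert single <= {r.pair.key for r in pooled.covered_aml_pairs}

    @pytest.mark.parametrize("seed", [3, 4])
    def test_matches_brute_force_pair_enumeration(self, seed):
        herbs, links, pairs = random_instance(seed, n_herbs=12)
        disease, _ = filter_sl_pairs(pairs, min_conf=0.3)
        for a, b in combinations(herbs, 2):
            rep = herb_pair_sl(a, b, links, disease)
            got = {r.pair.key for r in rep.covered_aml_pairs}
            assert got == brute_cross_coverage(a, b, links, disease)

    def test_safety_ratio_bounds_and_decrease(self):
        a, b = herb("a", {"c1"}), herb("b", {"c2"})
        links = {"c1": frozenset({"GA", "GC"}), "c2": frozenset({"GB", "GD"})}
        disease = [SLPairRecord("GA", "GB", 0.9, frozenset({"AML"}))]
        clean = herb_pair_sl(a, b, links, disease, all_pairs=disease)
        assert clean.safety_ratio == pytest.approx(1.0)
        with_off = herb_pair_sl(
            a, b, links, disease, all_pairs=disease + [SLPairRecord("GC", "GD", 0.4)]
        )
        assert 0.0 <= with_off.safety_ratio < clean.safety_ratio


class TestSideEffects:
    def test_only_disease_pairs_counts_zero(self):
        h = herb("h1", {"atp"})
        links = {"atp": frozenset({"GA", "GB"})}
        disease = [SLPairRecord("GA", "GB", 0.9, frozenset({"AML"}))]
        assert side_effect_count(h, links, disease, disease) == 0

    def test_planted_three_aml_and_sixty_five_other(self):
        """A herb wired to 3 disease pairs and 65 off-target pairs counts 65."""
        off_genes = [f"O{i}" for i in range(12)]
        links = {"mix": frozenset({"GA", "GB", "GC"} | set(off_genes))}
        h = herb("h1", {"mix"})
        disease = [
            SLPairRecord(a, b, 0.8, frozenset({"AML"}))
            for a, b in [("GA", "GB"), ("GA", "GC"), ("GB", "GC")]
        ]
        others = [
            SLPairRecord(a, b, 0.5, frozenset({"BRCA"}))
            for a, b in list(combinations(off_genes, 2))[:65]
        ]
        assert side_effect_count(h, links, disease + others, disease) == 65

    @pytest.mark.parametrize("seed", [6, 7])
    def test_equals_set_difference_oracle(self, seed):
        herbs, links, pairs = random_instance(seed)
        disease, all_pairs = filter_sl_pairs(pairs, min_conf=0.7)
        for h in herbs[:10]:
            covered = brute_single_coverage(h, links, all_pairs)
            expected = len(covered - {p.key for p in disease})
            assert side_effect_count(h, links, all_pairs, disease) == expected


class TestHubCMSelection:
    def test_fixture_exclusion_leaves_four(self, t2):
        disease, all_pairs = filter_sl_pairs(t2.sl_pairs)
        exclusions = [("Panax ginseng", "ambiguous role in AML")]
        reports = build_herb_reports(
            list(t2.herbs), t2.links, disease, list(all_pairs), manual_exclusions=exclusions
        )
        hub_cms = select_hub_cms(reports, exclusions)
        assert hub_cms == frozenset(
            {
                "Camellia sinensis",
                "Cornu Cervi Pantotrichum",
                "Folium camelliae sinensis",
                "Ilex cornuta",
            }
        )

    def test_no_candidates_gives_empty(self):
        assert select_hub_cms([]) == frozenset()

    def test_exclusion_of_non_candidate_warns(self, caplog):
        with caplog.at_level("WARNING"):
            result = select_hub_cms([], [("ghost", "whatever")])
        assert result == frozenset()
        assert any("ghost" in r.message for r in caplog.records)

    def test_planted_covering_herbs_recovered(self, bundle, pipeline_result):
        assert sorted(pipeline_result.hub_cms) == bundle.manifest["covering_herbs"]


class TestPairEnumeration:
    def test_restriction_to_hub_cms(self):
        herbs, links, pairs = random_instance(10, n_herbs=10)
        disease, _ = filter_sl_pairs(pairs, min_conf=0.2)
        unrestricted = enumerate_herb_pairs(herbs, links, disease)
        hub = {herbs[0].herb_id}
        restricted = enumerate_herb_pairs(herbs, links, disease, hub_cms=hub)
        assert all(hub & {r.herb_1, r.herb_2} for r in restricted)
        assert {(r.herb_1, r.herb_2) for r in restricted} <= {
            (r.herb_1, r.herb_2) for r in unrestricted
        }

    def test_planted_pairs_recovered_exactly(self, bundle, pipeline_result):
        got = sorted((r.herb_1, r.herb_2) for r in pipeline_result.herb_pairs)
        expected = sorted(tuple(p) for p in bundle.manifest["expected_herb_pairs"])
        assert got == expected


class TestDrugOverlap:
    def test_fixture_prkcd_overlap(self, t2):
        from herbnet.mapping import build_target_profiles

        profiles = build_target_profiles(
            list(t2.herbs), list(t2.links), list(t2.deg_records)
        )
        overlap = drug_target_overlap(
            profiles["Cornu Cervi Pantotrichum"], t2.drug_targets
        )
        assert overlap == [("Ingenol Mebutate", frozenset({"PRKCD"}))]

    def test_disjoint_sets_empty(self, t2):
        from herbnet.mapping import build_target_profiles

        profiles = build_target_profiles(
            list(t2.herbs), list(t2.links), list(t2.deg_records)
        )
        assert drug_target_overlap(profiles["Morus alba"], {"d": frozenset({"ZZZ"})}) == []

    def test_matches_pairwise_intersection(self):
        rng = random.Random(19)
        genes = [f"G{i}" for i in range(30)]

        class Prof:
            targeted_degs = frozenset(rng.sample(genes, 10))

        drugs = {f"d{i}": frozenset(rng.sample(genes, 5)) for i in range(8)}
        got = dict(drug_target_overlap(Prof(), drugs))
        for d, targets in drugs.items():
            inter = Prof.targeted_degs & targets
            if inter:
                assert got[d] == inter
            else:
                assert d not in got
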