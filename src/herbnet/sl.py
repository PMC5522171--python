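"""Synthetic-lethality coverage of herbs and herb pairs.

A herb *covers* an SL gene pair when some ingredient targets one gene of
the pair and some ingredient (possibly the same compound) targets the
other. A herb *pair* covers an SL pair, under the default cross
requirement, when the two genes are reached through ingredients of
different member herbs (either orientation) — the combination, not either
member alone, is what induces the joint perturbation.

Disease-related pairs are filtered at strict confidence > 0.7 (the SL
database scale); off-target ("other SL") coverage is counted with no
confidence floor by default, as potential side-effect burden.

Ingredient→target links reuse the high-confidence (>= 0.9), hub-restricted
chemical link set from the mapping stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import (
    Dict,
    FrozenSet,
    Iterable,
    List,
    Mapping,
    Optional,
    Sequence,
    Set,
    Tuple,
    Union,
)

import pandas as pd

from .types import (
    ChemicalProteinLink,
    HerbnetError,
    HerbRecord,
    SLCoverageRecord,
    SLPairRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HerbSLReport",
    "HerbPairReport",
    "build_ingredient_target_map",
    "filter_sl_pairs",
    "herb_sl_coverage",
    "herb_pair_sl",
    "side_effect_count",
    "build_herb_reports",
    "select_hub_cms",
    "enumerate_herb_pairs",
    "drug_target_overlap",
    "group_pair_matrix",
    "coverage_to_dataframe",
]

DEFAULT_SL_CONFIDENCE = 0.7

LinkMap = Mapping[str, FrozenSet[str]]


def build_ingredient_target_map(
    links: Union[Iterable[ChemicalProteinLink], LinkMap]
) -> Dict[str, FrozenSet[str]]:
    """Collapse links to {compound_id: targeted protein set}."""
    if isinstance(links, Mapping):
        return {c: frozenset(t) for c, t in links.items()}
    out: Dict[str, Set[str]] = {}
    for link in links:
        out.setdefault(link.compound_id, set()).add(link.protein)
    return {c: frozenset(t) for c, t in out.items()}


def filter_sl_pairs(
    sl_db: Sequence[SLPairRecord],
    min_conf: float = DEFAULT_SL_CONFIDENCE,
    disease: str = "AML",
) -> Tuple[List[SLPairRecord], List[SLPairRecord]]:
    """Split the SL database into disease-tagged high-confidence pairs and
    the untouched full list (kept for side-effect accounting).

    The disease filter is strict (confidence > ``min_conf``).
    """
    if not (0.0 <= min_conf <= 1.0):
        raise HerbnetError(f"min_conf must be in [0, 1], got {min_conf}")
    all_pairs = list(sl_db)
    if not any(disease in p.diseases for p in all_pairs):
        logger.warning("disease tag %r not present in the SL database", disease)
    disease_pairs = [
        p for p in all_pairs if disease in p.diseases and p.confidence > min_conf
    ]
    return disease_pairs, all_pairs


def _witnesses_single(
    ingredients: FrozenSet[str], links: LinkMap, pair: SLPairRecord
) -> List[Tuple[str, str]]:
    side_a = sorted(i for i in ingredients if pair.gene_a in links.get(i, frozenset()))
    side_b = sorted(i for i in ingredients if pair.gene_b in links.get(i, frozenset()))
    return [(ia, ib) for ia in side_a for ib in side_b]


def herb_sl_coverage(
    herb: HerbRecord,
    links: Union[Iterable[ChemicalProteinLink], LinkMap],
    pairs: Sequence[SLPairRecord],
    all_witnesses: bool = False,
) -> List[SLCoverageRecord]:
    """SL pairs covered by one herb, with witness ingredients.

    By default one record per covered pair carrying the canonical witness:
    the lexicographically smallest (ingredient_1, ingredient_2) with
    targets aligned to the pair's canonical gene order. ``all_witnesses``
    returns every witness combination instead.
    """
    link_map = build_ingredient_target_map(links)
    records: List[SLCoverageRecord] = []
    for pair in pairs:
        wits = _witnesses_single(herb.ingredients, link_map, pair)
        if not wits:
            continue
        chosen = wits if all_witnesses else [min(wits)]
        for ia, ib in chosen:
            records.append(
                SLCoverageRecord(
                    herb_1=herb.herb_id,
                    ingredient_1=ia,
                    target_1=pair.gene_a,
                    ingredient_2=ib,
                    target_2=pair.gene_b,
                    pair=pair,
                )
            )
    return records


@dataclass(frozen=True)
class HerbSLReport:
    """Per-herb SL account: disease pairs covered, off-target burden, and
    hub-CM status after any manual exclusion."""

    herb_id: str
    aml_pairs_covered: Tuple[SLCoverageRecord, ...]
    other_pairs_count: int
    is_hub_cm: bool
    manual_exclusion_reason: Optional[str] = None


@dataclass(frozen=True)
class HerbPairReport:
    """Per-herb-pair SL account (herb_1 < herb_2 by id)."""

    herb_1: str
    herb_2: str
    covered_aml_pairs: Tuple[SLCoverageRecord, ...]
    other_pairs_count: int
    categories: Tuple[int, int]

    @property
    def safety_ratio(self) -> float:
        """Disease-related fraction of all covered SL pairs (0 when none)."""
        denom = len(self.covered_aml_pairs) + self.other_pairs_count
        return len(self.covered_aml_pairs) / denom if denom else 0.0


def _covered_pair_keys(
    ingredients: FrozenSet[str], links: LinkMap, pairs: Sequence[SLPairRecord]
) -> Set[Tuple[str, str]]:
    covered = set()
    for pair in pairs:
        has_a = any(pair.gene_a in links.get(i, frozenset()) for i in ingredients)
        has_b = any(pair.gene_b in links.get(i, frozenset()) for i in ingredients)
        if has_a and has_b:
            covered.add(pair.key)
    return covered


def _cross_witnesses(
    ing_a: FrozenSet[str],
    ing_b: FrozenSet[str],
    links: LinkMap,
    pair: SLPairRecord,
) -> List[Tuple[str, str]]:
    """Witnesses (i1 -> gene_a, i2 -> gene_b) using one ingredient from each
    herb, in either orientation."""
    a_side_1 = [i for i in ing_a if pair.gene_a in links.get(i, frozenset())]
    b_side_2 = [i for i in ing_b if pair.gene_b in links.get(i, frozenset())]
    b_side_1 = [i for i in ing_b if pair.gene_a in links.get(i, frozenset())]
    a_side_2 = [i for i in ing_a if pair.gene_b in links.get(i, frozenset())]
    wits = [(i1, i2) for i1 in a_side_1 for i2 in b_side_2]
    wits += [(i1, i2) for i1 in b_side_1 for i2 in a_side_2]
    return sorted(set(wits))


def herb_pair_sl(
    herb_a: HerbRecord,
    herb_b: HerbRecord,
    links: Union[Iterable[ChemicalProteinLink], LinkMap],
    disease_pairs: Sequence[SLPairRecord],
    all_pairs: Optional[Sequence[SLPairRecord]] = None,
    require_cross: bool = True,
    offtarget_min_conf: Optional[float] = None,
) -> HerbPairReport:
    """SL coverage of an unordered herb pair.

    With ``require_cross`` (default) a pair counts only when the two genes
    are reached via ingredients of different members; with it lifted the
    combined ingredient pool is scored, which subsumes single-member
    coverage. Symmetric in its two herbs.
    """
    if herb_a.herb_id == herb_b.herb_id:
        raise HerbnetError(f"herb pair needs two distinct herbs, got {herb_a.herb_id} twice")
    if herb_a.herb_id > herb_b.herb_id:
        herb_a, herb_b = herb_b, herb_a
    link_map = build_ingredient_target_map(links)
    covered: List[SLCoverageRecord] = []
    for pair in disease_pairs:
        if require_cross:
            wits = _cross_witnesses(herb_a.ingredients, herb_b.ingredients, link_map, pair)
        else:
            wits = _witnesses_single(herb_a.ingredients | herb_b.ingredients, link_map, pair)
        if not wits:
            continue
        ia, ib = min(wits)
        covered.append(
            SLCoverageRecord(
                herb_1=herb_a.herb_id,
                herb_2=herb_b.herb_id,
                ingredient_1=ia,
                target_1=pair.gene_a,
                ingredient_2=ib,
                target_2=pair.gene_b,
                pair=pair,
            )
        )
    other = 0
    if all_pairs is not None:
        disease_keys = {p.key for p in disease_pairs}
        pool = [
            p
            for p in all_pairs
            if offtarget_min_conf is None or p.confidence > offtarget_min_conf
        ]
        if require_cross:
            other_keys = {
                p.key
                for p in pool
                if _cross_witnesses(herb_a.ingredients, herb_b.ingredients, link_map, p)
            }
        else:
            other_keys = _covered_pair_keys(
                herb_a.ingredients | herb_b.ingredients, link_map, pool
            )
        other = len(other_keys - disease_keys)
    return HerbPairReport(
        herb_1=herb_a.herb_id,
        herb_2=herb_b.herb_id,
        covered_aml_pairs=tuple(covered),
        other_pairs_count=other,
        categories=(herb_a.category, herb_b.category),
    )


def side_effect_count(
    entity: Union[HerbRecord, Tuple[HerbRecord, HerbRecord]],
    links: Union[Iterable[ChemicalProteinLink], LinkMap],
    all_pairs: Sequence[SLPairRecord],
    disease_pairs: Sequence[SLPairRecord],
    min_conf: Optional[float] = None,
    require_cross: bool = True,
) -> int:
    """Covered SL pairs that are not disease-related.

    No confidence floor is applied to the off-target side unless
    ``min_conf`` is given (strict >). ``entity`` is a herb or a 2-tuple of
    herbs (scored with the cross requirement by default).
    """
    link_map = build_ingredient_target_map(links)
    pool = [p for p in all_pairs if min_conf is None or p.confidence > min_conf]
    if isinstance(entity, HerbRecord):
        covered = _covered_pair_keys(entity.ingredients, link_map, pool)
    else:
        a, b = entity
        if require_cross:
            covered = {
                p.key for p in pool if _cross_witnesses(a.ingredients, b.ingredients, link_map, p)
            }
        else:
            covered = _covered_pair_keys(a.ingredients | b.ingredients, link_map, pool)
    return len(covered - {p.key for p in disease_pairs})


def build_herb_reports(
    herbs: Sequence[HerbRecord],
    links: Union[Iterable[ChemicalProteinLink], LinkMap],
    disease_pairs: Sequence[SLPairRecord],
    all_pairs: Sequence[SLPairRecord],
    manual_exclusions: Sequence[Tuple[str, str]] = (),
    offtarget_min_conf: Optional[float] = None,
) -> List[HerbSLReport]:
    """Per-herb SL reports over the whole cohort."""
    link_map = build_ingredient_target_map(links)
    exclusions = dict(manual_exclusions)
    reports = []
    for herb in herbs:
        covered = herb_sl_coverage(herb, link_map, disease_pairs)
        other = side_effect_count(
            herb, link_map, all_pairs, disease_pairs, min_conf=offtarget_min_conf
        )
        reason = exclusions.get(herb.herb_id)
        reports.append(
            HerbSLReport(
                herb_id=herb.herb_id,
                aml_pairs_covered=tuple(covered),
                other_pairs_count=other,
                is_hub_cm=bool(covered) and reason is None,
                manual_exclusion_reason=reason,
            )
        )
    return reports


def select_hub_cms(
    reports: Sequence[HerbSLReport],
    manual_exclusions: Sequence[Tuple[str, str]] = (),
) -> FrozenSet[str]:
    """Hub CMs: herbs covering >= 1 high-confidence disease SL pair, minus
    manual exclusions (each logged with its reason)."""
    candidates = {r.herb_id for r in reports if r.aml_pairs_covered}
    excluded = set()
    for herb_id, reason in manual_exclusions:
        if herb_id not in candidates:
            logger.warning(
                "manual exclusion of %s (%s): herb is not a hub-CM candidate", herb_id, reason
            )
            continue
        logger.info("manually excluding hub-CM candidate %s: %s", herb_id, reason)
        excluded.add(herb_id)
    return frozenset(candidates - excluded)


def enumerate_herb_pairs(
    herbs: Sequence[HerbRecord],
    links: Union[Iterable[ChemicalProteinLink], LinkMap],
    disease_pairs: Sequence[SLPairRecord],
    all_pairs: Optional[Sequence[SLPairRecord]] = None,
    hub_cms: Optional[Set[str]] = None,
    require_cross: bool = True,
) -> List[HerbPairReport]:
    """All herb pairs that cover >= 1 disease SL pair.

    When ``hub_cms`` is given, enumeration is restricted to pairs
    containing at least one hub CM (every effective pair is anchored by a
    hub CM); pass ``None`` to lift the restriction.
    """
    link_map = build_ingredient_target_map(links)
    out = []
    for a, b in combinations(sorted(herbs, key=lambda h: h.herb_id), 2):
        if hub_cms is not None and a.herb_id not in hub_cms and b.herb_id not in hub_cms:
            continue
        report = herb_pair_sl(
            a, b, link_map, disease_pairs, all_pairs=all_pairs, require_cross=require_cross
        )
        if report.covered_aml_pairs:
            out.append(report)
    return out


def drug_target_overlap(
    herb_profile, drug_targets: Mapping[str, FrozenSet[str]]
) -> List[Tuple[str, FrozenSet[str]]]:
    """Approved drugs sharing >= 1 target gene with a herb's DEG-target
    profile; empty intersections omitted."""
    targets = frozenset(herb_profile.targeted_degs)
    out = []
    for drug in sorted(drug_targets):
        shared = targets & frozenset(drug_targets[drug])
        if shared:
            out.append((drug, shared))
    return out


def group_pair_matrix(
    pair_reports: Sequence[HerbPairReport],
) -> pd.DataFrame:
    """Category × category counts of effective herb pairs (upper triangle
    including the diagonal; unordered category pairs)."""
    mat = pd.DataFrame(0, index=range(1, 9), columns=range(1, 9))
    for rep in pair_reports:
        c1, c2 = sorted(rep.categories)
        mat.loc[c1, c2] += 1
    return mat


def coverage_to_dataframe(
    records: Sequence[SLCoverageRecord],
    herb_table: Sequence[HerbRecord],
) -> pd.DataFrame:
    """Coverage evidence in the five-column report dialect
    (CM name, Ingredient 1, Target 1, Ingredient 2, Target 2, confidence)."""
    latin = {h.herb_id: h.latin_name for h in herb_table}

    def cm_name(rec: SLCoverageRecord) -> str:
        name = latin.get(rec.herb_1, rec.herb_1)
        if rec.herb_2 is not None:
            name += " + " + latin.get(rec.herb_2, rec.herb_2)
        return name

    rows = sorted(
        records,
        key=lambda r: (cm_name(r), r.pair.key, r.ingredient_1, r.ingredient_2),
    )
    return pd.DataFrame(
        {
            "CM name": [cm_name(r) for r in rows],
            "Ingredient 1": [r.ingredient_1 for r in rows],
            "Target 1": [r.target_1 for r in rows],
            "Ingredient 2": [r.ingredient_2 for r in rows],
            "Target 2": [r.target_2 for r in rows],
            "confidence scores": [r.pair.confidence for r in rows],
        }
    )
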