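"""Compound filtering, herb mapping and DEG-target coverage scoring.

Stage logic: keep chemical–protein links at high confidence (>= 0.9 by
default) whose protein is a hub target; map surviving compounds into herb
ingredient sets; drop herbs flagged as unconventional, toxic or
incompletely annotated; then score each retained herb by the number of
distinct DEG-encoded proteins its ingredients reach through surviving
links, and summarize the eight traditional-pharmacology categories.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set, Tuple

import pandas as pd

from .types import (
    ChemicalProteinLink,
    GeneRecord,
    HerbRecord,
    MalformedRecordError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "HerbTargetProfile",
    "GroupSummary",
    "filter_links",
    "map_compounds_to_herbs",
    "apply_exclusions",
    "build_target_profile",
    "build_target_profiles",
    "group_summaries",
    "rank_herbs",
    "round_half_up",
]

DEFAULT_LINK_CONFIDENCE = 0.9


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Half-up decimal rounding used for reported means (12.25 -> 12.3)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def filter_links(
    links: Iterable[ChemicalProteinLink],
    hubs: Set[str],
    min_conf: float = DEFAULT_LINK_CONFIDENCE,
) -> List[ChemicalProteinLink]:
    """Keep links with confidence >= ``min_conf`` (inclusive) and protein in
    the hub set. Idempotent."""
    if not (0.0 <= min_conf <= 1.0):
        raise MalformedRecordError(f"min_conf must be in [0, 1], got {min_conf}")
    hubs = set(hubs)
    kept = [l for l in links if l.confidence >= min_conf and l.protein in hubs]
    logger.info(
        "filter_links: kept %d links (%d compounds, %d proteins)",
        len(kept), len({l.compound_id for l in kept}), len({l.protein for l in kept}),
    )
    return kept


def map_compounds_to_herbs(
    filtered_links: Iterable[ChemicalProteinLink],
    herb_table: Sequence[HerbRecord],
) -> Tuple[FrozenSet[str], FrozenSet[str]]:
    """Compounds present in >=1 herb's ingredient set, and the herbs holding
    >=1 such compound. Many-to-many: a shared compound makes every holder a
    candidate."""
    compounds = {l.compound_id for l in filtered_links}
    matched: Set[str] = set()
    candidates: Set[str] = set()
    for herb in herb_table:
        hit = compounds & herb.ingredients
        if hit:
            matched |= hit
            candidates.add(herb.herb_id)
    return frozenset(matched), frozenset(candidates)


def apply_exclusions(
    candidate_herbs: Iterable[str], herb_table: Sequence[HerbRecord]
) -> List[HerbRecord]:
    """Drop herbs flagged ``excluded``; log each removal with its reason."""
    candidates = set(candidate_herbs)
    by_id = {h.herb_id: h for h in herb_table}
    retained: List[HerbRecord] = []
    for hid in sorted(candidates):
        herb = by_id.get(hid)
        if herb is None:
            logger.warning("apply_exclusions: unknown herb_id %s dropped", hid)
            continue
        if herb.excluded:
            logger.info(
                "excluding %s (%s): %s", herb.herb_id, herb.latin_name, herb.exclusion_reason
            )
            continue
        retained.append(herb)
    return retained


@dataclass(frozen=True)
class HerbTargetProfile:
    """DEG-target coverage of one herb through high-confidence links."""

    herb_id: str
    matched_ingredients: FrozenSet[str]
    targeted_degs: FrozenSet[str]
    n_up: int
    n_down: int

    @property
    def n_targets(self) -> int:
        return len(self.targeted_degs)


def build_target_profile(
    herb: HerbRecord,
    filtered_links: Iterable[ChemicalProteinLink],
    deg_records: Sequence[GeneRecord],
) -> HerbTargetProfile:
    """Distinct DEG-encoded proteins reachable through any herb ingredient.

    Set semantics: two ingredients hitting the same protein count it once;
    no weighting by confidence or ingredient multiplicity.
    """
    regulation = {r.symbol: r.regulation for r in deg_records}
    matched: Set[str] = set()
    targets: Set[str] = set()
    for link in filtered_links:
        if link.compound_id in herb.ingredients and link.protein in regulation:
            matched.add(link.compound_id)
            targets.add(link.protein)
    n_up = sum(1 for g in targets if regulation[g] == "up")
    return HerbTargetProfile(
        herb_id=herb.herb_id,
        matched_ingredients=frozenset(matched),
        targeted_degs=frozenset(targets),
        n_up=n_up,
        n_down=len(targets) - n_up,
    )


def build_target_profiles(
    herbs: Sequence[HerbRecord],
    filtered_links: Iterable[ChemicalProteinLink],
    deg_records: Sequence[GeneRecord],
) -> Dict[str, HerbTargetProfile]:
    links = list(filtered_links)
    return {h.herb_id: build_target_profile(h, links, deg_records) for h in herbs}


@dataclass(frozen=True)
class GroupSummary:
    """Per-category herb count, cohort proportion and mean DEG-target count.

    ``mean_targets`` keeps full precision; ``mean_targets_reported`` is the
    half-up 1-decimal value used in tabular reports.
    """

    category: int
    n_herbs: int
    proportion: float
    mean_targets: float

    @property
    def mean_targets_reported(self) -> float:
        return round_half_up(self.mean_targets, 1)


def group_summaries(
    profiles: Dict[str, HerbTargetProfile],
    herb_table: Sequence[HerbRecord],
) -> List[GroupSummary]:
    """Summaries for the categories present among the profiled herbs."""
    by_id = {h.herb_id: h for h in herb_table}
    counts: Dict[int, int] = {}
    totals: Dict[int, int] = {}
    for hid, prof in profiles.items():
        herb = by_id.get(hid)
        if herb is None:
            raise MalformedRecordError(f"profile for unknown herb_id {hid}")
        counts[herb.category] = counts.get(herb.category, 0) + 1
        totals[herb.category] = totals.get(herb.category, 0) + prof.n_targets
    n_total = sum(counts.values())
    return [
        GroupSummary(
            category=c,
            n_herbs=counts[c],
            proportion=counts[c] / n_total,
            mean_targets=totals[c] / counts[c],
        )
        for c in sorted(counts)
    ]


def rank_herbs(
    profiles: Dict[str, HerbTargetProfile], herb_table: Sequence[HerbRecord]
) -> List[HerbTargetProfile]:
    """Profiles sorted by target count descending, ties by Latin name."""
    latin = {h.herb_id: h.latin_name for h in herb_table}
    return sorted(
        profiles.values(), key=lambda p: (-p.n_targets, latin.get(p.herb_id, ""), p.herb_id)
    )


def profiles_to_dataframe(
    profiles: Dict[str, HerbTargetProfile], herb_table: Sequence[HerbRecord]
) -> pd.DataFrame:
    ranked = rank_herbs(profiles, herb_table)
    return pd.DataFrame(
        {
            "herb_id": [p.herb_id for p in ranked],
            "n_targets": [p.n_targets for p in ranked],
            "n_up": [p.n_up for p in ranked],
            "n_down": [p.n_down for p in ranked],
            "targets": [";".join(sorted(p.targeted_degs)) for p in ranked],
        }
    )


def group_summary_to_dataframe(summaries: Sequence[GroupSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "category": [s.category for s in summaries],
            "n_herbs": [s.n_herbs for s in summaries],
            "proportion": [round(s.proportion, 4) for s in summaries],
            "mean_targets": [s.mean_targets_reported for s in summaries],
        }
    )
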