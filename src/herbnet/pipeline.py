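"""End-to-end orchestration of the screening pipeline.

Stage order: hub selection on the PPI network → high-confidence link
filtering → compound→herb mapping and exclusions → per-herb DEG-target
profiles and category summaries → per-category pathway enrichment with
overlap/shared/unique analysis → SL coverage (herbs, then herb pairs
anchored on hub CMs) → optional prescription assembly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

from .enrichment import (
    EnrichmentRow,
    OverlapReport,
    SharedUniqueReport,
    enrich,
    overlap_with_degs,
    shared_and_unique,
)
from .hubs import DEFAULT_HUB_THRESHOLD, HubSelectionResult, compute_degrees, select_hubs
from .mapping import (
    DEFAULT_LINK_CONFIDENCE,
    GroupSummary,
    HerbTargetProfile,
    apply_exclusions,
    build_target_profiles,
    filter_links,
    group_summaries,
    map_compounds_to_herbs,
)
from .sl import (
    DEFAULT_SL_CONFIDENCE,
    HerbPairReport,
    HerbSLReport,
    build_herb_reports,
    enumerate_herb_pairs,
    filter_sl_pairs,
    select_hub_cms,
)
from .types import (
    ChemicalProteinLink,
    GeneRecord,
    HerbRecord,
    InteractionNetwork,
    PathwayAnnotation,
    SLPairRecord,
)

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    hub_result: HubSelectionResult
    filtered_links: List[ChemicalProteinLink]
    retained_herbs: List[HerbRecord]
    profiles: Dict[str, HerbTargetProfile]
    summaries: List[GroupSummary]
    deg_enrichment: Optional[List[EnrichmentRow]]
    group_enrichment: Dict[int, List[EnrichmentRow]]
    overlap: Optional[OverlapReport]
    shared_unique: Optional[SharedUniqueReport]
    herb_reports: List[HerbSLReport]
    hub_cms: FrozenSet[str]
    herb_pairs: List[HerbPairReport]


def run_pipeline(
    deg_records: Sequence[GeneRecord],
    network: InteractionNetwork,
    links: Sequence[ChemicalProteinLink],
    herbs: Sequence[HerbRecord],
    sl_pairs: Sequence[SLPairRecord],
    pathways: Optional[Sequence[PathwayAnnotation]] = None,
    hub_threshold: int = DEFAULT_HUB_THRESHOLD,
    link_min_conf: float = DEFAULT_LINK_CONFIDENCE,
    sl_min_conf: float = DEFAULT_SL_CONFIDENCE,
    disease: str = "AML",
    alpha: float = 0.05,
    manual_exclusions: Sequence[Tuple[str, str]] = (),
) -> PipelineResult:
    degrees = compute_degrees(network, [r.symbol for r in deg_records])
    hub_result = select_hubs(degrees, deg_records, threshold=hub_threshold)

    flinks = filter_links(links, hub_result.hub_set, min_conf=link_min_conf)
    _, candidates = map_compounds_to_herbs(flinks, herbs)
    retained = apply_exclusions(candidates, herbs)
    profiles = build_target_profiles(retained, flinks, deg_records)
    summaries = group_summaries(profiles, retained)

    deg_rows = None
    group_rows: Dict[int, List[EnrichmentRow]] = {}
    overlap = None
    shared = None
    if pathways:
        background = set().union(*(p.members for p in pathways))
        deg_query = {r.symbol for r in deg_records} & background
        if deg_query:
            deg_rows = enrich(deg_query, pathways, background, alpha=alpha)
        by_cat: Dict[int, set] = {}
        for herb in retained:
            by_cat.setdefault(herb.category, set()).update(
                profiles[herb.herb_id].targeted_degs
            )
        for cat, query in sorted(by_cat.items()):
            query &= background
            if query:
                group_rows[cat] = enrich(query, pathways, background, alpha=alpha)
        if deg_rows is not None and group_rows:
            overlap = overlap_with_degs(deg_rows, group_rows)
        if len(group_rows) >= 2:
            shared = shared_and_unique(group_rows)

    disease_pairs, all_pairs = filter_sl_pairs(sl_pairs, min_conf=sl_min_conf, disease=disease)
    herb_reports = build_herb_reports(
        retained, flinks, disease_pairs, all_pairs, manual_exclusions=manual_exclusions
    )
    hub_cms = select_hub_cms(herb_reports, manual_exclusions)
    herb_pairs = enumerate_herb_pairs(
        retained, flinks, disease_pairs, all_pairs=all_pairs, hub_cms=hub_cms
    )
    return PipelineResult(
        hub_result=hub_result,
        filtered_links=flinks,
        retained_herbs=retained,
        profiles=profiles,
        summaries=summaries,
        deg_enrichment=deg_rows,
        group_enrichment=group_rows,
        overlap=overlap,
        shared_unique=shared,
        herb_reports=herb_reports,
        hub_cms=hub_cms,
        herb_pairs=herb_pairs,
    )
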