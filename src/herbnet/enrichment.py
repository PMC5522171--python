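"""Hypergeometric pathway enrichment and cross-group overlap analysis.

For a query gene set of size ``n`` drawn from a background universe of
size ``N``, a pathway with ``K`` members in the background and ``k`` hits
in the query is scored with the one-sided upper-tail hypergeometric
probability

    p = P(X >= k),  X ~ Hypergeometric(N, K, n),

and p-values are corrected across all tested pathways with the
Benjamini–Hochberg step-up procedure. A pathway is *involved in* a query
when q <= alpha (default 0.05).

The background is the set of genes appearing anywhere in the pathway
database — the only self-contained universe. Query genes outside the
background are ignored (silently intersected): herb target sets routinely
contain proteins that no pathway annotates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Sequence, Set, Tuple, Union

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .types import HerbnetError, PathwayAnnotation

__all__ = [
    "EnrichmentRow",
    "GroupPathwayProfile",
    "enrich",
    "significant_ids",
    "OverlapReport",
    "overlap_with_degs",
    "SharedUniqueReport",
    "shared_and_unique",
]

DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class EnrichmentRow:
    pathway_id: str
    name: str
    k: int  # hits in query
    K: int  # pathway size within background
    n: int  # query size within background
    N: int  # background size
    p_value: float
    q_value: float
    significant: bool


@dataclass(frozen=True)
class GroupPathwayProfile:
    """The significant pathway set of one herb category."""

    category: int
    significant_pathways: FrozenSet[str]


def enrich(
    query: Set[str],
    pathways: Sequence[PathwayAnnotation],
    background: Set[str],
    alpha: float = DEFAULT_ALPHA,
) -> List[EnrichmentRow]:
    """One-sided hypergeometric enrichment with BH correction.

    Rows are sorted by p ascending, ties broken by pathway_id. Pathways
    with no member inside the background are skipped. Raises on empty
    query or background.
    """
    background = set(background)
    if not background:
        raise HerbnetError("enrichment background is empty")
    query = set(query) & background
    if not query:
        raise HerbnetError("enrichment query is empty (after background intersection)")
    N = len(background)
    n = len(query)
    tested: List[Tuple[PathwayAnnotation, int, int, float]] = []
    for pw in pathways:
        members = pw.members & background
        K = len(members)
        if K == 0:
            continue
        k = len(query & members)
        # P(X >= k) == sf(k - 1); k = 0 gives the degenerate tail p = 1
        p = float(hypergeom.sf(k - 1, N, K, n))
        tested.append((pw, k, K, min(p, 1.0)))
    if not tested:
        return []
    reject, q_values, _, _ = multipletests(
        [t[3] for t in tested], alpha=alpha, method="fdr_bh"
    )
    rows = [
        EnrichmentRow(
            pathway_id=pw.pathway_id,
            name=pw.name,
            k=k,
            K=K,
            n=n,
            N=N,
            p_value=p,
            q_value=float(q),
            significant=bool(r),
        )
        for (pw, k, K, p), q, r in zip(tested, q_values, reject)
    ]
    rows.sort(key=lambda r: (r.p_value, r.pathway_id))
    return rows


def significant_ids(result: Union[Iterable[EnrichmentRow], Iterable[str], FrozenSet[str]]) -> FrozenSet[str]:
    """Significant pathway ids from an enrichment result, or pass a plain
    id collection through unchanged."""
    items = list(result)
    if items and isinstance(items[0], EnrichmentRow):
        return frozenset(r.pathway_id for r in items if r.significant)
    return frozenset(str(x) for x in items)


@dataclass(frozen=True)
class OverlapReport:
    """Pathways significant for the DEG set and for >=1 herb category,
    with the sorted category list per overlapping pathway."""

    overlap: FrozenSet[str]
    categories_by_pathway: Mapping[str, Tuple[int, ...]]

    def to_dataframe(self, names: Mapping[str, str] | None = None) -> pd.DataFrame:
        names = names or {}
        rows = sorted(self.overlap, key=lambda p: names.get(p, p))
        return pd.DataFrame(
            {
                "pathway": [names.get(p, p) for p in rows],
                "categories": [
                    ",".join(str(c) for c in self.categories_by_pathway[p]) for p in rows
                ],
            }
        )


def overlap_with_degs(
    deg_result,
    group_results: Mapping[int, object],
) -> OverlapReport:
    """Intersect DEG-significant pathways with the union over categories.

    ``deg_result`` and each group result may be enrichment row lists or
    plain pathway-id sets (both computed against the same database).
    """
    deg_sig = significant_ids(deg_result)
    group_sig = {c: significant_ids(res) for c, res in group_results.items()}
    union = frozenset().union(*group_sig.values()) if group_sig else frozenset()
    overlap = deg_sig & union
    categories = {
        p: tuple(sorted(c for c, s in group_sig.items() if p in s)) for p in overlap
    }
    return OverlapReport(overlap=overlap, categories_by_pathway=categories)


@dataclass(frozen=True)
class SharedUniqueReport:
    shared: FrozenSet[str]
    unique_by_group: Mapping[int, FrozenSet[str]]
    n_significant_by_group: Mapping[int, int]
    union_size: int

    @property
    def shared_proportion_percent(self) -> float:
        """|shared| / |union of all groups| as a 1-decimal percentage."""
        if self.union_size == 0:
            return 0.0
        return round(100.0 * len(self.shared) / self.union_size, 1)


def shared_and_unique(group_results: Mapping[int, object]) -> SharedUniqueReport:
    """Pathways shared by every category and those unique to exactly one.

    Requires at least two groups; shared and unique sets partition
    disjointly by construction.
    """
    if len(group_results) < 2:
        raise HerbnetError("shared/unique analysis needs >= 2 groups")
    sig = {c: significant_ids(res) for c, res in group_results.items()}
    shared = frozenset.intersection(*sig.values())
    union = frozenset().union(*sig.values())
    unique = {
        c: frozenset(
            p for p in s if all(p not in sig[o] for o in sig if o != c)
        )
        for c, s in sig.items()
    }
    return SharedUniqueReport(
        shared=shared,
        unique_by_group=unique,
        n_significant_by_group={c: len(s) for c, s in sig.items()},
        union_size=len(union),
    )


def enrichment_to_dataframe(rows: Sequence[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pathway_id": [r.pathway_id for r in rows],
            "name": [r.name for r in rows],
            "k": [r.k for r in rows],
            "K": [r.K for r in rows],
            "n": [r.n for r in rows],
            "N": [r.N for r in rows],
            "p_value": [r.p_value for r in rows],
            "q_value": [r.q_value for r in rows],
            "significant": [str(r.significant).lower() for r in rows],
        }
    )
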