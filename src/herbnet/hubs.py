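"""Hub target-protein selection from PPI degree.

A DEG-encoded protein is a *hub target* when it interacts with at least
``threshold`` distinct partners in the global PPI network (default 25), or
when it carries the curated key-protein flag regardless of degree. Degree
counts partners anywhere in the network, not only among DEGs: a DEG
product's neighbourhood is dominated by non-DEG proteins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, List, Sequence, Set

import pandas as pd

from .types import ConfigError, GeneRecord, InteractionNetwork

__all__ = ["HubSelectionResult", "compute_degrees", "select_hubs"]

DEFAULT_HUB_THRESHOLD = 25


def compute_degrees(network: InteractionNetwork, genes: Iterable[str]) -> Dict[str, int]:
    """Degree (distinct-partner count) of each requested gene.

    Genes absent from the network map to 0; they are reported as
    *unmatched* by :func:`select_hubs`.
    """
    return {g: network.degree(g) for g in genes}


@dataclass(frozen=True)
class HubSelectionResult:
    """Outcome of hub selection at a given degree threshold."""

    degree_by_gene: Dict[str, int]
    matched_genes: FrozenSet[str]
    unmatched_genes: FrozenSet[str]
    hub_set: FrozenSet[str]
    threshold: int
    n_degree_qualified: int
    n_key_only: int          # keys below threshold, included regardless
    n_keys_in_qualified: int  # keys that also pass the degree rule
    n_hub_up: int
    n_hub_down: int

    def to_dataframe(self, deg_records: Sequence[GeneRecord]) -> pd.DataFrame:
        """Per-gene report sorted by degree descending then symbol."""
        rows = []
        for rec in deg_records:
            deg = self.degree_by_gene.get(rec.symbol, 0)
            rows.append(
                {
                    "symbol": rec.symbol,
                    "degree": deg,
                    "regulation": rec.regulation,
                    "is_key": str(rec.is_key).lower(),
                    "is_hub": str(rec.symbol in self.hub_set).lower(),
                }
            )
        df = pd.DataFrame(rows)
        return df.sort_values(
            ["degree", "symbol"], ascending=[False, True], kind="mergesort"
        ).reset_index(drop=True)


def select_hubs(
    degrees: Dict[str, int],
    deg_records: Sequence[GeneRecord],
    threshold: int = DEFAULT_HUB_THRESHOLD,
) -> HubSelectionResult:
    """Select hub targets: degree >= threshold, unioned with key proteins.

    Key proteins below the threshold are always included; keys above it are
    not double-counted. Raises :class:`ConfigError` for threshold < 1.
    """
    if int(threshold) < 1:
        raise ConfigError(f"hub degree threshold must be >= 1, got {threshold}")
    threshold = int(threshold)
    by_symbol = {r.symbol: r for r in deg_records}
    degree_by_gene = {r.symbol: int(degrees.get(r.symbol, 0)) for r in deg_records}
    matched = frozenset(g for g, d in degree_by_gene.items() if d > 0)
    unmatched = frozenset(by_symbol) - matched
    qualified: Set[str] = {g for g, d in degree_by_gene.items() if d >= threshold}
    keys = {g for g, r in by_symbol.items() if r.is_key}
    hub_set = frozenset(qualified | keys)
    n_up = sum(1 for g in hub_set if by_symbol[g].regulation == "up")
    return HubSelectionResult(
        degree_by_gene=degree_by_gene,
        matched_genes=matched,
        unmatched_genes=unmatched,
        hub_set=hub_set,
        threshold=threshold,
        n_degree_qualified=len(qualified),
        n_key_only=len(keys - qualified),
        n_keys_in_qualified=len(keys & qualified),
        n_hub_up=n_up,
        n_hub_down=len(hub_set) - n_up,
    )
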