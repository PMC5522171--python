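"""Domain types shared by every pipeline stage.

The pipeline joins six tabular resources — differentially expressed genes
(DEGs), a protein–protein interaction (PPI) network, confidence-scored
chemical–protein links, herb ingredient annotations, synthetic-lethality
(SL) gene pairs and pathway memberships — on one identifier namespace:
HGNC-style gene symbols. Every record type normalizes symbols on
construction so that joins performed before or after normalization agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import FrozenSet, Iterable, Optional, Tuple

__all__ = [
    "HerbnetError",
    "MalformedRecordError",
    "TableParseError",
    "ConfigError",
    "normalize_symbol",
    "GeneRecord",
    "InteractionNetwork",
    "ChemicalProteinLink",
    "HerbRecord",
    "SLPairRecord",
    "PathwayAnnotation",
    "SLCoverageRecord",
    "EXCLUSION_REASONS",
]


class HerbnetError(Exception):
    """Base class for all package errors."""


class MalformedRecordError(HerbnetError, ValueError):
    """A single record violates an invariant (empty symbol, bad range...)."""


class TableParseError(HerbnetError, ValueError):
    """A tabular input could not be parsed; names the offending line."""

    def __init__(self, message: str, path: Optional[str] = None, line: Optional[int] = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class ConfigError(HerbnetError, ValueError):
    """Invalid configuration (e.g. non-positive hub threshold)."""


def normalize_symbol(raw: str) -> str:
    """Normalize a raw gene symbol: strip whitespace and upper-case.

    Idempotent. Raises :class:`MalformedRecordError` for empty or
    whitespace-only input.
    """
    if raw is None:
        raise MalformedRecordError("gene symbol is missing")
    sym = str(raw).strip().upper()
    if not sym:
        raise MalformedRecordError(f"gene symbol is empty or whitespace-only: {raw!r}")
    return sym


@dataclass(frozen=True)
class GeneRecord:
    """A differentially expressed gene with its regulation direction.

    ``is_key`` flags genes curated from the literature as having an
    explicit, experimentally supported role in the disease; such genes are
    promoted to hub status regardless of their PPI degree.
    """

    symbol: str
    regulation: str  # "up" | "down"
    is_key: bool = False

    def __post_init__(self):
        object.__setattr__(self, "symbol", normalize_symbol(self.symbol))
        reg = str(self.regulation).strip().lower()
        if reg not in ("up", "down"):
            raise MalformedRecordError(
                f"regulation must be 'up' or 'down', got {self.regulation!r}"
            )
        object.__setattr__(self, "regulation", reg)
        object.__setattr__(self, "is_key", bool(self.is_key))


class InteractionNetwork:
    """An undirected PPI network stored as a set of unordered symbol pairs.

    Self-loops are dropped on construction and duplicate edges (in either
    orientation) are merged. Node degree counts distinct interaction
    partners.
    """

    __slots__ = ("edges", "_degree")

    def __init__(self, edges: Iterable[Tuple[str, str]]):
        canon = set()
        for a, b in edges:
            a = normalize_symbol(a)
            b = normalize_symbol(b)
            if a == b:
                continue  # self-loop: excluded by invariant
            canon.add((a, b) if a < b else (b, a))
        self.edges: FrozenSet[Tuple[str, str]] = frozenset(canon)
        deg: Counter = Counter()
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        self._degree = dict(deg)

    @property
    def nodes(self) -> FrozenSet[str]:
        return frozenset(self._degree)

    def degree(self, gene: str) -> int:
        """Number of distinct partners of ``gene``; 0 if absent."""
        return self._degree.get(normalize_symbol(gene), 0)

    def degrees(self) -> dict:
        """Degree of every node present in the network."""
        return dict(self._degree)

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edges_from(self.edges)
        return g

    def __len__(self) -> int:
        return len(self.edges)

    def __eq__(self, other) -> bool:
        return isinstance(other, InteractionNetwork) and self.edges == other.edges

    def __hash__(self) -> int:
        return hash(self.edges)

    def __repr__(self) -> str:
        return f"InteractionNetwork({len(self.edges)} edges, {len(self._degree)} nodes)"


@dataclass(frozen=True)
class ChemicalProteinLink:
    """One scored compound→protein association (STITCH-style).

    Confidence lives on the unit scale; readers can divide STITCH's
    0–1000 integer scores by 1000 on request.
    """

    compound_id: str
    compound_name: str
    protein: str
    confidence: float

    def __post_init__(self):
        object.__setattr__(self, "compound_id", str(self.compound_id).strip())
        if not self.compound_id:
            raise MalformedRecordError("compound_id is empty")
        object.__setattr__(self, "protein", normalize_symbol(self.protein))
        conf = float(self.confidence)
        if not (0.0 <= conf <= 1.0):
            raise MalformedRecordError(
                f"confidence must be in [0, 1], got {self.confidence!r}"
            )
        object.__setattr__(self, "confidence", conf)


EXCLUSION_REASONS = ("unconventional", "toxic", "incomplete-annotation")

#: Traditional-pharmacology category labels, in the conventional order.
CATEGORY_NAMES = {
    1: "exterior-releasing",
    2: "heat-clearing",
    3: "tonic",
    4: "antirheumatic",
    5: "hemostyptic",
    6: "hemorheologic",
    7: "energen-regulating",
    8: "others",
}


@dataclass(frozen=True)
class HerbRecord:
    """A Chinese medicine (herb/animal/mineral material) with its category
    label (1–8, traditional-pharmacology grouping) and ingredient set."""

    herb_id: str
    latin_name: str
    pinyin_name: str
    category: int
    ingredients: FrozenSet[str] = frozenset()
    excluded: bool = False
    exclusion_reason: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "herb_id", str(self.herb_id).strip())
        if not self.herb_id:
            raise MalformedRecordError("herb_id is empty")
        cat = int(self.category)
        if cat not in range(1, 9):
            raise MalformedRecordError(
                f"herb {self.herb_id}: category must be 1..8, got {self.category!r}"
            )
        object.__setattr__(self, "category", cat)
        object.__setattr__(
            self, "ingredients", frozenset(str(i).strip() for i in self.ingredients)
        )
        object.__setattr__(self, "excluded", bool(self.excluded))
        reason = self.exclusion_reason
        if reason is not None:
            reason = str(reason).strip() or None
        if self.excluded and reason not in EXCLUSION_REASONS:
            raise MalformedRecordError(
                f"herb {self.herb_id}: excluded herbs need a reason in "
                f"{EXCLUSION_REASONS}, got {reason!r}"
            )
        object.__setattr__(self, "exclusion_reason", reason)


@dataclass(frozen=True)
class SLPairRecord:
    """An unordered synthetic-lethality gene pair with a database confidence
    score and disease tags; stored with gene_a < gene_b."""

    gene_a: str
    gene_b: str
    confidence: float
    diseases: FrozenSet[str] = frozenset()

    def __post_init__(self):
        a = normalize_symbol(self.gene_a)
        b = normalize_symbol(self.gene_b)
        if a == b:
            raise MalformedRecordError(f"SL pair genes must differ, got {a!r} twice")
        if a > b:
            a, b = b, a
        object.__setattr__(self, "gene_a", a)
        object.__setattr__(self, "gene_b", b)
        conf = float(self.confidence)
        if not (0.0 <= conf <= 1.0):
            raise MalformedRecordError(
                f"SL confidence must be in [0, 1], got {self.confidence!r}"
            )
        object.__setattr__(self, "confidence", conf)
        object.__setattr__(
            self, "diseases", frozenset(str(d).strip() for d in self.diseases if str(d).strip())
        )

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset((self.gene_a, self.gene_b))

    @property
    def key(self) -> Tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class PathwayAnnotation:
    """A named gene set (KEGG-style pathway)."""

    pathway_id: str
    name: str
    members: FrozenSet[str]

    def __post_init__(self):
        object.__setattr__(self, "pathway_id", str(self.pathway_id).strip())
        if not self.pathway_id:
            raise MalformedRecordError("pathway_id is empty")
        members = frozenset(normalize_symbol(m) for m in self.members)
        if not members:
            raise MalformedRecordError(
                f"pathway {self.pathway_id}: member set is empty"
            )
        object.__setattr__(self, "members", members)


@dataclass(frozen=True)
class SLCoverageRecord:
    """Evidence that a herb (or herb pair) acts on one SL gene pair.

    ``herb_2`` is ``None`` for single-herb coverage, in which case both
    witness ingredients belong to ``herb_1``. The same ingredient may
    witness both sides (one compound hitting both genes of the pair).
    Targets are aligned to the pair's canonical (gene_a, gene_b) order.
    """

    herb_1: str
    ingredient_1: str
    target_1: str
    ingredient_2: str
    target_2: str
    pair: SLPairRecord
    herb_2: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "target_1", normalize_symbol(self.target_1))
        object.__setattr__(self, "target_2", normalize_symbol(self.target_2))
        if {self.target_1, self.target_2} != self.pair.genes:
            raise MalformedRecordError(
                f"coverage targets {{{self.target_1}, {self.target_2}}} do not match "
                f"SL pair {self.pair.key}"
            )
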