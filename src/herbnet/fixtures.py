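"""In-memory fixtures encoding the published AML screening evidence.

Two printed evidence tables are carried verbatim: the DEG-vs-category
pathway overlap (17 KEGG pathways with their sorted category lists) and
the SL coverage table (54 rows of CM / witness-ingredient / target / SL
confidence evidence). Around them, :func:`table2_fixture` reconstructs the
*input* tables (herbs, ingredient links, SL pairs) that reproduce the
reported SL facts when run through the pipeline:

* the AML-tagged SL database holds five pairs — BRCA1-TP53 (0.82046875),
  CHEK1-TP53 (0.85), ATM-TP53 (0.56), PNKP-PTPN6 (0.56) and
  FLT3-MAPK8 (0.56) — of which exactly two exceed the strict 0.7 cutoff;
* Cornu Cervi Pantotrichum covers all five pairs, Panax ginseng four
  (all but PNKP-PTPN6), and five distinct CMs cover a high-confidence
  pair.

The printed coverage table names no witness ingredients for PNKP-PTPN6 or
FLT3-MAPK8; the fixture supplies chosen witnesses (a dedicated
antler-peptide compound for PNKP/PTPN6, and adenosine triphosphate
extended to FLT3/MAPK8). Those links, the ligustilide→TP53 witness for
Angelica sinensis, and the four blood-activating herbs behind the
decoction variants are synthetic stand-ins constructed for testability,
not published annotations.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Mapping, Tuple

from .types import (
    ChemicalProteinLink,
    GeneRecord,
    HerbRecord,
    SLPairRecord,
)

__all__ = [
    "TABLE1_ROWS",
    "TABLE2_ROWS",
    "table1_fixture",
    "table2_fixture",
    "shengma_fixture",
    "fixture_checksums",
    "Table2Fixture",
]

# ---------------------------------------------------------------------------
# Pathway-overlap table: (KEGG pathway name, sorted category labels).
# Categories: 1 exterior-releasing, 2 heat-clearing, 3 tonic,
# 4 antirheumatic, 5 hemostyptic, 6 hemorheologic, 7 energen-regulating,
# 8 others.
TABLE1_ROWS: Tuple[Tuple[str, Tuple[int, ...]], ...] = (
    ("Adherens junction", (3,)),
    ("Amoebiasis", (1, 2)),
    ("Chagas disease (American trypanosomiasis)", (1, 2)),
    ("Chemokine signaling pathway", (1, 2, 3, 4, 5, 6, 7, 8)),
    ("Cytokine-cytokine receptor interaction", (8,)),
    ("Dilated cardiomyopathy", (1, 2, 3, 4, 5, 6, 7)),
    ("Glycerolipid metabolism", (3,)),
    ("GnRH signaling pathway", (1, 2)),
    ("HIF-1 signaling pathway", (2,)),
    ("Hypertrophic cardiomyopathy (HCM)", (1, 2)),
    ("Inflammatory mediator regulation of TRP channels", (1, 2)),
    ("Pathways in cancer", (1, 2, 3)),
    ("Proteoglycans in cancer", (1, 2)),
    ("Rap1 signaling pathway", (1, 2)),
    ("Regulation of actin cytoskeleton", (3,)),
    ("Rheumatoid arthritis", (2,)),
    ("TNF signaling pathway", (1,)),
)

#: Pathways named as shared across all eight categories without being
#: DEG-enriched; they pad the group profiles so the DEG overlap stays a
#: strict subset of each union.
SHARED_NONDEG_PATHWAYS: Tuple[str, ...] = (
    "Calcium signaling pathway",
    "Fc epsilon RI signaling pathway",
    "Neuroactive ligand-receptor interaction",
)


def table1_fixture() -> Tuple[FrozenSet[str], Dict[int, FrozenSet[str]]]:
    """DEG-significant pathway set and the 8 per-category pathway profiles
    reproducing the printed overlap table."""
    deg_pathways = frozenset(name for name, _ in TABLE1_ROWS)
    groups: Dict[int, set] = {c: set(SHARED_NONDEG_PATHWAYS) for c in range(1, 9)}
    for name, cats in TABLE1_ROWS:
        for c in cats:
            groups[c].add(name)
    return deg_pathways, {c: frozenset(s) for c, s in groups.items()}


# ---------------------------------------------------------------------------
# SL coverage evidence: (CM name, Ingredient 1, Target 1, Ingredient 2,
# Target 2, confidence score) — 54 rows, verbatim.
TABLE2_ROWS: Tuple[Tuple[str, str, str, str, str, float], ...] = (
    ("Arachis hypogaea", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Camellia sinensis", "caffeine", "ATM", "caffeine", "TP53", 0.75),
    ("Camellia sinensis", "caffeine", "ATM", "epigallocatechin 3-gallate", "TP53", 0.75),
    ("Camellia sinensis", "caffeine", "CHEK1", "caffeine", "TP53", 0.85),
    ("Camellia sinensis", "caffeine", "CHEK1", "epigallocatechin 3-gallate", "TP53", 0.85),
    ("Capsicum annuum", "capsaicin", "ATM", "capsaicin", "TP53", 0.75),
    ("Cornu Cervi Pantotrichum", "adenosine triphosphate", "BRCA1", "adenosine triphosphate", "TP53", 0.82),
    ("Cornu Cervi Pantotrichum", "adenosine triphosphate", "ATM", "adenosine triphosphate", "TP53", 0.75),
    ("Cornu Cervi Pantotrichum", "adenosine triphosphate", "CHEK1", "adenosine triphosphate", "TP53", 0.85),
    ("Cistanche deserticola", "genistein", "ATM", "lysine acid", "TP53", 0.75),
    ("Cistanche deserticola", "genistein", "ATM", "lysine", "TP53", 0.75),
    ("Cistanche deserticola", "genistein", "ATM", "zinc", "TP53", 0.75),
    ("Diospyros kaki", "genistein", "ATM", "quercetin", "TP53", 0.75),
    ("Folium camelliae sinensis", "caffeine", "ATM", "caffeine", "TP53", 0.75),
    ("Folium camelliae sinensis", "caffeine", "CHEK1", "caffeine", "TP53", 0.85),
    ("fructus Sophorae", "genistein", "ATM", "quercetin", "TP53", 0.75),
    ("Gardenia jasminoides", "genistein", "ATM", "zinc", "TP53", 0.75),
    ("Gardenia jasminoides", "genistein", "ATM", "quercetin", "TP53", 0.75),
    ("Glehnia littoralis", "Vanilloid", "ATM", "Vanilloid", "TP53", 0.75),
    ("Glehnia littoralis", "Vanilloid", "ATM", "quercetin", "TP53", 0.75),
    ("Ilex cornuta", "caffeine", "ATM", "caffeine", "TP53", 0.75),
    ("Ilex cornuta", "caffeine", "CHEK1", "caffeine", "TP53", 0.85),
    ("Imperata cylindrica var. major", "Vanilloid", "ATM", "Vanilloid", "TP53", 0.75),
    ("Morus alba", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Panax ginseng", "adenosine triphosphate", "BRCA1", "adenosine triphosphate", "TP53", 0.82),
    ("Panax ginseng", "adenosine triphosphate", "ATM", "adenosine triphosphate", "TP53", 0.75),
    ("Panax ginseng", "adenosine triphosphate", "CHEK1", "adenosine triphosphate", "TP53", 0.85),
    ("Polygonum cuspidatum", "trans-resveratrol", "ATM", "trans-resveratrol", "TP53", 0.75),
    ("Polygonum cuspidatum", "trans-resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Polygonum cuspidatum", "trans-resveratrol", "ATM", "quercetin", "TP53", 0.75),
    ("Polygonum cuspidatum", "resveratrol", "ATM", "trans-resveratrol", "TP53", 0.75),
    ("Polygonum cuspidatum", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Polygonum cuspidatum", "resveratrol", "ATM", "quercetin", "TP53", 0.75),
    ("Polygonum multiflorum", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Radix Cudraniae", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Rheum wittrocki", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Semen Phaseoli", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Semen Sojae Praeparata", "genistein", "ATM", "arsenicum", "TP53", 0.75),
    ("Semen Sojae Praeparata", "genistein", "ATM", "lysine", "TP53", 0.75),
    ("Smilax glabra", "trans-resveratrol", "ATM", "trans-resveratrol", "TP53", 0.75),
    ("Smilax glabra", "trans-resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Smilax glabra", "resveratrol", "ATM", "trans-resveratrol", "TP53", 0.75),
    ("Smilax glabra", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Smilax menispermoidea", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Sophora japonica", "genistein", "ATM", "quercetin", "TP53", 0.75),
    ("Testa Arachidis Hypogaeae", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Testa Arachidis Hypogaeae", "resveratrol", "ATM", "quercetin", "TP53", 0.75),
    ("Thalictrum ichangense", "capsaicin", "ATM", "capsaicin", "TP53", 0.75),
    ("Trifolium pratense", "genistein", "ATM", "quercetin", "TP53", 0.75),
    ("Vatica rassak", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Veratrum album", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Veratrum grandiflorum", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Veratrum nigrum var. ussuriense", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
    ("Vitis vinifera", "resveratrol", "ATM", "resveratrol", "TP53", 0.75),
)

# Category assignments for the CMs whose group matters downstream; every
# other coverage-table CM defaults to "others" (8).
_CATEGORY_BY_CM: Mapping[str, int] = {
    "Cornu Cervi Pantotrichum": 3,
    "Panax ginseng": 3,
    "Cistanche deserticola": 3,
    "Angelica sinensis": 3,
    "Camellia sinensis": 2,
    "Folium camelliae sinensis": 2,
    "Ilex cornuta": 2,
}

_PINYIN_BY_CM: Mapping[str, str] = {
    "Cornu Cervi Pantotrichum": "Lu Rong",
    "Panax ginseng": "Ren Shen",
    "Cistanche deserticola": "Rou Cong Rong",
    "Angelica sinensis": "Dang Gui",
    "Camellia sinensis": "Ye Cha Ye",
    "Folium camelliae sinensis": "Lv Cha",
    "Ilex cornuta": "Gou Gu",
}

#: Regulation directions for the fixture's DEG-encoded target genes.
_FIXTURE_DEGS: Tuple[Tuple[str, str], ...] = (
    ("TP53", "down"),
    ("BRCA1", "up"),
    ("CHEK1", "up"),
    ("ATM", "down"),
    ("PNKP", "down"),
    ("PTPN6", "down"),
    ("FLT3", "up"),
    ("MAPK8", "up"),
    ("PRKCD", "down"),
)

_ANTLER_PEPTIDE = "pilose antler peptide"
_LINK_CONFIDENCE = 0.95  # all fixture links sit above the 0.9 cutoff


@dataclass(frozen=True)
class Table2Fixture:
    """Reconstructed input tables behind the printed SL coverage table."""

    rows: Tuple[Tuple[str, str, str, str, str, float], ...]
    herbs: Tuple[HerbRecord, ...]
    deg_records: Tuple[GeneRecord, ...]
    links: Tuple[ChemicalProteinLink, ...]
    sl_pairs: Tuple[SLPairRecord, ...]
    drug_targets: Mapping[str, FrozenSet[str]]

    @property
    def herbs_by_id(self) -> Dict[str, HerbRecord]:
        return {h.herb_id: h for h in self.herbs}


def table2_fixture() -> Table2Fixture:
    """Build the SL-analysis fixture (see module docstring for provenance)."""
    ingredients: Dict[str, set] = {}
    link_targets: Dict[str, set] = {}
    for cm, i1, t1, i2, t2, _conf in TABLE2_ROWS:
        ingredients.setdefault(cm, set()).update((i1, i2))
        link_targets.setdefault(i1, set()).add(t1)
        link_targets.setdefault(i2, set()).add(t2)
    # witnesses beyond the printed rows (chosen; see module docstring)
    ingredients["Cornu Cervi Pantotrichum"].add(_ANTLER_PEPTIDE)
    link_targets.setdefault(_ANTLER_PEPTIDE, set()).update({"PNKP", "PTPN6", "PRKCD"})
    link_targets["adenosine triphosphate"].update({"FLT3", "MAPK8"})
    ingredients["Angelica sinensis"] = {"ligustilide"}
    link_targets.setdefault("ligustilide", set()).add("TP53")

    herbs = tuple(
        HerbRecord(
            herb_id=cm,
            latin_name=cm,
            pinyin_name=_PINYIN_BY_CM.get(cm, ""),
            category=_CATEGORY_BY_CM.get(cm, 8),
            ingredients=frozenset(ing),
        )
        for cm, ing in sorted(ingredients.items())
    )
    links = tuple(
        ChemicalProteinLink(
            compound_id=c, compound_name=c, protein=t, confidence=_LINK_CONFIDENCE
        )
        for c in sorted(link_targets)
        for t in sorted(link_targets[c])
    )
    deg_records = tuple(GeneRecord(symbol=s, regulation=r) for s, r in _FIXTURE_DEGS)
    sl_pairs = (
        SLPairRecord("BRCA1", "TP53", 0.82046875, frozenset({"AML"})),
        SLPairRecord("CHEK1", "TP53", 0.85, frozenset({"AML"})),
        SLPairRecord("ATM", "TP53", 0.56, frozenset({"AML"})),
        SLPairRecord("PNKP", "PTPN6", 0.56, frozenset({"AML"})),
        SLPairRecord("FLT3", "MAPK8", 0.56, frozenset({"AML"})),
    )
    drug_targets = {
        "Ingenol Mebutate": frozenset({"PRKCD"}),
        "Cytarabine": frozenset({"POLA1"}),
        "Daunorubicin": frozenset({"TOP2A"}),
        "Idarubicin": frozenset({"TOP2A"}),
        "Mitoxantrone": frozenset({"TOP2B"}),
    }
    return Table2Fixture(
        rows=TABLE2_ROWS,
        herbs=herbs,
        deg_records=deg_records,
        links=links,
        sl_pairs=sl_pairs,
        drug_targets=drug_targets,
    )


def shengma_fixture() -> Dict[str, object]:
    """Decoction-modification fixture around Shengma-Biejia.

    The base decoction holds three tonic herbs (Glycyrrhiza uralensis,
    Carapax Trionycis, Angelica sinensis) and one exterior-releasing herb
    (Cimicifuga dahurica). Because tonic is saturated, the expected
    extension is a heat-clearing hub CM pairing with Angelica sinensis.
    The four blood-activating (hemorheologic) herbs behind the three
    clinical-feature variants are illustrative stand-ins: the published
    analysis leaves them unnamed.
    """
    t2 = table2_fixture()
    base = (
        HerbRecord("Glycyrrhiza uralensis", "Glycyrrhiza uralensis", "Gan Cao", 3),
        HerbRecord("Carapax Trionycis", "Carapax Trionycis", "Bie Jia", 3),
        t2.herbs_by_id["Angelica sinensis"],
        HerbRecord("Cimicifuga dahurica", "Cimicifuga dahurica", "Sheng Ma", 1),
    )
    hemorheologic = tuple(
        HerbRecord(h, h, py, 6)
        for h, py in (
            ("Ligusticum chuanxiong", "Chuan Xiong"),
            ("Salvia miltiorrhiza", "Dan Shen"),
            ("Carthamus tinctorius", "Hong Hua"),
            ("Prunus persica", "Tao Ren"),
        )
    )
    feature_rules = {
        "expectoration": ["Ligusticum chuanxiong", "Salvia miltiorrhiza"],
        "abdominal pain": ["Carthamus tinctorius"],
        "joint pain": ["Prunus persica", "Salvia miltiorrhiza"],
    }
    return {
        "table2": t2,
        "base_herbs": tuple(h.herb_id for h in base),
        "herbs": t2.herbs + base[:2] + (base[3],) + hemorheologic,
        "feature_rules": feature_rules,
    }


def _digest(rows) -> str:
    payload = "\n".join("\t".join(map(str, row)) for row in rows)
    return hashlib.sha256(payload.encode("utf-8")).hexdigest()


def fixture_checksums() -> Dict[str, str]:
    """SHA-256 digests of the verbatim table encodings (guards drift)."""
    table1 = [(name, ",".join(map(str, cats))) for name, cats in TABLE1_ROWS]
    return {"table1": _digest(table1), "table2": _digest(TABLE2_ROWS)}
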